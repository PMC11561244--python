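"""Editing matrices: assembly from per-sample calls, harmonization, annotation.

An editing matrix is sites x samples of editing levels with missing entries
wherever a site failed calling in a sample. Harmonization applies the
detection-rate / mean-editing / sample-missingness filters that define the
"common high-quality site" set before imputation and differential modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EditingMatrix",
    "HarmonizeConfig",
    "build_matrix",
    "harmonize",
    "annotate_region",
]

REGION_PRIORITY = ["CDS", "UTR3", "UTR5", "INTRON", "INTERGENIC"]
_FEATURE_TO_REGION = {
    "CDS": "CDS",
    "three_prime_UTR": "UTR3",
    "five_prime_UTR": "UTR5",
    "intron": "INTRON",
}


@dataclass
class EditingMatrix:
    """Sites x samples editing levels (NaN = missing) plus site annotations."""

    levels: pd.DataFrame  # index site_id, columns sample_id
    sites: pd.DataFrame   # index site_id: chrom, pos, strand, ...

    def __post_init__(self) -> None:
        if not self.levels.index.equals(self.sites.index):
            raise ValueError("levels and site annotation indexes differ")
        vals = self.levels.to_numpy(dtype=float)
        bad = np.nonzero((vals < 0) | (vals > 1))
        if bad[0].size:
            raise ValueError("editing levels must lie in [0, 1]")

    @property
    def detection_rate(self) -> pd.Series:
        """Per-site fraction of samples where the site was called."""
        return self.levels.notna().mean(axis=1)

    @property
    def mean_editing(self) -> pd.Series:
        """Per-site mean level over non-missing entries."""
        return self.levels.mean(axis=1)

    @property
    def missing_fraction(self) -> pd.Series:
        """Per-sample fraction of missing sites."""
        return self.levels.isna().mean(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape


@dataclass
class HarmonizeConfig:
    min_detection: float = 0.60
    min_mean_editing: float = 0.05
    max_sample_missing: float = 0.20

    def validate(self) -> None:
        for f in ("min_detection", "min_mean_editing", "max_sample_missing"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")


def build_matrix(calls_by_sample: dict[str, pd.DataFrame]) -> EditingMatrix:
    """Assemble per-sample call tables into one editing matrix.

    Only CALLED entries carry a level; every other status is missing. The
    site axis is the union over samples, ordered by (chrom, pos). A site
    appearing twice within one sample is an integrity error.
    """
    series = {}
    meta_frames = []
    for sample, calls in calls_by_sample.items():
        if calls["site_id"].duplicated().any():
            dup = calls.loc[calls["site_id"].duplicated(), "site_id"].iloc[0]
            raise ValueError(f"sample {sample!r} lists site {dup!r} twice")
        called = calls[calls["status"] == "CALLED"]
        series[sample] = called.set_index("site_id")["level"]
        meta_frames.append(calls[["site_id", "chrom", "pos", "strand"]])
    if not series:
        empty = pd.DataFrame()
        return EditingMatrix(empty, pd.DataFrame(index=empty.index))
    sites = (
        pd.concat(meta_frames)
        .drop_duplicates("site_id")
        .sort_values(["chrom", "pos"])
        .set_index("site_id")
    )
    levels = pd.DataFrame(series, index=sites.index)
    levels.columns.name = "sample_id"
    return EditingMatrix(levels, sites)


def harmonize(
    matrix: EditingMatrix, config: HarmonizeConfig | None = None
) -> tuple[EditingMatrix, pd.DataFrame]:
    """Apply the detection / mean-editing / sample-missingness filters.

    Order: (1) drop samples whose missing fraction exceeds the cap; (2)
    recompute site statistics over the retained samples; (3) drop sites
    below the detection-rate or mean-editing thresholds. Returns the
    filtered matrix and a report listing every dropped item with its reason.
    """
    config = config or HarmonizeConfig()
    config.validate()
    report_rows = []

    miss = matrix.missing_fraction
    bad_samples = miss[miss > config.max_sample_missing]
    for s, frac in bad_samples.items():
        report_rows.append(("sample", s, "missing_fraction", frac))
    keep_samples = [s for s in matrix.levels.columns if s not in bad_samples.index]
    if not keep_samples:
        raise ValueError("all samples exceed the missing-value cap")
    levels = matrix.levels[keep_samples]

    detection = levels.notna().mean(axis=1)
    mean_edit = levels.mean(axis=1)
    drop_det = detection < config.min_detection
    drop_mean = (~drop_det) & (mean_edit.fillna(0.0) < config.min_mean_editing)
    for sid in levels.index[drop_det]:
        report_rows.append(("site", sid, "detection_rate", detection[sid]))
    for sid in levels.index[drop_mean]:
        report_rows.append(("site", sid, "mean_editing", mean_edit[sid]))
    keep_sites = levels.index[~(drop_det | drop_mean)]

    filtered = EditingMatrix(levels.loc[keep_sites], matrix.sites.loc[keep_sites])
    report = pd.DataFrame(report_rows, columns=["axis", "id", "reason", "value"])
    return filtered, report


def annotate_region(sites: pd.DataFrame, gene_model: pd.DataFrame) -> pd.DataFrame:
    """Assign each site exactly one genomic-region label.

    ``gene_model`` is a GFF-style table (1-based inclusive start/end) whose
    features include CDS, three_prime_UTR, five_prime_UTR and intron. On
    overlapping features the priority is CDS > UTR3 > UTR5 > INTRON;
    uncovered sites are INTERGENIC.
    """
    out = sites.copy()
    labels = np.full(len(out), "INTERGENIC", dtype=object)
    rank = {r: i for i, r in enumerate(REGION_PRIORITY)}
    current = np.full(len(out), rank["INTERGENIC"])
    pos = out["pos"].to_numpy()
    chrom = out["chrom"].to_numpy()
    feats = gene_model[gene_model["feature"].isin(_FEATURE_TO_REGION)]
    for f in feats.itertuples():
        region = _FEATURE_TO_REGION[f.feature]
        hit = (chrom == f.chrom) & (pos >= f.start) & (pos <= f.end)
        better = hit & (rank[region] < current)
        labels[better] = region
        current[better] = rank[region]
    out["region"] = labels
    return out
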