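"""Cross-layer summaries linking editing to expression and cell fitness.

Covers the correlation of per-site delta editing with gene expression
log-fold change, variance in the Alu Editing Index explained by ADAR-family
expression, gene-set score trajectories against the index, and germ-layer
fitness fractions across knockout conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import EffectSizeResult, bin_contrast

__all__ = [
    "CorrelationResult",
    "correlate_delta_expression",
    "variance_explained",
    "score_gene_set",
    "correlate_score_aei",
    "fitness_fractions",
]


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float

    @property
    def r_squared(self) -> float:
        return self.r ** 2

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, len(x), np.nan)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), len(x), float(p))


def correlate_delta_expression(
    differential: pd.DataFrame,
    logfc_by_gene: pd.Series,
    gene_of_site: pd.Series,
    fdr_threshold: float = 0.05,
) -> CorrelationResult:
    """Pearson r between per-gene delta editing and expression log-fold change.

    Differentially edited sites (FDR below threshold) are mapped to genes via
    ``gene_of_site``; sites sharing a gene contribute their mean delta, and
    each gene pairs once with its expression log-fold change.
    """
    sig = differential[differential["fdr"] < fdr_threshold]
    genes = gene_of_site.reindex(sig.index)
    per_gene = sig["delta"].groupby(genes).mean()
    common = per_gene.index.intersection(logfc_by_gene.index)
    return _pearson(per_gene.loc[common].to_numpy(),
                    logfc_by_gene.loc[common].to_numpy())


def variance_explained(
    aei_by_unit: pd.Series, expression_by_unit: pd.Series
) -> CorrelationResult:
    """Fraction of Alu-index variance explained by one gene's expression.

    Simple least squares of index on expression over matched units (cell
    types or samples); ``r_squared`` is the quantity of interest. A constant
    predictor yields a flagged undefined result.
    """
    common = aei_by_unit.index.intersection(expression_by_unit.index)
    return _pearson(expression_by_unit.loc[common].to_numpy(),
                    aei_by_unit.loc[common].to_numpy())


def score_gene_set(expression: pd.DataFrame, gene_set: list[str],
                   set_name: str = "gene_set") -> pd.Series:
    """Per-sample gene-set score: mean z-score of the member genes.

    ``expression`` is genes x samples. Each member gene is z-scored across
    samples (sample SD); the score is the mean z over members, which makes it
    invariant to per-gene affine rescaling of the raw values. This is a
    transparent substitute for kernel-based set-scoring methods; it preserves
    the quantity used downstream (the correlation of a set-level summary
    with the editing index).
    """
    members = [g for g in gene_set if g in expression.index]
    if not members:
        raise ValueError(f"no member genes of {set_name!r} found: {gene_set}")
    sub = expression.loc[members].astype(float)
    sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    score = z.mean(axis=0)
    score.name = set_name
    return score


def correlate_score_aei(score: pd.Series, aei: pd.Series) -> CorrelationResult:
    """Pearson correlation of a gene-set score with the editing index."""
    common = score.index.intersection(aei.index)
    return _pearson(score.loc[common].to_numpy(), aei.loc[common].to_numpy())


def fitness_fractions(
    counts: pd.DataFrame,
    reference_condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-replicate condition fractions per germ layer, plus contrasts.

    ``counts`` has columns stratum, condition, replicate, count. Within each
    (stratum, replicate) the fraction of cells per condition is computed
    (summing to 1); each condition is then contrasted against the reference
    across replicates with Student's t and Cohen's d. With a single
    replicate the fractions are still reported but contrasts are refused.
    """
    required = {"stratum", "condition", "replicate", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    frac = counts.copy()
    totals = frac.groupby(["stratum", "replicate"])["count"].transform("sum")
    frac["fraction"] = frac["count"] / totals

    for (stratum, rep), grp in frac.groupby(["stratum", "replicate"]):
        if reference_condition not in set(grp["condition"]):
            raise ValueError(
                f"replicate {rep!r} of stratum {stratum!r} lacks the reference "
                f"condition {reference_condition!r}"
            )

    rows = []
    for stratum, grp in frac.groupby("stratum"):
        wide = grp.pivot(index="replicate", columns="condition", values="fraction")
        if len(wide) < 2:
            continue  # single replicate: no contrast
        ref = wide[reference_condition].to_numpy()
        for cond in wide.columns:
            if cond == reference_condition:
                continue
            res: EffectSizeResult = bin_contrast(
                {"ref": ref, "ko": wide[cond].to_numpy()}, ("ref", "ko")
            )
            rows.append((stratum, cond, res.d, res.t, res.p, res.n1, res.n2))
    contrasts = pd.DataFrame(
        rows, columns=["stratum", "condition", "d", "t", "p", "n_ref", "n_ko"]
    )
    return frac, contrasts
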