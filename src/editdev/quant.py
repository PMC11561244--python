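"""Base counting, editing-site calling, and the Alu Editing Index.

The counting model re-creates an mpileup-style traversal with the masking
rules used for A-to-I quantification: bases within a fixed distance of read
termini or splice-gap boundaries are ignored, as are low-quality bases and
low-MAPQ reads. Site calling then interprets strand-frame A+G (or T+C)
coverage at cataloged positions, and the Alu Editing Index aggregates the
same mismatch ratio over all adenosines in stranded Alu intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "QuantConfig",
    "PileupCounts",
    "AluEditingIndex",
    "pileup",
    "call_sites",
    "compute_aei",
    "stratify_by_repeat",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


@dataclass
class QuantConfig:
    """Masking and calling thresholds.

    ``end_mask_bp`` and ``splice_mask_bp`` are inclusive: a base whose
    1-based distance to a read terminus / splice boundary is <= the mask is
    dropped. Coverage and edited-read minimums gate site calls.
    """

    end_mask_bp: int = 5
    splice_mask_bp: int = 5
    min_base_quality: int = 20
    min_mapq: int = 20
    min_coverage: int = 5
    min_edited: int = 3

    def validate(self) -> None:
        for f in ("end_mask_bp", "splice_mask_bp", "min_base_quality",
                  "min_mapq", "min_coverage", "min_edited"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


class PileupCounts:
    """Per-position base counts over one or more reference windows.

    Holds, per chromosome, a window offset and a 4 x width array of
    (A, C, G, T) read-base counts in reference frame after masking.
    """

    def __init__(self) -> None:
        self._windows: dict[str, tuple[int, np.ndarray]] = {}

    def _ensure(self, chrom: str, start0: int, end0: int) -> None:
        if chrom not in self._windows:
            self._windows[chrom] = (start0, np.zeros((4, end0 - start0), dtype=np.int64))

    def counts_at(self, chrom: str, pos1: int) -> np.ndarray:
        """(n_A, n_C, n_G, n_T) at a 1-based position; zeros outside windows."""
        win = self._windows.get(chrom)
        if win is None:
            return np.zeros(4, dtype=np.int64)
        off, arr = win
        i = pos1 - 1 - off
        if i < 0 or i >= arr.shape[1]:
            return np.zeros(4, dtype=np.int64)
        return arr[:, i]

    def window(self, chrom: str) -> tuple[int, np.ndarray]:
        return self._windows[chrom]

    def chroms(self) -> list[str]:
        return list(self._windows)

    def to_frame(self) -> pd.DataFrame:
        """Long table (chrom, pos 1-based, n_A, n_C, n_G, n_T), covered positions only."""
        rows = []
        for chrom, (off, arr) in self._windows.items():
            covered = arr.sum(axis=0) > 0
            for i in np.nonzero(covered)[0]:
                rows.append((chrom, off + int(i) + 1, *arr[:, i].tolist()))
        return pd.DataFrame(rows, columns=["chrom", "pos", "n_A", "n_C", "n_G", "n_T"])


def _query_keep_mask(read: pysam.AlignedSegment, config: QuantConfig) -> np.ndarray:
    """Which query positions of this read may contribute a base."""
    L = read.query_length or len(read.query_sequence)
    keep = np.ones(L, dtype=bool)
    m = config.end_mask_bp
    if m > 0:
        keep[:m] = False
        if m <= L:
            keep[L - m:] = False
        else:
            keep[:] = False
    quals = read.query_qualities
    if quals is not None and config.min_base_quality > 0:
        keep &= np.asarray(quals) >= config.min_base_quality
    # splice-gap boundaries in query coordinates: an N op between query
    # index j-1 (last base of the left block) and j
    if config.splice_mask_bp > 0 and read.cigartuples:
        q = 0
        for op, length in read.cigartuples:
            if op in (0, 7, 8, 1, 4):  # ops that consume query
                q += length
            elif op == 3:  # N: splice gap at query boundary q
                lo = max(0, q - config.splice_mask_bp)
                hi = min(L, q + config.splice_mask_bp)
                keep[lo:hi] = False
    return keep


def pileup(
    alignments: Iterable[pysam.AlignedSegment],
    reference: dict[str, str],
    config: QuantConfig | None = None,
    region: tuple[str, int, int] | None = None,
) -> PileupCounts:
    """Count reference-frame read bases per position with masking applied.

    ``region`` is (chrom, start0, end0) half-open; ``None`` counts over every
    full chromosome of the reference. Input must be coordinate-sorted per
    chromosome (checked). A read contributes its base at a position iff the
    position falls in an aligned match block, the base is clear of the
    terminal and splice masks, its quality passes, and the read's MAPQ passes.
    """
    config = config or QuantConfig()
    config.validate()
    counts = PileupCounts()
    if region is not None:
        chrom, r0, r1 = region
        if chrom not in reference:
            raise ValueError(f"region chromosome {chrom!r} not in reference")
        if r0 < 0 or r1 > len(reference[chrom]) or r0 >= r1:
            raise ValueError(f"region {region} outside reference bounds")
        counts._ensure(chrom, r0, r1)
    else:
        for chrom, seq in reference.items():
            counts._ensure(chrom, 0, len(seq))

    last_pos: dict[str, int] = {}
    for read in alignments:
        if read.is_unmapped:
            continue
        chrom = read.reference_name
        if chrom not in reference:
            raise ValueError(f"read {read.query_name} maps to unknown {chrom!r}")
        if read.reference_start < last_pos.get(chrom, -1):
            raise ValueError(
                f"alignments not coordinate-sorted at {chrom}:{read.reference_start + 1}"
            )
        last_pos[chrom] = read.reference_start
        if chrom not in counts._windows:
            continue
        if read.mapping_quality < config.min_mapq:
            continue
        seq = read.query_sequence
        if not seq:
            continue
        keep = _query_keep_mask(read, config)
        base_idx = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        keep &= base_idx >= 0
        off, arr = counts._windows[chrom]
        width = arr.shape[1]

        q = 0
        r = read.reference_start
        for op, length in read.cigartuples:
            if op in (0, 7, 8):  # aligned match block
                qs = np.arange(q, q + length)
                rs = np.arange(r, r + length) - off
                ok = keep[qs] & (rs >= 0) & (rs < width)
                if ok.any():
                    np.add.at(arr, (base_idx[qs[ok]], rs[ok]), 1)
                q += length
                r += length
            elif op in (1, 4):  # insertion / soft clip consume query only
                q += length
            elif op in (2, 3):  # deletion / splice consume reference only
                r += length
    return counts


def call_sites(
    counts: PileupCounts,
    site_catalog: pd.DataFrame,
    snp_panel: pd.DataFrame,
    reference: dict[str, str],
    config: QuantConfig | None = None,
) -> pd.DataFrame:
    """Per-site editing calls at cataloged positions.

    ``site_catalog`` needs columns site_id, chrom, pos (1-based), strand. In
    the site's strand frame, coverage = A+G reads and edited = G reads
    (T+C / C in reference frame for minus-strand sites). Status is one of
    CALLED / LOW_COVERAGE / LOW_EDITED / SNP_MASKED / NOT_DETECTED, and the
    editing level ``edited / coverage`` is reported only for CALLED sites.
    """
    config = config or QuantConfig()
    snp_keys = set(zip(snp_panel["chrom"], snp_panel["pos"])) if len(snp_panel) else set()
    rows = []
    for site in site_catalog.itertuples():
        refbase = reference[site.chrom][site.pos - 1].upper()
        want = "A" if site.strand == "+" else "T"
        if refbase != want:
            raise ValueError(
                f"catalog site {site.site_id} is {refbase}, not a strand-frame "
                f"adenosine ({want} expected on {site.strand})"
            )
        n = counts.counts_at(site.chrom, site.pos)
        if site.strand == "+":
            coverage = int(n[_BASE_INDEX["A"]] + n[_BASE_INDEX["G"]])
            edited = int(n[_BASE_INDEX["G"]])
        else:
            coverage = int(n[_BASE_INDEX["T"]] + n[_BASE_INDEX["C"]])
            edited = int(n[_BASE_INDEX["C"]])
        if (site.chrom, site.pos) in snp_keys:
            status = "SNP_MASKED"
        elif coverage == 0:
            status = "NOT_DETECTED"
        elif coverage < config.min_coverage:
            status = "LOW_COVERAGE"
        elif edited < config.min_edited:
            status = "LOW_EDITED"
        else:
            status = "CALLED"
        level = edited / coverage if status == "CALLED" else np.nan
        rows.append((site.site_id, site.chrom, site.pos, site.strand,
                     coverage, edited, level, status))
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "pos", "strand", "coverage",
                       "edited", "level", "status"],
    )


@dataclass
class AluEditingIndex:
    """Aggregate A-to-G mismatch ratio over Alu adenosines for one sample."""

    sample_id: str
    numerator: int
    denominator: int

    @property
    def aei(self) -> float:
        if self.denominator == 0:
            return np.nan

        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def compute_aei(
    alignments: Iterable[pysam.AlignedSegment],
    alu_intervals: pd.DataFrame,
    reference: dict[str, str],
    snp_panel: pd.DataFrame,
    config: QuantConfig | None = None,
    sample_id: str = "sample",
    counts: PileupCounts | None = None,
) -> AluEditingIndex:
    """Alu Editing Index: edited-base mass over adenosine coverage in Alus.

    For every position inside a stranded Alu interval whose strand-frame
    reference base is A (and which is not in the SNP panel), the numerator
    accumulates strand-frame G read bases and the denominator strand-frame
    A+G read bases, using the same masked pileup as site calling. Positions
    covered by overlapping intervals on both strands are evaluated once per
    interval, each in its own strand frame. A zero denominator yields a
    flagged undefined index rather than an error.

    A precomputed ``counts`` pileup may be passed to avoid re-reading the
    alignment stream (``alignments`` is then ignored).
    """
    config = config or QuantConfig()
    if counts is None:
        counts = pileup(alignments, reference, config)
    snp_keys = set(zip(snp_panel["chrom"], snp_panel["pos"])) if len(snp_panel) else set()
    iA, iC, iG, iT = (_BASE_INDEX[b] for b in "ACGT")
    num = den = 0
    for iv in alu_intervals.itertuples():
        seq = reference[iv.chrom]
        want = "A" if iv.strand == "+" else "T"
        for p0 in range(iv.start, iv.end):
            if seq[p0].upper() != want:
                continue
            if (iv.chrom, p0 + 1) in snp_keys:
                continue
            n = counts.counts_at(iv.chrom, p0 + 1)
            if iv.strand == "+":
                num += int(n[iG])
                den += int(n[iA] + n[iG])
            else:
                num += int(n[iC])
                den += int(n[iT] + n[iC])
    return AluEditingIndex(sample_id, num, den)


def stratify_by_repeat(calls: pd.DataFrame, repeats: pd.DataFrame) -> pd.DataFrame:
    """Label calls by repeat context: ALU > NONALU_REP > NONREP on overlap.

    ``repeats`` is a BED-like table with a repeat_class column; positions not
    covered by any repeat interval default to NONREP.
    """
    out = calls.copy()
    labels = np.full(len(out), "NONREP", dtype=object)
    for cls in ("NONALU_REP", "ALU"):  # ALU applied last wins on overlap
        ivs = repeats[repeats.repeat_class == cls]
        for iv in ivs.itertuples():
            hit = (
                (out["chrom"] == iv.chrom)
                & (out["pos"] > iv.start)
                & (out["pos"] <= iv.end)
            )
            labels[hit.to_numpy()] = cls
    out["repeat_class"] = labels
    return out
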