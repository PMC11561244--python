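"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive results from first principles (raw SAM text,
naive per-read loops, direct formula evaluation) so they share no code with
the package paths they check.
"""

from __future__ import annotations

import re

import numpy as np

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def brute_force_pileup(
    sam_text: str,
    end_mask: int = 5,
    splice_mask: int = 5,
    min_base_quality: int = 20,
    min_mapq: int = 20,
) -> dict[tuple[str, int], dict[str, int]]:
    """Naive per-read, per-base recount straight from SAM text.

    Returns (chrom, pos 1-based) -> {A, C, G, T} counts after applying the
    terminal, splice-distance, base-quality and MAPQ masks.
    """
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        flag, chrom, pos, mapq = int(f[1]), f[2], int(f[3]), int(f[4])
        cigar, seq, qual = f[5], f[9], f[10]
        if flag & 4 or mapq < min_mapq:
            continue
        L = len(seq)
        placements: list[tuple[int, int]] = []  # (query index, ref index 0-based)
        gap_boundaries: list[int] = []  # query index just right of each N gap
        q = 0
        r = pos - 1
        for n_str, op in _CIGAR_RE.findall(cigar):
            n = int(n_str)
            if op in "M=X":
                for i in range(n):
                    placements.append((q + i, r + i))
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op == "N":
                gap_boundaries.append(q)
                r += n
            elif op == "D":
                r += n
        for qi, ri in placements:
            if qi < end_mask or qi >= L - end_mask:
                continue
            if ord(qual[qi]) - 33 < min_base_quality:
                continue
            if any(b - splice_mask <= qi < b + splice_mask for b in gap_boundaries):
                continue
            base = seq[qi].upper()
            if base not in "ACGT":
                continue
            key = (chrom, ri + 1)
            if key not in counts:
                counts[key] = {b: 0 for b in "ACGT"}
            counts[key][base] += 1
    return counts


def brute_force_call(
    counts: dict[tuple[str, int], dict[str, int]],
    chrom: str,
    pos: int,
    strand: str,
    in_snp_panel: bool,
    min_coverage: int = 5,
    min_edited: int = 3,
) -> tuple[int, int, float, str]:
    """Apply the site-calling rules directly to brute-force counts."""
    n = counts.get((chrom, pos), {b: 0 for b in "ACGT"})
    if strand == "+":
        coverage, edited = n["A"] + n["G"], n["G"]
    else:
        coverage, edited = n["T"] + n["C"], n["C"]
    if in_snp_panel:
        status = "SNP_MASKED"
    elif coverage == 0:
        status = "NOT_DETECTED"
    elif coverage < min_coverage:
        status = "LOW_COVERAGE"
    elif edited < min_edited:
        status = "LOW_EDITED"
    else:
        status = "CALLED"
    level = edited / coverage if status == "CALLED" else float("nan")
    return coverage, edited, level, status


def brute_force_bh(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg from the sorted p*m/rank definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(monotone, 1.0)
    return out


def brute_force_cohens_d(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    s1 = np.sum((a - a.mean()) ** 2) / (n1 - 1)
    s2 = np.sum((b - b.mean()) ** 2) / (n2 - 1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    return (b.mean() - a.mean()) / pooled
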