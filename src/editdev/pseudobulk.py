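"""Pseudobulk construction: split reads by cell state and collapse PCR duplicates.

Single-cell / single-nucleus alignments tagged with cell barcodes (CB) and
UMIs (UB) are partitioned into per-state streams (cell type, batch, KO
condition) and deduplicated per (barcode, position, strand) group, either by
exact UMI identity or with the directional network collapse scheme used by
UMI-tools, where a high-count UMI absorbs Hamming-1 neighbours whose count
is at most about half its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pysam

__all__ = ["CellStateMap", "DedupConfig", "split_by_state", "dedup_umi"]

SINK_STATE = "unassigned"


@dataclass
class CellStateMap:
    """barcode -> state label; unmapped or untagged barcodes go to a sink."""

    mapping: dict[str, str]
    sink: str = SINK_STATE

    def state_of(self, barcode: str | None) -> str:
        if barcode is None:
            return self.sink
        return self.mapping.get(barcode, self.sink)


@dataclass
class DedupConfig:
    """PCR-duplicate collapse policy.

    ``exact`` keeps one read per distinct UMI in each (barcode, start,
    strand) group. ``directional`` first merges UMIs: u1 absorbs a Hamming-1
    neighbour u2 iff count(u1) >= 2*count(u2) - 1, resolved greedily from the
    highest-count UMI down, then keeps one read per surviving UMI. The kept
    read is the one with the highest mean base quality (ties broken by the
    lexicographically smallest read name).
    """

    mode: str = "exact"
    max_hamming: int = 1

    def validate(self) -> None:
        if self.mode not in ("exact", "directional"):
            raise ValueError(f"unknown dedup mode {self.mode!r}")


def _barcode(read: pysam.AlignedSegment) -> str | None:
    return read.get_tag("CB") if read.has_tag("CB") else None


def _umi(read: pysam.AlignedSegment) -> str | None:
    return read.get_tag("UB") if read.has_tag("UB") else None


def split_by_state(
    alignments: Iterable[pysam.AlignedSegment],
    state_map: CellStateMap,
) -> tuple[dict[str, list[pysam.AlignedSegment]], int]:
    """Partition reads by the state of their cell barcode.

    Every read lands in exactly one stream; input order (hence coordinate
    sorting) is preserved within each stream. Reads without a CB tag are
    routed to the sink, and their number is returned alongside the streams.
    """
    streams: dict[str, list[pysam.AlignedSegment]] = {}
    missing = 0
    for read in alignments:
        bc = _barcode(read)
        if bc is None:
            missing += 1
        streams.setdefault(state_map.state_of(bc), []).append(read)
    if missing:
        warnings.warn(f"{missing} reads had no CB barcode tag; routed to "
                      f"{state_map.sink!r}", stacklevel=2)
    return streams, missing


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) == 1


def _directional_survivors(umi_counts: dict[str, int]) -> dict[str, str]:
    """Map each UMI to the UMI that absorbs it (itself if it survives).

    Greedy pass over UMIs ordered by descending count (ties lexicographic):
    an unabsorbed UMI becomes a cluster head and absorbs any still-free
    Hamming-1 neighbour u2 with count(head) >= 2*count(u2) - 1, then keeps
    absorbing transitively from the absorbed node (breadth-first), matching
    the directional adjacency network.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned: dict[str, str] = {}
    for head in order:
        if head in assigned:
            continue
        assigned[head] = head
        frontier = [head]
        while frontier:
            nxt = []
            for u1 in frontier:
                for u2 in order:
                    if u2 in assigned or not _hamming1(u1, u2):
                        continue
                    if umi_counts[u1] >= 2 * umi_counts[u2] - 1:
                        assigned[u2] = head
                        nxt.append(u2)
            frontier = nxt
    return assigned


def _mean_quality(read: pysam.AlignedSegment) -> float:
    q = read.query_qualities
    return float(np.mean(q)) if q is not None and len(q) else 0.0


def dedup_umi(
    alignments: Iterable[pysam.AlignedSegment],
    config: DedupConfig | None = None,
) -> list[pysam.AlignedSegment]:
    """Remove PCR duplicates within (barcode, alignment start, strand) groups.

    Input must be coordinate-sorted; output preserves that order. Reads
    missing a UB tag raise an error naming the read.
    """
    config = config or DedupConfig()
    config.validate()
    groups: dict[tuple, list[pysam.AlignedSegment]] = {}
    order: list[tuple] = []
    for read in alignments:
        umi = _umi(read)
        if umi is None:
            raise ValueError(f"read {read.query_name} has no UB tag; UMI dedup "
                             "requires UMI-tagged reads")
        key = (_barcode(read), read.reference_name, read.reference_start,
               read.is_reverse)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(read)

    kept: list[pysam.AlignedSegment] = []
    for key in order:
        members = groups[key]
        counts: dict[str, int] = {}
        for r in members:
            counts[_umi(r)] = counts.get(_umi(r), 0) + 1
        if config.mode == "directional" and len(counts) > 1:
            absorb = _directional_survivors(counts)
        else:
            absorb = {u: u for u in counts}
        by_cluster: dict[str, list[pysam.AlignedSegment]] = {}
        for r in members:
            by_cluster.setdefault(absorb[_umi(r)], []).append(r)
        for head in sorted(by_cluster):
            best = min(by_cluster[head],
                       key=lambda r: (-_mean_quality(r), r.query_name))
            kept.append(best)
    # groups were recorded in first-appearance order of a sorted stream, and
    # within a position ties keep stable order, so output stays sorted
    return kept
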