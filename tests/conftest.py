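from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from editdev.synthetic import (
    ReferenceBundle,
    SampleDesign,
    SyntheticGenomeSpec,
    generate_reference,
)


@pytest.fixture(scope="session")
def tiny_bundle() -> ReferenceBundle:
    """One 10 kb chromosome with 8 Alus, a few other repeats, 4 genes."""
    spec = SyntheticGenomeSpec(
        n_chroms=1, chrom_length=10_000, n_alus=8, alu_length=300, seed=11
    )
    return generate_reference(spec)


@pytest.fixture(scope="session")
def designs_8() -> list[SampleDesign]:
    pre = [SampleDesign(f"pre_{i}", w, "wpc", "FM"[i % 2])
           for i, w in enumerate([5, 8, 12, 18])]
    post = [SampleDesign(f"post_{i}", y, "years", "MF"[i % 2])
            for i, y in enumerate([1, 10, 30, 55])]
    return pre + post


def make_header(reference: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_references(
        list(reference), [len(s) for s in reference.values()]
    )


def make_read(
    header: pysam.AlignmentHeader,
    chrom: str,
    start0: int,
    seq: str,
    cigar: list[tuple[int, int]] | None = None,
    quals: list[int] | int = 37,
    mapq: int = 60,
    name: str = "read",
    flag: int = 0,
    tags: dict[str, str] | None = None,
) -> pysam.AlignedSegment:
    """Construct one aligned read for hand-built fixtures."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = list(header.references).index(chrom)
    a.reference_start = start0
    a.mapping_quality = mapq
    a.cigartuples = cigar or [(0, len(seq))]
    if isinstance(quals, int):
        quals = [quals] * len(seq)
    a.query_qualities = quals
    for tag, value in (tags or {}).items():
        a.set_tag(tag, value)
    return a


def sam_text(header: pysam.AlignmentHeader,
             reads: list[pysam.AlignedSegment]) -> str:
    """Serialize reads to SAM text (the oracle's input format)."""
    lines = [str(header).rstrip("\n")]
    lines += [r.to_string() for r in reads]
    return "\n".join(lines) + "\n"


def random_reads(
    rng: np.random.Generator,
    header: pysam.AlignmentHeader,
    reference: dict[str, str],
    n_reads: int,
    read_length: int = 40,
    spliced_fraction: float = 0.3,
    mismatch_rate: float = 0.1,
) -> list[pysam.AlignedSegment]:
    """Random fixture reads: mixed quality, MAPQ, splices, and mismatches."""
    chroms = list(reference)
    reads = []
    layouts = []
    for i in range(n_reads):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = len(reference[chrom])
        spliced = rng.random() < spliced_fraction
        gap = int(rng.integers(10, 200)) if spliced else 0
        start = int(rng.integers(0, clen - read_length - gap))
        layouts.append((chrom, start, gap))
    layouts.sort(key=lambda t: (t[0], t[1]))
    for i, (chrom, start, gap) in enumerate(layouts):
        if gap:
            left = int(rng.integers(1, read_length))
            cigar = [(0, left), (3, gap), (0, read_length - left)]
            ref_seq = (reference[chrom][start: start + left]
                       + reference[chrom][start + left + gap:
                                          start + left + gap + read_length - left])
        else:
            cigar = [(0, read_length)]
            ref_seq = reference[chrom][start: start + read_length]
        bases = np.array(list(ref_seq))
        hit = rng.random(read_length) < mismatch_rate
        for j in np.nonzero(hit)[0]:
            bases[j] = "ACGT"[int(rng.integers(4))]
        quals = rng.integers(5, 41, size=read_length).tolist()
        mapq = int(rng.choice([0, 10, 20, 60]))
        reads.append(
            make_read(header, chrom, start, "".join(bases), cigar, quals, mapq,
                      name=f"rnd{i}")
        )
    return reads


@pytest.fixture
def flat_reference() -> dict[str, str]:
    """Two small chromosomes of mixed sequence for hand-built read tests."""
    rng = np.random.default_rng(7)
    return {
        "chrA": "".join(rng.choice(list("ACGT"), size=600)),
        "chrB": "".join(rng.choice(list("ACGT"), size=400)),
    }


def simple_calls(site_ids, statuses, levels, chrom="chr1"):
    """Minimal per-sample call table for matrix-assembly tests."""
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "chrom": chrom,
            "pos": np.arange(1, len(site_ids) + 1) * 10,
            "strand": "+",
            "coverage": 10,
            "edited": 5,
            "level": levels,
            "status": statuses,
        }
    )
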