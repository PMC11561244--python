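"""Synthetic genomes, editing truth tables, reads, and expression profiles.

This module fabricates miniature but structurally faithful inputs for the
editing pipeline: chromosomes carrying stranded A-rich Alu repeats, a simple
gene model (5'UTR / CDS / intron / CDS / 3'UTR), a SNP exclusion panel,
splice junctions, per-site editing "truth" rates that follow developmental
trajectories with covariate coupling, aligned reads (SAM) whose A-to-G
mismatch fractions realize those rates binomially, and ADAR-family
expression tables. Everything is deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SyntheticGenomeSpec",
    "ReferenceBundle",
    "SampleDesign",
    "TrajectoryModel",
    "generate_reference",
    "simulate_truth",
    "uniform_alu_truth",
    "simulate_reads",
    "simulate_expression",
    "matrix_from_truth",
    "mar_mask",
    "age_in_years",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Base composition of synthetic repeats in the strand frame: adenosine-rich,
# so that stranded intervals carry many editable positions.
_ALU_PROBS = {"A": 0.45, "C": 0.15, "G": 0.15, "T": 0.25}


class ConfigurationError(ValueError):
    """Raised when a simulation request cannot be satisfied."""


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a miniature genome with planted stranded repeats."""

    n_chroms: int = 2
    chrom_length: int = 50_000
    n_alus: int = 60
    alu_length: int = 300
    alu_strand_fraction_plus: float = 0.6
    gc_content: float = 0.42
    seed: int = 0
    # non-Alu repeats are planted at this ratio relative to Alus
    nonalu_repeat_fraction: float = 0.15
    genes_per_chrom: int = 4
    snps_per_chrom: int = 30

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1000:
            raise ConfigurationError("need at least one chromosome of >= 1 kb")
        if not 0.0 <= self.alu_strand_fraction_plus <= 1.0:
            raise ConfigurationError("alu_strand_fraction_plus must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigurationError("gc_content must be in (0, 1)")
        if self.n_alus * self.alu_length >= self.n_chroms * self.chrom_length:
            raise ConfigurationError("requested repeats do not fit in the genome")


@dataclass
class ReferenceBundle:
    """All reference-side artifacts produced by :func:`generate_reference`.

    Intervals (``alu``, ``repeats``) are BED-style 0-based half-open with a
    strand column; ``genes`` uses GFF-style 1-based inclusive coordinates;
    ``snps`` positions are 1-based.
    """

    sequences: dict[str, str]
    alu: pd.DataFrame
    repeats: pd.DataFrame
    genes: pd.DataFrame
    snps: pd.DataFrame
    junctions: pd.DataFrame

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_references(
            list(self.sequences), [len(s) for s in self.sequences.values()]
        )


@dataclass
class SampleDesign:
    """One sample: identity, age, and the covariates the models adjust for."""

    sample_id: str
    age_value: float
    age_unit: str  # "wpc" | "years"
    sex: str = "F"
    adar_expr: float = 0.0
    adarb1_expr: float = 0.0
    modality: str = "bulk"  # "bulk" | "single_cell" | "single_nucleus"

    def __post_init__(self) -> None:
        if self.age_unit not in ("wpc", "years"):
            raise ConfigurationError(f"unknown age unit {self.age_unit!r}")
        if self.age_value < 0:
            raise ConfigurationError("age must be non-negative")

    @property
    def group(self) -> str:
        # weeks-post-conception samples are prenatal by definition
        return "prenatal" if self.age_unit == "wpc" else "postnatal"


def age_in_years(age_value: float, age_unit: str) -> float:
    """Map an age to a single axis: years relative to birth (prenatal < 0)."""
    if age_unit == "wpc":
        return (age_value - 40.0) / 52.0
    return float(age_value)


@dataclass
class TrajectoryModel:
    """Developmental trajectory of a rate or expression value.

    ``constant`` holds at ``baseline``; ``logistic_increase`` rises smoothly
    by ``amplitude`` around birth; ``early_drop`` falls during gestation and
    recovers postnatally. ``covariate_effects`` adds ``slope * covariate``
    per unit of the named sample covariate.
    """

    baseline: float = 0.2
    amplitude: float = 0.0
    shape: str = "constant"
    noise_sd: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def mean_value(self, design: SampleDesign) -> float:
        t = age_in_years(design.age_value, design.age_unit)
        if self.shape == "constant":
            v = self.baseline
        elif self.shape == "logistic_increase":
            v = self.baseline + self.amplitude / (1.0 + np.exp(-t))
        elif self.shape == "early_drop":
            if t < 0:
                # falls from baseline+amplitude at conception to baseline at birth
                v = self.baseline + self.amplitude * min(1.0, -t / 0.75)
            else:
                v = self.baseline + self.amplitude * (1.0 - np.exp(-t / 5.0))
        else:
            raise ConfigurationError(f"unknown trajectory shape {self.shape!r}")
        for cov, slope in self.covariate_effects.items():
            v += slope * getattr(design, cov)
        return float(v)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _repeat_sequence(rng: np.random.Generator, n: int, strand: str) -> np.ndarray:
    probs = np.array([_ALU_PROBS[b] for b in "ACGT"])
    seq = rng.choice(_BASES, size=n, p=probs)
    if strand == "-":
        comp = np.array([_COMPLEMENT[b] for b in seq])
        seq = comp[::-1]
    return seq


def generate_reference(spec: SyntheticGenomeSpec) -> ReferenceBundle:
    """Build a deterministic miniature reference with planted annotations.

    Repeats are placed one per equal-width slot, which guarantees they are
    non-overlapping and inside chromosome bounds. A fixed fraction of planted
    repeats is labeled non-Alu repetitive; the rest are Alu. Each chromosome
    carries ``genes_per_chrom`` genes laid out as
    5'UTR - CDS - intron - CDS - 3'UTR (the 3'UTR is the widest segment),
    giving one splice junction per gene. The SNP panel mixes random positions
    with strand-frame adenosines inside Alus so SNP masking is exercised
    where it matters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_rep = max(1, int(round(spec.n_alus * spec.nonalu_repeat_fraction)))
    total_intervals = spec.n_alus + n_rep
    per_chrom = np.full(spec.n_chroms, total_intervals // spec.n_chroms)
    per_chrom[: total_intervals % spec.n_chroms] += 1

    n_plus = int(round(spec.n_alus * spec.alu_strand_fraction_plus))
    alu_strands = np.array(["+"] * n_plus + ["-"] * (spec.n_alus - n_plus))
    rng.shuffle(alu_strands)
    # which of the planted intervals are Alu vs other repeat
    classes = np.array(["ALU"] * spec.n_alus + ["NONALU_REP"] * n_rep)
    rng.shuffle(classes)
    rep_strands = rng.choice(["+", "-"], size=n_rep)

    sequences: dict[str, str] = {}
    rep_rows = []
    gene_rows = []
    junc_rows = []
    snp_rows = []
    alu_i = rep_i = interval_i = 0

    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, spec.chrom_length, spec.gc_content)

        k = per_chrom[ci]
        if k:
            slot = spec.chrom_length // k
            if slot < spec.alu_length + 2:
                raise ConfigurationError(
                    f"cannot pack {k} repeats of {spec.alu_length} bp "
                    f"into {spec.chrom_length} bp"
                )
            for s in range(k):
                start = s * slot + int(rng.integers(0, slot - spec.alu_length + 1))
                end = start + spec.alu_length
                cls = classes[interval_i]
                if cls == "ALU":
                    strand = alu_strands[alu_i]
                    name = f"Alu_{chrom}_{alu_i}"
                    alu_i += 1
                else:
                    strand = rep_strands[rep_i]
                    name = f"Rep_{chrom}_{rep_i}"
                    rep_i += 1
                interval_i += 1
                seq[start:end] = _repeat_sequence(rng, spec.alu_length, strand)
                rep_rows.append((chrom, start, end, name, 0, strand, cls))

        # gene model: tile the chromosome with genes, alternating strand
        span = spec.chrom_length // spec.genes_per_chrom
        for gi in range(spec.genes_per_chrom):
            g0 = gi * span + span // 20
            glen = span - span // 10
            strand = "+" if gi % 2 == 0 else "-"
            gene_id = f"gene_{chrom}_{gi}"
            # segment widths as fractions of the gene body (3'UTR widest)
            widths = (np.array([0.05, 0.15, 0.40, 0.10, 0.30]) * glen).astype(int)
            bounds = g0 + np.concatenate([[0], np.cumsum(widths)])
            order = ["five_prime_UTR", "CDS", "intron", "CDS", "three_prime_UTR"]
            if strand == "-":
                order = order[::-1]
            gene_rows.append(
                (chrom, "editdev", "gene", g0 + 1, int(bounds[-1]), ".", strand, ".",
                 f"ID={gene_id}")
            )
            for fi, feat in enumerate(order):
                s0, e0 = int(bounds[fi]), int(bounds[fi + 1])
                gene_rows.append(
                    (chrom, "editdev", feat, s0 + 1, e0, ".", strand, ".",
                     f"Parent={gene_id}")
                )
                if feat == "intron":
                    junc_rows.append((chrom, s0, e0))

        sequences[chrom] = "".join(seq)

    repeats = pd.DataFrame(
        rep_rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "repeat_class"],
    )
    alu = repeats[repeats.repeat_class == "ALU"].drop(columns="repeat_class")
    alu = alu.reset_index(drop=True)

    # SNP panel: half random genomic positions, half Alu strand-frame adenosines
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = sequences[chrom]
        n_random = spec.snps_per_chrom // 2
        pos0 = rng.choice(spec.chrom_length, size=n_random, replace=False)
        for p in sorted(int(x) for x in pos0):
            snp_rows.append((chrom, p + 1, seq[p]))
        alu_c = alu[alu.chrom == chrom]
        cands = []
        for _, iv in alu_c.iterrows():
            want = "A" if iv.strand == "+" else "T"
            cands.extend(
                p for p in range(iv.start, iv.end) if seq[p] == want
            )
        if cands:
            take = min(spec.snps_per_chrom - n_random, len(cands))
            chosen = rng.choice(np.array(cands), size=take, replace=False)
            for p in sorted(int(x) for x in chosen):
                snp_rows.append((chrom, p + 1, seq[p]))

    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref"])
    snps = snps.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    genes = pd.DataFrame(
        gene_rows,
        columns=["chrom", "source", "feature", "start", "end", "score", "strand",
                 "frame", "attributes"],
    )
    junctions = pd.DataFrame(junc_rows, columns=["chrom", "start", "end"])
    return ReferenceBundle(sequences, alu, repeats, genes, snps, junctions)


def _strand_frame_adenosines(seq: str, start: int, end: int, strand: str) -> list[int]:
    """0-based positions in [start, end) whose strand-frame base is A."""
    want = "A" if strand == "+" else "T"
    return [p for p in range(start, end) if seq[p] == want]


def _candidate_sites(bundle: ReferenceBundle, repeat_class: str,
                     rng: np.random.Generator) -> list[tuple[str, int, str]]:
    out: list[tuple[str, int, str]] = []
    if repeat_class in ("ALU", "NONALU_REP"):
        ivs = bundle.repeats[bundle.repeats.repeat_class == repeat_class]
        for _, iv in ivs.iterrows():
            for p in _strand_frame_adenosines(
                bundle.sequences[iv.chrom], iv.start, iv.end, iv.strand
            ):
                out.append((iv.chrom, p, iv.strand))
    else:  # NONREP: anywhere outside planted repeats
        for chrom, seq in bundle.sequences.items():
            covered = np.zeros(len(seq), dtype=bool)
            for _, iv in bundle.repeats[bundle.repeats.chrom == chrom].iterrows():
                covered[iv.start: iv.end] = True
            n_scan = min(len(seq), 4000)
            pos = rng.choice(len(seq), size=n_scan, replace=False)
            for p in sorted(int(x) for x in pos):
                if covered[p]:
                    continue
                b = seq[p]
                if b == "A":
                    out.append((chrom, p, "+"))
                elif b == "T":
                    out.append((chrom, p, "-"))
    return out


def simulate_truth(
    bundle: ReferenceBundle,
    sites_per_class: dict[str, int],
    designs: list[SampleDesign],
    model: TrajectoryModel,
    seed: int = 0,
    diff_fraction: float = 0.0,
    diff_delta: float = 0.15,
    baseline_jitter: float = 0.0,
) -> pd.DataFrame:
    """Draw editing sites and per-sample true editing rates.

    Sites are placed on strand-frame adenosines of the requested repeat
    classes. Each sample's rate follows ``model`` evaluated at the sample's
    age plus covariate effects and Gaussian noise, clipped to [0, 1]. A
    ``diff_fraction`` of sites additionally carries a prenatal-vs-postnatal
    shift of ``diff_delta`` (added to postnatal samples). ``baseline_jitter``
    spreads per-site baselines uniformly to decorrelate sites.

    Returns a table with one row per site: metadata columns plus one rate
    column per sample_id.
    """
    rng = np.random.default_rng(seed)
    from .matrix import annotate_region  # local import: avoids a cycle at import time

    rows = []
    for cls, n in sites_per_class.items():
        cands = _candidate_sites(bundle, cls, rng)
        if n > len(cands):
            raise ConfigurationError(
                f"requested {n} {cls} sites but only {len(cands)} candidate "
                "adenosines are annotated"
            )
        idx = rng.choice(len(cands), size=n, replace=False)
        for i in sorted(int(x) for x in idx):
            chrom, p0, strand = cands[i]
            rows.append((chrom, p0 + 1, strand, cls))

    truth = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "repeat_class"])
    truth = truth.drop_duplicates(["chrom", "pos", "strand"]).reset_index(drop=True)
    truth.insert(
        0, "site_id",
        [f"{c}:{p}:{s}" for c, p, s in zip(truth.chrom, truth.pos, truth.strand)],
    )
    truth["region"] = annotate_region(truth, bundle.genes)["region"].to_numpy()

    n_sites = len(truth)
    is_diff = np.zeros(n_sites, dtype=bool)
    n_diff = int(round(diff_fraction * n_sites))
    if n_diff:
        is_diff[rng.choice(n_sites, size=n_diff, replace=False)] = True
    truth["is_differential"] = is_diff

    base_shift = rng.uniform(-baseline_jitter, baseline_jitter, size=n_sites) \
        if baseline_jitter > 0 else np.zeros(n_sites)

    for d in designs:
        mean = model.mean_value(d)
        r = mean + base_shift
        if model.noise_sd > 0:
            r = r + rng.normal(0.0, model.noise_sd, size=n_sites)
        if d.group == "postnatal":
            r = r + np.where(is_diff, diff_delta, 0.0)
        truth[d.sample_id] = np.clip(r, 0.0, 1.0)
    return truth


def uniform_alu_truth(
    bundle: ReferenceBundle, rate: float, sample_ids: list[str]
) -> pd.DataFrame:
    """Truth table giving every Alu strand-frame adenosine the same rate.

    This is the fixture behind aggregate-index recovery checks: with every
    editable position edited at ``rate``, the Alu editing index of simulated
    reads converges on ``rate``.
    """
    rows = []
    for _, iv in bundle.alu.iterrows():
        for p in _strand_frame_adenosines(
            bundle.sequences[iv.chrom], iv.start, iv.end, iv.strand
        ):
            rows.append((f"{iv.chrom}:{p + 1}:{iv.strand}", iv.chrom, p + 1, iv.strand))
    truth = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "strand"])
    truth["repeat_class"] = "ALU"
    truth["region"] = "NA"
    truth["is_differential"] = False
    for s in sample_ids:
        truth[s] = rate
    return truth


_UMI_BASES = np.array(list("ACGT"))


def simulate_reads(
    bundle: ReferenceBundle,
    truth: pd.DataFrame,
    design: SampleDesign,
    depth: float = 30.0,
    read_length: int = 100,
    error_rate: float = 0.001,
    three_prime_bias: bool = False,
    spliced_fraction: float = 0.1,
    seed: int = 0,
    barcodes: list[str] | None = None,
    umi_length: int = 10,
    base_quality: int = 37,
    mapq: int = 60,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Simulate a coordinate-sorted alignment stream realizing the truth table.

    Reads are uniform random placements (optionally 3'-biased within genes,
    emulating poly-A capture) of ``read_length`` bases; a ``spliced_fraction``
    of reads spans a gene's splice junction with an N gap in the CIGAR. At an
    edited site each overlapping read independently carries the edited base
    (G on +-strand sites, C on -: the reference-frame image of A-to-I) with
    probability equal to the sample's true rate, so read-level counts are
    binomial. Uniform substitution errors are applied at ``error_rate``.
    Single-cell and single-nucleus samples get CB/UB tags.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    rng = np.random.default_rng(seed)
    header = bundle.sam_header()
    sid = design.sample_id
    if sid not in truth.columns:
        raise ConfigurationError(f"truth table has no rate column for {sid!r}")
    tagged = design.modality in ("single_cell", "single_nucleus")
    if tagged and not barcodes:
        barcodes = [f"{sid}-1"]

    # per-chrom edited-position lookup: pos0 -> (edited_base, rate)
    edits: dict[str, dict[int, tuple[str, float]]] = {}
    for row in truth.itertuples():
        eb = "G" if row.strand == "+" else "C"
        edits.setdefault(row.chrom, {})[row.pos - 1] = (eb, getattr(row, sid))

    reads: list[pysam.AlignedSegment] = []
    for tid, (chrom, seq) in enumerate(bundle.sequences.items()):
        clen = len(seq)
        if read_length >= clen:
            raise ConfigurationError("read_length exceeds chromosome length")
        n_reads = int(round(depth * clen / read_length))
        juncs = bundle.junctions[bundle.junctions.chrom == chrom]
        genes = bundle.genes[
            (bundle.genes.chrom == chrom) & (bundle.genes.feature == "gene")
        ]
        chrom_edits = edits.get(chrom, {})

        layouts = []  # (start, blocks as [(ref_start, length), ...])
        for _ in range(n_reads):
            if len(juncs) and rng.random() < spliced_fraction:
                j = juncs.iloc[int(rng.integers(len(juncs)))]
                left = int(rng.integers(1, read_length))
                start = j.start - left
                right_end = j.end + (read_length - left)
                if start >= 0 and right_end <= clen:
                    layouts.append((start, [(start, left), (j.end, read_length - left)]))
                    continue
            if three_prime_bias and len(genes):
                g = genes.iloc[int(rng.integers(len(genes)))]
                g0, g1 = g.start - 1, g.end
                u = rng.beta(3.0, 1.0)
                if g.strand == "-":
                    u = 1.0 - u
                start = int(g0 + u * max(1, (g1 - g0 - read_length)))
                start = min(max(start, 0), clen - read_length)
            else:
                start = int(rng.integers(0, clen - read_length + 1))
            layouts.append((start, [(start, read_length)]))

        layouts.sort(key=lambda t: t[0])
        for ri, (start, blocks) in enumerate(layouts):
            parts = []
            for bs, bl in blocks:
                block = np.array(list(seq[bs: bs + bl]))
                for off in range(bl):
                    hit = chrom_edits.get(bs + off)
                    if hit is not None and rng.random() < hit[1]:
                        block[off] = hit[0]
                parts.append(block)
            bases = np.concatenate(parts)
            if error_rate > 0:
                errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                for e in errs:
                    alts = [b for b in "ACGT" if b != bases[e]]
                    bases[e] = alts[int(rng.integers(3))]

            a = pysam.AlignedSegment(header)
            a.query_name = f"{sid}:{chrom}:r{ri}"
            a.query_sequence = "".join(bases)
            a.flag = 16 if rng.random() < 0.5 else 0
            a.reference_id = tid
            a.reference_start = start
            a.mapping_quality = mapq
            if len(blocks) == 1:
                a.cigartuples = [(0, read_length)]
            else:
                gap = blocks[1][0] - (blocks[0][0] + blocks[0][1])
                a.cigartuples = [(0, blocks[0][1]), (3, gap), (0, blocks[1][1])]
            a.query_qualities = pysam.qualitystring_to_array(
                chr(base_quality + 33) * read_length
            )
            if tagged:
                a.set_tag("CB", str(barcodes[int(rng.integers(len(barcodes)))]))
                a.set_tag("UB", "".join(rng.choice(_UMI_BASES, size=umi_length)))
            reads.append(a)
    return header, reads


def simulate_expression(
    designs: list[SampleDesign],
    coupling: dict[str, TrajectoryModel],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample expression for named genes following given trajectories.

    Returns genes x samples. Values are trajectory means plus Gaussian noise;
    they are not clipped (expression is on an arbitrary normalized scale).
    """
    if not designs:
        raise ConfigurationError("no sample designs given")
    rng = np.random.default_rng(seed)
    out = {}
    for gene, model in coupling.items():
        vals = [model.mean_value(d) for d in designs]
        if model.noise_sd > 0:
            vals = np.asarray(vals) + rng.normal(0, model.noise_sd, size=len(designs))
        out[gene] = np.asarray(vals, dtype=float)
    return pd.DataFrame(out, index=[d.sample_id for d in designs]).T


def matrix_from_truth(truth: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Extract the sites x samples rate matrix from a truth table."""
    return truth.set_index("site_id")[list(sample_ids)].astype(float)


def mar_mask(
    levels: pd.DataFrame,
    designs: list[SampleDesign],
    base_rate: float = 0.07,
    age_slope: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Missing-at-random masking driven by an observed covariate (age).

    Each entry of ``levels`` (sites x samples) is set missing with a
    probability that depends on the sample's age (logit-linear), never on the
    value itself — the MAR mechanism multiple imputation assumes.
    """
    rng = np.random.default_rng(seed)
    ages = np.array([age_in_years(d.age_value, d.age_unit) for d in designs])
    z = (ages - ages.mean()) / (ages.std() or 1.0)
    logit0 = np.log(base_rate / (1 - base_rate))
    p_miss = 1.0 / (1.0 + np.exp(-(logit0 + age_slope * z)))
    out = levels.copy()
    for j, d in enumerate(designs):
        mask = rng.random(len(out)) < p_miss[j]
        out.loc[mask, d.sample_id] = np.nan
    if out.isna().all(axis=1).any():
        warnings.warn("mar_mask produced fully-missing sites", stacklevel=2)
    return out
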