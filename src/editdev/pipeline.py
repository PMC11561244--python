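"""End-to-end orchestration: simulate -> quantify -> pseudobulk -> matrix ->
differential -> integration, with every artifact written as a text table.

The default configuration is a deliberately small but complete study: a
two-chromosome genome with stranded Alu repeats, twelve bulk samples spanning
early gestation through senescence, one barcoded single-cell sample, editing
trajectories that rise postnatally with ADAR-coupled covariate effects, and
a knockout fitness table. One pipeline seed is split deterministically into
per-stage streams.
"""

from __future__ import annotations

import copy
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .differential import (
    DEFAULT_BINS,
    ImputationConfig,
    assign_bins,
    bin_contrast,
    differential_editing,
)
from .integration import (
    correlate_delta_expression,
    correlate_score_aei,
    fitness_fractions,
    score_gene_set,
    variance_explained,
)
from .matrix import HarmonizeConfig, annotate_region, build_matrix, harmonize
from .pseudobulk import CellStateMap, DedupConfig, dedup_umi, split_by_state
from .quant import QuantConfig, call_sites, compute_aei, pileup, stratify_by_repeat
from .synthetic import (
    SampleDesign,
    SyntheticGenomeSpec,
    TrajectoryModel,
    generate_reference,
    matrix_from_truth,
    simulate_expression,
    simulate_reads,
    simulate_truth,
)

__all__ = ["default_config", "load_config", "run_pipeline", "OUTPUT_FILES"]

# every file a full run is expected to emit
OUTPUT_FILES = [
    "reference.fa", "alu.bed", "repeats.bed", "genes.gff3", "snps.tsv",
    "junctions.tsv", "truth.tsv", "design.tsv", "expression.tsv",
    "aei.tsv", "matrix.tsv", "site_annotation.tsv", "filter_report.tsv",
    "differential.tsv", "contrasts.tsv", "correlations.tsv",
    "dedup_report.tsv", "fitness.tsv", "fitness_contrasts.tsv",
    "run_log.yaml",
]


def default_config() -> dict:
    return {
        "genome": {
            "n_chroms": 2, "chrom_length": 40_000, "n_alus": 40,
            "alu_length": 300, "alu_strand_fraction_plus": 0.6,
            "gc_content": 0.42,
        },
        "samples": {
            "prenatal_wpc": [4, 5, 7, 8, 9, 11, 13, 16, 18, 20],
            "postnatal_years": [0.5, 2, 5, 10, 15, 19, 28, 35, 45, 60],
            "single_cell": {
                "age_years": 30,
                "barcodes_per_state": 2,
                "states": ["neuron", "muscle", "hepatocyte"],
            },
        },
        "truth": {
            "sites_per_class": {"ALU": 80, "NONALU_REP": 15, "NONREP": 15},
            "baseline": 0.15, "amplitude": 0.15, "shape": "logistic_increase",
            "noise_sd": 0.02, "adar_slope": 0.03,
            "diff_fraction": 0.15, "diff_delta": 0.15, "baseline_jitter": 0.05,
        },
        "reads": {
            "depth": 30.0, "read_length": 100, "error_rate": 0.001,
            "spliced_fraction": 0.1, "single_cell_depth": 10.0,
        },
        "quant": {},        # QuantConfig defaults
        "harmonize": {},    # HarmonizeConfig defaults
        "differential": {"m": 5, "max_iter": 10, "moderation": True,
                         "pooling": "average"},
        "integration": {
            "gene_set": {"name": "viral_response",
                         "members": ["IFI6", "ISG15", "MX1"]},
        },
        "fitness": {
            "conditions": ["AAVS1_KO", "ADAR_KO", "ADARB1_KO", "ADARB2_KO"],
            "reference": "AAVS1_KO",
            "strata": ["ectoderm", "mesoderm", "endoderm"],
            "replicates": 4,
            "base_count": 1000,
            # relative fitness of ADAR-KO cells per germ layer
            "adar_ko_fitness": {"ectoderm": 0.55, "mesoderm": 0.4, "endoderm": 0.8},
        },
    }


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}

    def merge(base: dict, over: dict) -> dict:
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v
        return base

    return merge(cfg, user)


def _build_designs(cfg: dict) -> tuple[list[SampleDesign], SampleDesign, dict[str, str]]:
    sexes = ["F", "M"]
    bulk: list[SampleDesign] = []
    for i, wpc in enumerate(cfg["samples"]["prenatal_wpc"]):
        bulk.append(SampleDesign(f"pre_{i}", float(wpc), "wpc", sexes[i % 2]))
    for i, yr in enumerate(cfg["samples"]["postnatal_years"]):
        bulk.append(SampleDesign(f"post_{i}", float(yr), "years", sexes[(i + 1) % 2]))
    sc_cfg = cfg["samples"]["single_cell"]
    sc = SampleDesign("sc_0", float(sc_cfg["age_years"]), "years", "F",
                      modality="single_cell")
    barcode_map = {}
    for state in sc_cfg["states"]:
        for b in range(sc_cfg["barcodes_per_state"]):
            barcode_map[f"{state}-{b}"] = state
    return bulk, sc, barcode_map


def _gene_of_site(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Map each site to the ID of the gene body containing it (else NA)."""
    bodies = genes[genes.feature == "gene"]
    out = pd.Series(pd.NA, index=sites.index, dtype=object)
    for g in bodies.itertuples():
        gid = re.search(r"ID=([^;]+)", g.attributes).group(1)
        hit = (sites["chrom"] == g.chrom) & (sites["pos"] >= g.start) & (sites["pos"] <= g.end)
        out[hit] = gid
    return out


def _simulate_fitness_counts(cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for stratum in cfg["strata"]:
        for rep in range(cfg["replicates"]):
            for cond in cfg["conditions"]:
                lam = cfg["base_count"]
                if cond == "ADAR_KO":
                    lam *= cfg["adar_ko_fitness"][stratum]
                rows.append((stratum, cond, f"rep{rep}", int(rng.poisson(lam))))
    return pd.DataFrame(rows, columns=["stratum", "condition", "replicate", "count"])


def run_pipeline(config: dict | None = None, outdir: str | Path = "editdev_out",
                 seed: int = 0) -> dict:
    """Run the full synthetic study and write all artifacts under ``outdir``.

    Returns a summary dict (also logged to run_log.yaml) with the headline
    quantities: per-sample AEI, significant-site count, staged contrasts, and
    the integration correlations.
    """
    cfg = copy.deepcopy(config) if config else default_config()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = {name: s for name, s in zip(
        ["genome", "expression", "truth", "reads", "sc_reads", "diff", "fitness"],
        ss.spawn(7),
    )}
    def seed_of(name: str) -> int:
        return int(seeds[name].generate_state(1)[0] % (2 ** 31))

    # --- reference -----------------------------------------------------
    spec = SyntheticGenomeSpec(seed=seed_of("genome"), **cfg["genome"])
    bundle = generate_reference(spec)
    io.write_fasta(bundle.sequences, out / "reference.fa")
    io.write_bed(bundle.alu, out / "alu.bed")
    io.write_bed(bundle.repeats, out / "repeats.bed")
    io.write_gff(bundle.genes, out / "genes.gff3")
    io.write_table(bundle.snps, out / "snps.tsv")
    io.write_table(bundle.junctions, out / "junctions.tsv")

    # --- samples and covariate-coupled expression ----------------------
    bulk, sc, barcode_map = _build_designs(cfg)
    designs = bulk + [sc]
    gene_set = cfg["integration"]["gene_set"]
    coupling = {
        "ADAR": TrajectoryModel(1.0, -0.3, "logistic_increase", 0.1),
        "ADARB1": TrajectoryModel(0.5, 0.6, "logistic_increase", 0.1),
        "ADARB2": TrajectoryModel(0.2, 0.3, "logistic_increase", 0.1),
    }
    for i, g in enumerate(gene_set["members"]):
        coupling[g] = TrajectoryModel(0.5, 0.4 * (-1) ** i, "logistic_increase", 0.1)
    # expression for the gene-model genes themselves, so site-level editing
    # changes can be paired with their host gene's expression fold change
    body_ids = [
        re.search(r"ID=([^;]+)", a).group(1)
        for a in bundle.genes.loc[bundle.genes.feature == "gene", "attributes"]
    ]
    for k, gid in enumerate(body_ids):
        amp = 0.5 * (-1) ** k * (1 + k % 3) / 3
        coupling[gid] = TrajectoryModel(1.0, amp, "logistic_increase", 0.15)
    expression = simulate_expression(designs, coupling, seed_of("expression"))
    for d in designs:
        d.adar_expr = float(expression.loc["ADAR", d.sample_id])
        d.adarb1_expr = float(expression.loc["ADARB1", d.sample_id])
    io.write_table(expression, out / "expression.tsv", index=True)
    design_df = pd.DataFrame(
        [(d.sample_id, d.age_value, d.age_unit, d.sex, d.group, d.modality,
          d.adar_expr, d.adarb1_expr) for d in designs],
        columns=["sample_id", "age_value", "age_unit", "sex", "group",
                 "modality", "adar_expr", "adarb1_expr"],
    )
    io.write_table(design_df, out / "design.tsv")

    # --- truth ----------------------------------------------------------
    t = cfg["truth"]
    model = TrajectoryModel(t["baseline"], t["amplitude"], t["shape"],
                            t["noise_sd"], {"adar_expr": t["adar_slope"]})
    truth = simulate_truth(
        bundle, t["sites_per_class"], designs, model, seed_of("truth"),
        diff_fraction=t["diff_fraction"], diff_delta=t["diff_delta"],
        baseline_jitter=t["baseline_jitter"],
    )
    io.write_table(truth, out / "truth.tsv")
    catalog = truth[["site_id", "chrom", "pos", "strand"]]

    # --- bulk reads, AEI, site calls ------------------------------------
    qc = QuantConfig(**cfg["quant"])
    rd = cfg["reads"]
    read_seeds = seeds["reads"].spawn(len(bulk))
    aei_rows = []
    calls_by_sample: dict[str, pd.DataFrame] = {}
    for d, rs in zip(bulk, read_seeds):
        _, reads = simulate_reads(
            bundle, truth, d, depth=rd["depth"], read_length=rd["read_length"],
            error_rate=rd["error_rate"], spliced_fraction=rd["spliced_fraction"],
            seed=int(rs.generate_state(1)[0] % (2 ** 31)),
        )
        counts = pileup(reads, bundle.sequences, qc)
        aei = compute_aei(None, bundle.alu, bundle.sequences, bundle.snps, qc,
                          sample_id=d.sample_id, counts=counts)
        aei_rows.append((d.sample_id, aei.numerator, aei.denominator, aei.aei))
        calls = call_sites(counts, catalog, bundle.snps, bundle.sequences, qc)
        calls_by_sample[d.sample_id] = stratify_by_repeat(calls, bundle.repeats)
    aei_table = pd.DataFrame(aei_rows,
                             columns=["sample_id", "numerator", "denominator", "aei"])
    io.write_table(aei_table, out / "aei.tsv")

    # --- single-cell pseudobulk -----------------------------------------
    header, sc_reads = simulate_reads(
        bundle, truth, sc, depth=rd["single_cell_depth"],
        read_length=rd["read_length"], error_rate=rd["error_rate"],
        three_prime_bias=True, spliced_fraction=rd["spliced_fraction"],
        seed=seed_of("sc_reads"), barcodes=list(barcode_map),
    )
    io.write_sam(header, sc_reads, out / "sc_reads.sam")
    streams, _ = split_by_state(sc_reads, CellStateMap(barcode_map))
    dedup_rows = []
    state_aei = {}
    for state, stream in sorted(streams.items()):
        kept = dedup_umi(stream, DedupConfig("exact"))
        dedup_rows.append((state, len(stream), len(kept)))
        counts = pileup(kept, bundle.sequences, qc)
        state_aei[state] = compute_aei(None, bundle.alu, bundle.sequences,
                                       bundle.snps, qc, sample_id=state,
                                       counts=counts).aei
        io.write_sam(header, kept, out / f"pseudobulk_{state}.sam")
    io.write_table(
        pd.DataFrame(dedup_rows, columns=["state", "reads_in", "reads_out"]),
        out / "dedup_report.tsv",
    )

    # --- editing matrix --------------------------------------------------
    mat = build_matrix(calls_by_sample)
    harmonized, report = harmonize(mat, HarmonizeConfig(**cfg["harmonize"]))
    io.write_matrix(harmonized.levels, out / "matrix.tsv")
    io.write_table(report, out / "filter_report.tsv")
    annot = annotate_region(harmonized.sites.reset_index(), bundle.genes)
    annot = stratify_by_repeat(annot, bundle.repeats).set_index("site_id")
    io.write_table(annot.reset_index(), out / "site_annotation.tsv")

    # --- differential editing --------------------------------------------
    dc = cfg["differential"]
    bulk_df = design_df[design_df.modality == "bulk"].set_index("sample_id")
    diff = differential_editing(
        harmonized.levels, bulk_df.loc[harmonized.levels.columns],
        ImputationConfig(m=dc["m"], max_iter=dc["max_iter"], seed=seed_of("diff")),
        moderation=dc["moderation"], pooling=dc["pooling"],
    )
    diff = diff.join(annot[["region", "repeat_class"]])
    io.write_table(diff.reset_index(), out / "differential.tsv")

    # --- staged contrasts -------------------------------------------------
    bins = assign_bins(bulk, DEFAULT_BINS)
    aei_by_sample = aei_table.set_index("sample_id")["aei"]
    values_by_bin = {
        b: aei_by_sample[bins[bins == b].index].to_numpy()
        for b in DEFAULT_BINS.bins
        if (bins == b).sum() >= 2
    }
    contrast_rows = []
    labels = [b for b in DEFAULT_BINS.bins if b in values_by_bin]
    for a, b in zip(labels, labels[1:]):
        r = bin_contrast(values_by_bin, (a, b))
        contrast_rows.append((r.contrast, r.n1, r.n2, r.t, r.p, r.d))
    contrasts = pd.DataFrame(
        contrast_rows, columns=["contrast", "n1", "n2", "t", "p", "d"])
    io.write_table(contrasts, out / "contrasts.tsv")

    # --- integration -------------------------------------------------------
    gene_of = _gene_of_site(harmonized.sites, bundle.genes)
    post_ids = [d.sample_id for d in bulk if d.group == "postnatal"]
    pre_ids = [d.sample_id for d in bulk if d.group == "prenatal"]
    logfc = expression[post_ids].mean(axis=1) - expression[pre_ids].mean(axis=1)
    corr_rows = []
    sig = diff[diff.fdr < 0.05]
    if gene_of.notna().sum() >= 3 and len(sig) >= 3:
        try:
            r = correlate_delta_expression(diff, logfc, gene_of)
            corr_rows.append(("delta_vs_logfc", r.r, r.r_squared, r.n, r.p))
        except ValueError:
            pass
    bulk_aei = aei_by_sample[[d.sample_id for d in bulk]]
    for gene in ("ADAR", "ADARB1"):
        r = variance_explained(bulk_aei, expression.loc[gene, bulk_aei.index])
        corr_rows.append((f"aei_vs_{gene}", r.r, r.r_squared, r.n, r.p))
    score = score_gene_set(expression[bulk_aei.index], gene_set["members"],
                           gene_set["name"])
    r = correlate_score_aei(score, bulk_aei)
    corr_rows.append((f"aei_vs_{gene_set['name']}_score", r.r, r.r_squared, r.n, r.p))
    correlations = pd.DataFrame(
        corr_rows, columns=["pair", "r", "r_squared", "n", "p"])
    io.write_table(correlations, out / "correlations.tsv")

    # --- fitness ------------------------------------------------------------
    fit_counts = _simulate_fitness_counts(
        cfg["fitness"], np.random.default_rng(seed_of("fitness")))
    frac, fit_contrasts = fitness_fractions(fit_counts, cfg["fitness"]["reference"])
    io.write_table(frac, out / "fitness.tsv")
    io.write_table(fit_contrasts, out / "fitness_contrasts.tsv")

    summary = {
        "seed": seed,
        "n_sites_truth": int(len(truth)),
        "n_sites_harmonized": int(harmonized.shape[0]),
        "n_samples_harmonized": int(harmonized.shape[1]),
        "n_significant": int((diff.fdr < 0.05).sum()),
        "aei": {k: float(v) for k, v in aei_by_sample.items()},
        "state_aei": {k: float(v) for k, v in state_aei.items()},
        "contrasts": contrasts.to_dict("records"),
        "correlations": correlations.to_dict("records"),
        "resolved_config": cfg,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return summary
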