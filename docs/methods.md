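# Methods

## Scope and model

A-to-I editing is measured from aligned RNA-seq reads as A→G mismatch
evidence against the genome, in the strand frame of each annotated site or
repeat: a plus-strand adenosine edits to G in read space, a minus-strand
adenosine appears as a reference T editing to C. The package quantifies
editing at two resolutions — per cataloged site and aggregated over Alu
repeats — and models developmental change in both.

### Base counting and masking

`quant.pileup` re-creates an mpileup-style traversal with explicit masking.
A read base contributes to the count at its reference position iff

1. the position lies in an aligned match block (CIGAR M/=/X; deleted and
   spliced-over positions never count);
2. its 1-based offset from *either* read terminus exceeds `end_mask_bp`
   (default 5; "within 5 bp" is read inclusively, so offsets 1–5 are
   masked and offset 6 is kept);
3. its distance in *read coordinates* to the nearest splice-gap (CIGAR N)
   boundary exceeds `splice_mask_bp` (default 5, same inclusive rule —
   measured in read rather than reference coordinates, since the masked
   artifact is misalignment at the read's own junction);
4. base quality ≥ `min_base_quality` (default Q20) and the read's MAPQ ≥
   `min_mapq` (default 20). The source pipeline states no quality
   thresholds; these defaults are conventional and configurable.

### Site calls

At a cataloged site, coverage counts only strand-frame A and G read bases;
C/T bases at a plus-strand site are treated as errors or variants and enter
neither numerator nor denominator, which keeps
`level = edited / (edited + unedited)` interpretable. Status is SNP_MASKED
(site in the exclusion panel), NOT_DETECTED (zero coverage), LOW_COVERAGE
(< 5 reads), LOW_EDITED (< 3 edited reads), or CALLED. Only CALLED sites
carry a level. A catalog position whose reference base is not a
strand-frame adenosine is an input error, not a silent skip.

### Alu Editing Index

For every position inside a stranded Alu interval whose strand-frame
reference base is A and which is not a panel SNP, the numerator accumulates
strand-frame G bases and the denominator strand-frame A+G bases from the
same masked pileup; the index is their ratio. Overlapping antisense
intervals are evaluated once per interval, each in its own strand frame, so
a genomic position may legitimately contribute in two frames. A zero
denominator yields a flagged undefined index rather than an exception.

### Pseudobulk and UMI deduplication

Barcoded reads are partitioned by a barcode → state map (cell type, batch,
knockout condition); untagged or unmapped barcodes go to a sink stream with
a warning count. Duplicates are collapsed within (barcode, alignment start,
strand) groups — start rather than fragment end, matching single-end
3'-capture data — either per distinct UMI (`exact`, the pipeline default:
deterministic and oracle-checkable) or with the directional network rule
(`directional`): UMIs ordered by count, a cluster head absorbs a Hamming-1
neighbour when `count(head) ≥ 2·count(neighbour) − 1`, transitively,
breadth-first. The kept read per surviving UMI is the one with the highest
mean base quality, ties broken by smallest read name. Exact mode is
idempotent; directional mode deliberately is not re-runnable (after
collapse all counts are 1 and 1 ≥ 2·1−1 merges surviving neighbours),
which mirrors the published scheme.

### Matrix harmonization

Per-sample call tables are assembled into a sites × samples matrix (only
CALLED entries carry values). Filters apply in a fixed order: samples with
more than `max_sample_missing` (20%) missing entries are dropped first,
site statistics are recomputed on the retained samples, then sites below
`min_detection` (60%) or `min_mean_editing` (5%, over non-missing entries)
are dropped. Sample exclusion first makes detection rates reflect the
retained cohort; the filter report lists every dropped item with its
reason, and dropped + kept reconstitutes the input on both axes.

Region annotation assigns each site one label with priority
CDS > 3'UTR > 5'UTR > intron > intergenic (recoding sites are the most
consequential, hence CDS first); repeat stratification uses
ALU > non-Alu-repeat > non-repeat on overlap.

### Imputation

Missing levels are completed by chained-equation predictive mean matching:
per incomplete site, an OLS regression of its observed values on the sample
covariates (group, sex, ADAR, ADARB1) plus the current values of its k = 10
most-correlated peer sites (complete-case correlation, computed once);
each missing entry is replaced by the observed value of one of the
`donors = 5` samples with the closest predicted mean, drawn uniformly.
Defaults are m = 5 chains and 30 sweeps; chains run from deterministically
split seeds. Imputed values therefore always belong to the site's observed
value set, and sites with fewer observed values than donors shrink the pool
with a warning. Full site × site chained equations would be quadratic in
sites; the covariates-plus-top-k predictor set is the tractable reduction.

Pooling of the m completions defaults to the element-wise mean consensus
matrix (`average`); `rubin` instead fits per completion and pools the group
coefficient by Rubin's rules (total variance = within + (1+1/m)·between,
with the standard (m−1)(1+W/((1+1/m)B))² degrees of freedom). The source
procedure does not state its pooling; both are provided.

### Differential model and moderation

Each site is fit by OLS on `[1, group, sex, ADAR, ADARB1]` (group:
postnatal = 1). With moderation on (the default for matrix-wide testing),
residual variances are shrunk toward an empirical prior:
the prior degrees of freedom d₀ and scale s₀² are moment-matched on the
distribution of log s²ᵍ via digamma/trigamma equations (trigamma inverse by
Newton iteration), then `s̃²ᵍ = (d₀s₀² + dᵍs²ᵍ)/(d₀ + dᵍ)` and the group
t-statistic uses d₀ + dᵍ degrees of freedom. When the log-variance
dispersion does not exceed its sampling noise, d₀ = ∞ and every site shares
s₀², taken as the geometric mean of the observed variances so that
identical variances are an exact fixed point. Moderation off reproduces
plain OLS t exactly. The implementation agrees with the reference
empirical-Bayes shrinkage to 10 significant digits on dispersed variances
(frozen oracle in the test suite).

`delta` is always reported from the *observed* (pre-imputation) group
means — the plain "postnatal minus prenatal editing difference" — while
`beta_group` is the covariate-adjusted coefficient; the two are
deliberately separate columns. FDR is step-up Benjamini–Hochberg; sites
with FDR < 0.05 are significant under the default policy.

### Staging and effect sizes

Ages bin into early gestation (4–10 wpc), late gestation (11–20 wpc),
newborn–teenager (0–20 years) and adult–senior (25–63 years); ages in the
gaps (e.g. 21–24 years) are excluded with a warning. An optional early
sub-split (4–7 and 8–11 wpc) exists as its own scheme and deliberately
meets the late-gestation boundary at 11 wpc, as printed in its source
analysis. Contrasts use the equal-variance two-tailed Student's t (Welch by
flag) and pooled-SD Cohen's d, oriented later-minus-earlier; two constant
identical groups give d = 0 and p = 1, while constant groups with unequal
means leave d flagged undefined. Multi-stratum effects pool d by total
sample size. Three or more groups go through one-way ANOVA with Tukey HSD.

### Integration layer

Differential sites are averaged per gene before correlating delta editing
with expression log-fold change (one pair per gene). Variance explained is
the r² of a simple regression of AEI on one gene's expression. Gene-set
scores are the mean per-gene z-score across samples — a transparent,
affine-invariant substitute for kernel-based set scoring; the quantity
used downstream (Pearson correlation of a set-level summary with AEI) is
unchanged, and parity with kernel methods is explicitly out of scope.
Fitness tables convert per-replicate cell counts to within-replicate
fractions (absorbing depth differences) before contrasting each knockout
against the reference condition across replicates.

## The synthetic generator

The generator emulates the structure of the real inputs, not their content:
chromosomes with planted non-overlapping 300-bp repeats that are
adenosine-rich in their strand frame (synthetic A-rich sequence, not an Alu
consensus — the index only needs editable stranded intervals); a gene model
of 5'UTR–CDS–intron–CDS–3'UTR with the 3'UTR widest; a SNP panel half of
which sits on Alu adenosines so masking is exercised where it matters;
per-site editing trajectories (constant, logistic postnatal increase, or
early-gestation drop with postnatal recovery) plus covariate coupling to
simulated ADAR/ADARB1 expression; binomial read-level editing; uniform
substitution sequencing errors (no indel errors — the pipeline considers
substitutions only); spliced reads across the gene model's junctions;
optional 3' positional bias within genes; and CB/UB tags for single-cell
and single-nucleus modalities, which differ only by parameters (their
editing rates are treated as one generator, reflecting their strong
empirical concordance). MAR masking makes missingness depend on observed
age, never on the missing value itself. Everything is deterministic given a
seed; BED intervals are 0-based half-open, site tables and SAM 1-based.

What passing tests therefore show: the *operations* are correct — masks,
thresholds, index arithmetic, dedup rules, filters, imputation and model
algebra, error control. What they cannot show: robustness to real-data
pathologies the generator omits — PCR and mappability bias, indels,
hyper-edited reads, strand-ambiguous libraries, isoform-aware annotation,
batch structure beyond a label.

## Problem sizes and defaults

The default end-to-end study uses a 2 × 40 kb genome with 40 Alu intervals,
10 prenatal + 10 postnatal bulk samples at 30× coverage, and one
single-cell sample at 10×, chosen so the harmonized matrix lands under the
~7% average missingness the procedure expects and a 0.15 editing delta at
15% of sites is detectable while the whole run stays desk-sized. The
calibration simulations use 2,000 sites × 20 samples × 20 replicates
(null) and 10 MAR replicates of 30 correlated sites (imputation
benchmark). Imputation sweeps are reduced from 30 to 10 in the pipeline
default; sweeps beyond ~10 do not change the consensus matrix appreciably
at these sizes.

## Known limitations

- At the default desk-scale sample size (10 per group) the matrix-wide
  moderated test is marginally powered for a 0.15 delta under read-level
  noise and ADAR-coupled covariate collinearity: the number of FDR < 0.05
  discoveries varies between 0 and ~10 across seeds. The calibration
  simulations (matrix-level, 2,000 sites) are the stable measure of error
  control and recovery; the read-level pipeline's discovery count is a
  demonstration, not a benchmark.
- The 3'-bias model is positional within gene bodies, not a transcript- or
  capture-chemistry model.
- Gene-set scoring is mean-z, not a kernel method; results are comparable
  in rank terms only.
- The AEI is computed per annotated interval; reads are not reassigned
  between overlapping sense/antisense repeats.
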