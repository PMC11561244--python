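"""Imputation, covariate-adjusted differential editing, and staged contrasts.

Missing editing levels are completed by chained-equation predictive mean
matching (PMM): each incomplete site is regressed on sample covariates plus
its most-correlated peer sites, and every missing entry is replaced by the
observed value of a donor whose model prediction is closest. Completed
matrices feed per-site linear models (editing ~ group + sex + ADAR + ADARB1)
with optional empirical-Bayes variance moderation, Benjamini-Hochberg FDR,
and developmental-stage contrasts summarized by Student's t and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .synthetic import SampleDesign, age_in_years

__all__ = [
    "ImputationConfig",
    "ModerationPrior",
    "DevBinScheme",
    "EffectSizeResult",
    "DEFAULT_BINS",
    "EARLY_SPLIT_BINS",
    "make_design_matrix",
    "impute_pmm",
    "consensus",
    "fit_differential",
    "differential_editing",
    "bh_adjust",
    "assign_bins",
    "bin_contrast",
    "pooled_effect",
    "anova_tukey",
]


# ---------------------------------------------------------------------------
# design handling

def make_design_matrix(designs: list[SampleDesign] | pd.DataFrame) -> pd.DataFrame:
    """Numeric design: intercept, group (postnatal=1), sex (M=1), ADAR, ADARB1."""
    if isinstance(designs, pd.DataFrame):
        df = designs.copy()
    else:
        df = pd.DataFrame(
            {
                "sample_id": [d.sample_id for d in designs],
                "group": [d.group for d in designs],
                "sex": [d.sex for d in designs],
                "adar_expr": [d.adar_expr for d in designs],
                "adarb1_expr": [d.adarb1_expr for d in designs],
            }
        ).set_index("sample_id")
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    g = df["group"]
    X["group"] = g.map({"prenatal": 0.0, "postnatal": 1.0}) if g.dtype == object \
        else g.astype(float)
    s = df["sex"]
    X["sex"] = s.map({"F": 0.0, "M": 1.0}) if s.dtype == object else s.astype(float)
    X["adar_expr"] = df["adar_expr"].astype(float)
    X["adarb1_expr"] = df["adarb1_expr"].astype(float)
    if X.isna().any().any():
        raise ValueError("design contains unmapped or missing covariate values")
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the offending columns via the QR diagonal
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.nonzero(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad or list(X.columns)}")


# ---------------------------------------------------------------------------
# multiple imputation by chained equations with predictive mean matching

@dataclass
class ImputationConfig:
    """PMM settings: m chains, sweeps per chain, donor-pool size, peer sites."""

    m: int = 5
    max_iter: int = 30
    donors: int = 5
    n_peer_sites: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _peer_sites(levels: pd.DataFrame, k: int) -> dict[str, list[int]]:
    """Top-k most correlated peer sites per incomplete site (complete-case r)."""
    if k <= 0 or levels.shape[0] < 2:
        return {sid: [] for sid in levels.index}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pairwise corr over sparse overlap
        corr = levels.T.corr(min_periods=3).abs().to_numpy()
    np.fill_diagonal(corr, -1.0)
    corr = np.nan_to_num(corr, nan=-1.0)
    peers = {}
    for i, sid in enumerate(levels.index):
        order = np.argsort(-corr[i])
        peers[sid] = [int(j) for j in order[:k] if corr[i, j] > 0]
    return peers


def impute_pmm(
    levels: pd.DataFrame,
    designs: list[SampleDesign] | pd.DataFrame | None = None,
    config: ImputationConfig | None = None,
) -> list[pd.DataFrame]:
    """Multiple imputation of a sites x samples matrix by chained PMM.

    Per chain: missing entries start as random draws from each site's
    observed values; then for ``max_iter`` sweeps every incomplete site is
    regressed (OLS) on the sample covariates plus the current values of its
    ``n_peer_sites`` most correlated peers, and each missing entry is
    replaced by the observed value of one of the ``donors`` samples with the
    closest predicted mean, drawn uniformly. Imputed values therefore always
    belong to the site's observed value set. ``m`` independent chains are
    run from split seeds and returned as ``m`` completed matrices.
    """
    config = config or ImputationConfig()
    config.validate()
    miss = levels.isna()
    if miss.all(axis=1).any():
        sid = levels.index[miss.all(axis=1)][0]
        raise ValueError(f"site {sid!r} has no observed values; filter before imputing")
    if not miss.any().any():
        return [levels.copy() for _ in range(config.m)]

    if designs is not None:
        Z = make_design_matrix(designs).loc[levels.columns].to_numpy()
    else:
        Z = np.ones((levels.shape[1], 1))
    peers = _peer_sites(levels, config.n_peer_sites)
    obs_mask = (~miss).to_numpy()
    y_all = levels.to_numpy(dtype=float)
    incomplete = np.nonzero(miss.any(axis=1).to_numpy())[0]

    seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    completed = []
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        filled = y_all.copy()
        for i in incomplete:
            obs = y_all[i, obs_mask[i]]
            filled[i, ~obs_mask[i]] = rng.choice(obs, size=(~obs_mask[i]).sum())
        for _ in range(config.max_iter):
            for i in incomplete:
                oi = obs_mask[i]
                pcols = peers[levels.index[i]]
                X = np.column_stack([Z] + [filled[j] for j in pcols])
                y_obs = y_all[i, oi]
                donors = min(config.donors, oi.sum())
                if donors < config.donors:
                    warnings.warn(
                        f"site {levels.index[i]!r}: donor pool shrunk to {donors}",
                        stacklevel=2,
                    )
                beta, *_ = np.linalg.lstsq(X[oi], y_obs, rcond=None)
                pred = X @ beta
                pred_obs = pred[oi]
                for j in np.nonzero(~oi)[0]:
                    d = np.abs(pred_obs - pred[j])
                    pool = np.argsort(d, kind="stable")[:donors]
                    filled[i, j] = y_obs[pool[int(rng.integers(donors))]]
        completed.append(pd.DataFrame(filled, index=levels.index, columns=levels.columns))
    return completed


def consensus(completed: list[pd.DataFrame], mode: str = "average"):
    """Pool completed matrices: element-wise mean, or defer to the fit stage.

    ``average`` returns a single consensus matrix; ``rubin`` returns the list
    unchanged so that :func:`differential_editing` can fit per imputation and
    pool coefficients by Rubin's rules.
    """
    if not completed:
        raise ValueError("no completed matrices")
    shapes = {m.shape for m in completed}
    if len(shapes) != 1:
        raise ValueError(f"completed matrices disagree in shape: {shapes}")
    if mode == "average":
        return sum(m for m in completed) / len(completed)
    if mode == "rubin":
        return completed
    raise ValueError(f"unknown consensus mode {mode!r}")


# ---------------------------------------------------------------------------
# moderated per-site linear models

@dataclass
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0_sq scale."""

    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Moment-match a scaled inverse-chi-square prior to the observed
    log residual variances (digamma/trigamma equations).

    With z = log(s2), E[z] = log(s0_sq) + digamma(df/2) - log(df/2)
    + digamma-type terms in d0; the excess variance of z over
    trigamma(df/2) identifies d0. Non-positive excess means the variances
    are no more dispersed than sampling noise alone: d0 = inf and every
    site shares s0_sq.
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    # zero excess dispersion: shrink fully to the geometric mean of the
    # observed variances, so identical s2 is an exact fixed point
    if len(s2) < 2:
        return ModerationPrior(np.inf, float(np.exp(np.mean(z))))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return ModerationPrior(np.inf, float(np.exp(np.mean(z))))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return ModerationPrior(float(d0), float(s0))


def squeeze_variances(s2: np.ndarray, df: float,
                      prior: ModerationPrior) -> np.ndarray:
    """Shrink per-site variances toward the prior: (d0*s0 + df*s2)/(d0 + df)."""
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)


def _ols_all_sites(Y: np.ndarray, X: np.ndarray):
    """Vectorized OLS of every site (rows of Y) on the shared design X."""
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T          # sites x p coefficients
    resid = Y - B @ X.T
    df = X.shape[0] - X.shape[1]
    s2 = (resid ** 2).sum(axis=1) / df
    return B, s2, df, XtX_inv


def fit_differential(
    levels: pd.DataFrame,
    designs: list[SampleDesign] | pd.DataFrame,
    moderation: bool = True,
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site linear model of editing on group + sex + ADAR + ADARB1.

    ``levels`` must be complete (post-imputation). With moderation on,
    residual variances are shrunk toward an empirically fitted prior and the
    group t-statistic uses d0 + df degrees of freedom; off reproduces plain
    OLS t exactly. ``delta`` is the postnatal-minus-prenatal difference of
    group means computed from ``observed`` (the pre-imputation matrix) when
    given, else from ``levels``. FDR is Benjamini-Hochberg.
    """
    X = make_design_matrix(designs).loc[levels.columns]
    grp = X["group"].to_numpy()
    for g in (0.0, 1.0):
        if (grp == g).sum() < 2:
            raise ValueError("need at least 2 samples per group")
    _check_full_rank(X)
    Xm = X.to_numpy(dtype=float)
    Y = levels.to_numpy(dtype=float)
    B, s2, df, XtX_inv = _ols_all_sites(Y, Xm)
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    gi = list(X.columns).index("group")
    v_group = XtX_inv[gi, gi]
    beta_g = B[:, gi]

    if moderation:
        prior = estimate_prior(s2, df)
        s2_used = squeeze_variances(s2, df, prior)
        df_total = prior.d0 + df
    else:
        s2_used = s2
        df_total = df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_g / np.sqrt(s2_used * v_group)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    src = observed if observed is not None else levels
    src = src.loc[levels.index, levels.columns]
    post = src.loc[:, grp == 1.0].mean(axis=1)
    pre = src.loc[:, grp == 0.0].mean(axis=1)

    out = pd.DataFrame(
        {
            "site_id": levels.index,
            "delta": (post - pre).to_numpy(),
            "beta_group": beta_g,
            "s2": s2,
            "t_mod": t,
            "p": np.clip(p, 0.0, 1.0),
        }
    ).set_index("site_id")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def _rubin_pool(fits: list[pd.DataFrame], m: int) -> pd.DataFrame:
    """Pool per-imputation fits: Rubin's rules on the group coefficient."""
    betas = np.column_stack([f["beta_group"].to_numpy() for f in fits])
    # within-imputation squared SE recovered from each fit's t
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = np.column_stack(
            [(f["beta_group"] / f["t_mod"]).to_numpy() ** 2 for f in fits]
        )
    beta_bar = betas.mean(axis=1)
    W = se2.mean(axis=1)
    Bv = betas.var(axis=1, ddof=1) if m > 1 else np.zeros_like(beta_bar)
    T = W + (1 + 1 / m) * Bv
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_bar / np.sqrt(T)
        r = (1 + 1 / m) * Bv / W
        df = np.where(Bv > 0, (m - 1) * (1 + 1 / np.maximum(r, 1e-300)) ** 2, np.inf)
    p = np.where(np.isinf(df), 2.0 * stats.norm.sf(np.abs(t)),
                 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1.0)))
    out = fits[0].copy()
    out["beta_group"] = beta_bar
    out["t_mod"] = t
    out["p"] = np.clip(p, 0.0, 1.0)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def differential_editing(
    observed: pd.DataFrame,
    designs: list[SampleDesign] | pd.DataFrame,
    imputation: ImputationConfig | None = None,
    moderation: bool = True,
    pooling: str = "average",
) -> pd.DataFrame:
    """Impute, fit, and FDR-correct in one call.

    ``average`` pooling fits one model on the consensus (mean) completed
    matrix; ``rubin`` fits per completed matrix and pools coefficients and
    variances by Rubin's rules. ``delta`` always comes from the observed
    (pre-imputation) group means.
    """
    completed = impute_pmm(observed, designs, imputation)
    if pooling == "average":
        cons = consensus(completed, "average")
        return fit_differential(cons, designs, moderation, observed=observed)
    if pooling == "rubin":
        fits = [
            fit_differential(c, designs, moderation, observed=observed)
            for c in completed
        ]
        return _rubin_pool(fits, len(completed))
    raise ValueError(f"unknown pooling {pooling!r}")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# developmental staging and effect sizes

@dataclass
class DevBinScheme:
    """Named age bins, each (unit, low, high) inclusive."""

    bins: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    def assign(self, age_value: float, age_unit: str) -> str | None:
        if age_value < 0:
            raise ValueError("negative age")
        for label, (unit, lo, hi) in self.bins.items():
            if unit == age_unit and lo <= age_value <= hi:
                return label
        return None


DEFAULT_BINS = DevBinScheme(
    {
        "early_gestation": ("wpc", 4, 10),
        "late_gestation": ("wpc", 11, 20),
        "newborn_teenager": ("years", 0, 20),
        "adult_senior": ("years", 25, 63),
    }
)

# sub-split of early development used only in its own analysis mode; note the
# second sub-bin deliberately meets the late-gestation boundary at 11 wpc
EARLY_SPLIT_BINS = DevBinScheme(
    {
        "early_phase1": ("wpc", 4, 7),
        "early_phase2": ("wpc", 8, 11),
    }
)


def assign_bins(
    designs: list[SampleDesign] | pd.DataFrame,
    scheme: DevBinScheme = DEFAULT_BINS,
) -> pd.Series:
    """Map each sample's age to a developmental bin (None if unmappable)."""
    if isinstance(designs, pd.DataFrame):
        items = list(designs[["age_value", "age_unit"]].itertuples())
        ids = list(designs.index)
        ages = [(r.age_value, r.age_unit) for r in items]
    else:
        ids = [d.sample_id for d in designs]
        ages = [(d.age_value, d.age_unit) for d in designs]
    labels = []
    unassigned = []
    for sid, (v, u) in zip(ids, ages):
        lab = scheme.assign(v, u)
        labels.append(lab)
        if lab is None:
            unassigned.append(sid)
    if unassigned:
        warnings.warn(f"samples outside all bins, excluded: {unassigned}",
                      stacklevel=2)
    return pd.Series(labels, index=ids, name="bin")


@dataclass
class EffectSizeResult:
    """One two-group contrast: Student's t, p, and pooled-SD Cohen's d."""

    contrast: str
    d: float
    t: float
    p: float
    n1: int
    n2: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.d)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean_b - mean_a) / pooled SD; NaN when the pooled SD is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        # two constant groups: equal means is a true zero effect,
        # unequal means leaves d undefined
        return 0.0 if b.mean() == a.mean() else np.nan
    return float((b.mean() - a.mean()) / pooled)


def bin_contrast(
    values_by_bin: dict[str, np.ndarray],
    contrast: tuple[str, str],
    equal_var: bool = True,
) -> EffectSizeResult:
    """Two-tailed t-test and Cohen's d for bin B vs bin A.

    The sign convention is B minus A (the later stage minus the earlier).
    Equal-variance Student's t by default; Welch by flag.
    """
    a_lab, b_lab = contrast
    a = np.asarray(values_by_bin[a_lab], dtype=float)
    b = np.asarray(values_by_bin[b_lab], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both bins need n >= 2")
    t, p = stats.ttest_ind(b, a, equal_var=equal_var)
    if np.array_equal(a, b):
        t, p = 0.0, 1.0  # identical groups: zero-variance t is 0/0
    d = cohens_d(a, b)
    return EffectSizeResult(f"{b_lab}_vs_{a_lab}", d, float(t), float(p),
                            len(a), len(b))


def pooled_effect(results: list[EffectSizeResult]) -> float:
    """Sample-size-weighted mean of per-stratum Cohen's d values."""
    if not results:
        raise ValueError("no stratum results to pool")
    ns = np.array([r.n1 + r.n2 for r in results], dtype=float)
    ds = np.array([r.d for r in results], dtype=float)
    return float(np.sum(ns * ds) / np.sum(ns))


def anova_tukey(
    values_by_group: dict[str, np.ndarray],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD over all group pairs.

    Returns (F, omnibus p, pairwise table with adjusted p-values). Fewer
    than three groups is an error — use :func:`bin_contrast` for two.
    """
    names = list(values_by_group)
    if len(names) < 3:
        raise ValueError("ANOVA/Tukey needs >= 3 groups; use bin_contrast for 2")
    arrays = [np.asarray(values_by_group[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    F, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                (names[i], names[j],
                 float(np.mean(arrays[j]) - np.mean(arrays[i])),
                 float(res.pvalue[i, j]))
            )
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj"])
    return float(F), float(p), table
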