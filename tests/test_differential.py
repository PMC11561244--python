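"""PMM imputation, moderated linear models, FDR, bins, and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editdev.differential import (
    DEFAULT_BINS,
    EARLY_SPLIT_BINS,
    EffectSizeResult,
    ImputationConfig,
    ModerationPrior,
    anova_tukey,
    assign_bins,
    bh_adjust,
    bin_contrast,
    cohens_d,
    consensus,
    differential_editing,
    estimate_prior,
    fit_differential,
    impute_pmm,
    make_design_matrix,
    pooled_effect,
    squeeze_variances,
)
from editdev.synthetic import (
    SampleDesign,
    TrajectoryModel,
    mar_mask,
    matrix_from_truth,
    simulate_truth,
)

from oracles import brute_force_bh, brute_force_cohens_d


def designs_n(n_per_group: int, rng=None) -> list[SampleDesign]:
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(n_per_group):
        out.append(SampleDesign(f"pre_{i}", 5 + i, "wpc", "FM"[i % 2],
                                adar_expr=float(rng.normal(1, 0.2)),
                                adarb1_expr=float(rng.normal(1, 0.2))))
    for i in range(n_per_group):
        out.append(SampleDesign(f"post_{i}", 1 + 3 * i, "years", "MF"[i % 2],
                                adar_expr=float(rng.normal(1, 0.2)),
                                adarb1_expr=float(rng.normal(1, 0.2))))
    return out


def null_levels(n_sites, designs, noise_sd, rng) -> pd.DataFrame:
    base = rng.uniform(0.1, 0.5, size=n_sites)
    data = base[:, None] + rng.normal(0, noise_sd, size=(n_sites, len(designs)))
    return pd.DataFrame(np.clip(data, 0, 1),
                        index=[f"site_{i}" for i in range(n_sites)],
                        columns=[d.sample_id for d in designs])


class TestImputePMM:
    def correlated_masked(self, seed, tiny_bundle, designs_8):
        truth = simulate_truth(
            tiny_bundle, {"ALU": 30}, designs_8,
            TrajectoryModel(0.3, 0.2, "logistic_increase", 0.03),
            seed=seed, baseline_jitter=0.1)
        levels = matrix_from_truth(truth, [d.sample_id for d in designs_8])
        return levels, mar_mask(levels, designs_8, 0.12, 0.5, seed + 1)

    def test_complete_matrix_returned_unchanged(self, tiny_bundle, designs_8):
        levels, _ = self.correlated_masked(1, tiny_bundle, designs_8)
        out = impute_pmm(levels, designs_8, ImputationConfig(seed=1))
        assert len(out) == 5
        for m in out:
            pd.testing.assert_frame_equal(m, levels)

    def test_default_emits_five_matrices(self, tiny_bundle, designs_8):
        levels, masked = self.correlated_masked(2, tiny_bundle, designs_8)
        out = impute_pmm(masked, designs_8,
                         ImputationConfig(max_iter=3, seed=2))
        assert len(out) == 5

    def test_donor_property_holds_everywhere(self, tiny_bundle, designs_8):
        """Every imputed value belongs to its own site's observed value set."""
        levels, masked = self.correlated_masked(3, tiny_bundle, designs_8)
        out = impute_pmm(masked, designs_8,
                         ImputationConfig(max_iter=5, seed=3))
        miss = masked.isna()
        for m in out:
            assert not m.isna().any().any()
            for sid in masked.index[miss.any(axis=1)]:
                observed = set(masked.loc[sid].dropna())
                imputed = set(m.loc[sid, miss.loc[sid]])
                assert imputed <= observed

    def test_observed_entries_never_touched(self, tiny_bundle, designs_8):
        levels, masked = self.correlated_masked(4, tiny_bundle, designs_8)
        out = impute_pmm(masked, designs_8,
                         ImputationConfig(max_iter=3, seed=4))
        obs = ~masked.isna()
        for m in out:
            assert np.allclose(m.to_numpy()[obs.to_numpy()],
                               masked.to_numpy()[obs.to_numpy()])

    def test_small_donor_pool_warns(self):
        levels = pd.DataFrame(
            {"s1": [0.1, 0.2], "s2": [0.2, 0.25], "s3": [0.3, np.nan]},
            index=["a", "b"])
        with pytest.warns(UserWarning, match="donor pool"):
            impute_pmm(levels, None, ImputationConfig(m=1, max_iter=1, seed=1))

    def test_all_missing_site_rejected(self):
        levels = pd.DataFrame({"s1": [np.nan], "s2": [np.nan]}, index=["a"])
        with pytest.raises(ValueError, match="no observed"):
            impute_pmm(levels, None, ImputationConfig(seed=1))

    def test_pmm_beats_column_mean_imputation(self, tiny_bundle, designs_8):
        """On MAR-masked correlated matrices, the consensus PMM completion
        has RMSE at or below per-site mean imputation, pooled over 10 seeded
        replicates."""
        se_pmm, se_mean = [], []
        for seed in range(10):
            levels, masked = self.correlated_masked(100 + seed, tiny_bundle,
                                                    designs_8)
            miss = masked.isna() & levels.notna()
            cons = consensus(impute_pmm(
                masked, designs_8, ImputationConfig(max_iter=10, seed=seed)))
            mean_imp = masked.apply(lambda r: r.fillna(r.mean()), axis=1)
            truth_vals = levels.to_numpy()[miss.to_numpy()]
            se_pmm.append((cons.to_numpy()[miss.to_numpy()] - truth_vals) ** 2)
            se_mean.append(
                (mean_imp.to_numpy()[miss.to_numpy()] - truth_vals) ** 2)
        rmse_pmm = np.sqrt(np.mean(np.concatenate(se_pmm)))
        rmse_mean = np.sqrt(np.mean(np.concatenate(se_mean)))
        assert rmse_pmm <= rmse_mean


class TestConsensus:
    def test_identical_matrices_average_to_self(self):
        m = pd.DataFrame({"s1": [0.1, 0.2]}, index=["a", "b"])
        pd.testing.assert_frame_equal(consensus([m.copy(), m.copy()]), m)

    def test_elementwise_mean(self):
        m1 = pd.DataFrame({"s1": [0.1]}, index=["a"])
        m2 = pd.DataFrame({"s1": [0.3]}, index=["a"])
        assert consensus([m1, m2]).iloc[0, 0] == pytest.approx(0.2)

    def test_rubin_mode_defers(self):
        m = pd.DataFrame({"s1": [0.1]}, index=["a"])
        out = consensus([m, m], mode="rubin")
        assert isinstance(out, list) and len(out) == 2

    def test_shape_mismatch_rejected(self):
        m1 = pd.DataFrame({"s1": [0.1]}, index=["a"])
        m2 = pd.DataFrame({"s1": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="shape"):
            consensus([m1, m2])


class TestModeration:
    # frozen oracle: limma::squeezeVar(s2, df=7) on this exact vector
    LIMMA_S2 = np.array([0.010, 0.025, 0.040, 0.055, 0.070, 0.090, 0.120,
                         0.015, 0.032, 0.080])
    LIMMA_D0 = 7.104415437
    LIMMA_S0 = 0.04181367208
    LIMMA_POST = np.array([0.02602459485, 0.03346907212, 0.04091354938,
                           0.04835802664, 0.0558025039, 0.06572847358,
                           0.0806174281, 0.02850608727, 0.0369431615,
                           0.06076548874])

    def test_matches_limma_squeeze_var(self):
        prior = estimate_prior(self.LIMMA_S2, 7)
        assert prior.d0 == pytest.approx(self.LIMMA_D0, rel=1e-8)
        assert prior.s0_sq == pytest.approx(self.LIMMA_S0, rel=1e-8)
        post = squeeze_variances(self.LIMMA_S2, 7, prior)
        assert np.allclose(post, self.LIMMA_POST, rtol=1e-8)

    def test_identical_variances_are_fixed_point(self):
        s2 = np.full(50, 0.03)
        prior = estimate_prior(s2, 7)
        assert np.allclose(squeeze_variances(s2, 7, prior), 0.03)

    def test_shrinkage_lies_between_own_and_prior(self):
        s2 = np.array([0.01, 0.09])
        prior = estimate_prior(s2, 7)
        post = squeeze_variances(s2, 7, prior)
        for own, p in zip(s2, post):
            lo, hi = sorted((own, prior.s0_sq))
            assert lo < p < hi

    def test_infinite_prior_df_collapses_to_s0(self):
        prior = ModerationPrior(np.inf, 0.02)
        s2 = np.array([0.001, 0.05, 0.2])
        assert np.allclose(squeeze_variances(s2, 7, prior), 0.02)


class TestFitDifferential:
    def test_exact_linear_signal_recovered(self):
        designs = designs_n(4)
        g = np.array([0.0] * 4 + [1.0] * 4)
        levels = pd.DataFrame(
            np.tile(0.1 + 0.2 * g, (3, 1)),
            index=["a", "b", "c"], columns=[d.sample_id for d in designs])
        out = fit_differential(levels, designs, moderation=False)
        assert np.allclose(out.beta_group, 0.2)
        assert np.allclose(out.s2, 0.0)
        assert np.allclose(out.delta, 0.2)

    def test_moderation_off_is_plain_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        designs = designs_n(5, rng)
        levels = null_levels(20, designs, 0.05, rng)
        out = fit_differential(levels, designs, moderation=False)
        X = make_design_matrix(designs).to_numpy()
        for i, sid in enumerate(levels.index[:5]):
            fit = sm.OLS(levels.loc[sid].to_numpy(), X).fit()
            assert out.loc[sid, "beta_group"] == pytest.approx(fit.params[1])
            assert out.loc[sid, "t_mod"] == pytest.approx(fit.tvalues[1])
            assert out.loc[sid, "p"] == pytest.approx(fit.pvalues[1])

    def test_moderated_t_uses_squeezed_variance(self):
        rng = np.random.default_rng(6)
        designs = designs_n(5, rng)
        levels = null_levels(50, designs, 0.05, rng)
        out = fit_differential(levels, designs, moderation=True)
        prior = estimate_prior(out.s2.to_numpy(), len(designs) - 5)
        s2_post = squeeze_variances(out.s2.to_numpy(), len(designs) - 5, prior)
        ratio = (out.t_mod.to_numpy() ** 2) * s2_post
        plain = fit_differential(levels, designs, moderation=False)
        ratio_plain = (plain.t_mod.to_numpy() ** 2) * plain.s2.to_numpy()
        assert np.allclose(ratio, ratio_plain)

    def test_rank_deficient_design_names_columns(self):
        designs = designs_n(3)
        for d in designs:
            d.adar_expr = 1.0
            d.adarb1_expr = 1.0  # both collinear with the intercept
        levels = null_levels(4, designs, 0.05, np.random.default_rng(1))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_differential(levels, designs)

    def test_single_group_rejected(self):
        designs = [SampleDesign(f"s{i}", 10 + i, "years") for i in range(6)]
        levels = null_levels(3, designs, 0.05, np.random.default_rng(1))
        with pytest.raises(ValueError, match="per group"):
            fit_differential(levels, designs)

    def test_rubin_pooling_runs_and_orders_sanely(self, tiny_bundle):
        designs = designs_n(4, np.random.default_rng(77))
        truth = simulate_truth(
            tiny_bundle, {"ALU": 20}, designs,
            TrajectoryModel(0.3, 0.0, "constant", 0.05), seed=7,
            baseline_jitter=0.1)
        levels = matrix_from_truth(truth, [d.sample_id for d in designs])
        masked = mar_mask(levels, designs, 0.1, 0.5, seed=8)
        out = differential_editing(
            masked, designs, ImputationConfig(m=3, max_iter=3, seed=9),
            pooling="rubin")
        assert (out.fdr >= out.p - 1e-12).all()
        assert out.fdr.between(0, 1).all()


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_equal_and_single_unchanged(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)
        assert np.allclose(bh_adjust([0.2]), [0.2])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p))


class TestBins:
    def test_methods_mapping(self):
        designs = [
            SampleDesign("early", 4, "wpc"),
            SampleDesign("late", 15, "wpc"),
            SampleDesign("adult", 30, "years"),
            SampleDesign("teen", 20, "years"),
        ]
        bins = assign_bins(designs)
        assert bins.tolist() == ["early_gestation", "late_gestation",
                                 "adult_senior", "newborn_teenager"]

    def test_gap_ages_excluded_with_warning(self):
        designs = [SampleDesign("gap", 22, "years"),
                   SampleDesign("ok", 30, "years")]
        with pytest.warns(UserWarning, match="gap"):
            bins = assign_bins(designs)
        assert bins["gap"] is None
        assert bins["ok"] == "adult_senior"

    def test_boundaries_inclusive(self):
        assert DEFAULT_BINS.assign(10, "wpc") == "early_gestation"
        assert DEFAULT_BINS.assign(11, "wpc") == "late_gestation"
        assert DEFAULT_BINS.assign(20, "years") == "newborn_teenager"
        assert DEFAULT_BINS.assign(63, "years") == "adult_senior"
        assert DEFAULT_BINS.assign(21, "wpc") is None

    def test_early_split_scheme(self):
        assert EARLY_SPLIT_BINS.assign(6, "wpc") == "early_phase1"
        assert EARLY_SPLIT_BINS.assign(11, "wpc") == "early_phase2"

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DEFAULT_BINS.assign(-1, "years")


class TestEffectSizes:
    def test_closed_form_example(self):
        res = bin_contrast({"A": np.array([1, 2, 3]),
                            "B": np.array([3, 4, 5])}, ("A", "B"))
        assert res.d == pytest.approx(2.0)
        assert res.n1 == res.n2 == 3

    def test_identical_groups(self):
        v = np.array([1.0, 2.0, 3.0])
        res = bin_contrast({"A": v, "B": v.copy()}, ("A", "B"))
        assert res.d == 0.0
        assert res.p == 1.0

    def test_translation_scales_by_sd(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 2.0, size=50)
        res = bin_contrast({"A": a, "B": a + 1.5}, ("A", "B"))
        assert res.d == pytest.approx(1.5 / a.std(ddof=1))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=int(rng.integers(2, 20)))
        b = rng.normal(0.5, 2, size=int(rng.integers(2, 20)))
        res = bin_contrast({"A": a, "B": b}, ("A", "B"))
        assert res.d == pytest.approx(brute_force_cohens_d(a, b))

    def test_pooled_effect_weighting(self):
        mk = lambda d, n: EffectSizeResult("c", d, 0, 1, n, n)
        assert pooled_effect([mk(0.5, 3), mk(0.5, 9)]) == pytest.approx(0.5)
        assert pooled_effect([mk(0.0, 5), mk(1.0, 5)]) == pytest.approx(0.5)
        assert pooled_effect([mk(1.21, 4)]) == pytest.approx(1.21)
        assert pooled_effect([mk(0.0, 2), mk(1.0, 6)]) == pytest.approx(0.75)

    def test_zero_pooled_sd_flagged_when_means_differ(self):
        d = cohens_d(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.isnan(d)


class TestAnovaTukey:
    def test_identical_groups_nothing_significant(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        F, p, table = anova_tukey({"a": v, "b": v.copy(), "c": v.copy()})
        assert F == pytest.approx(0.0)
        assert (table.p_adj > 0.9).all()

    def test_single_shifted_group_detected(self):
        """Groups N(0,1), N(0,1), N(5,1): only pairs with the third group
        reach significance, matching per-pair t-tests."""
        rng = np.random.default_rng(3)
        groups = {"g1": rng.normal(0, 1, 50), "g2": rng.normal(0, 1, 50),
                  "g3": rng.normal(5, 1, 50)}
        F, p, table = anova_tukey(groups)
        assert p < 1e-10
        sig = table[table.p_adj < 0.05]
        assert set(map(tuple, sig[["group_a", "group_b"]].to_numpy())) == {
            ("g1", "g3"), ("g2", "g3")}
        from scipy import stats
        for row in table.itertuples():
            t, pp = stats.ttest_ind(groups[row.group_a], groups[row.group_b])
            assert (pp < 0.05) == (row.p_adj < 0.06)

    def test_two_groups_refused(self):
        with pytest.raises(ValueError, match="bin_contrast"):
            anova_tukey({"a": np.ones(3), "b": np.ones(3)})


class TestErrorControl:
    def test_null_fdp_and_signal_recovery(self):
        """Small-scale version of the calibration study: BH at 0.05 controls
        the realized false-discovery proportion under the null, and injected
        deltas of 0.15 are recovered without systematic bias."""
        rng = np.random.default_rng(11)
        designs = designs_n(10, rng)
        g = np.array([0.0] * 10 + [1.0] * 10)
        fdps = []
        betas = []
        for rep in range(5):
            levels = null_levels(500, designs, 0.05, rng)
            truth_idx = rng.choice(500, size=50, replace=False)
            arr = levels.to_numpy()
            arr[truth_idx] = np.clip(arr[truth_idx] + 0.15 * g, 0, 1)
            levels = pd.DataFrame(arr, index=levels.index,
                                  columns=levels.columns)
            out = fit_differential(levels, designs, moderation=True)
            disc = out[out.fdr < 0.05]
            is_true = np.zeros(500, dtype=bool)
            is_true[truth_idx] = True
            false = (~is_true[[int(s.split("_")[1]) for s in disc.index]]).sum()
            fdps.append(false / max(len(disc), 1))
            if len(disc):
                betas.append(out.beta_group.to_numpy()[truth_idx].mean())
        assert np.mean(fdps) <= 0.05 + 2 * np.std(fdps) / np.sqrt(len(fdps)) + 0.02
        assert abs(np.mean(betas) - 0.15) < 0.03
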