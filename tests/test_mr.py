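"""MR engine: WGRS, pleiotropy filter, 2SLS, summary-level estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmr import (
    GRSWeights,
    MRSummarySet,
    SimParams,
    VariantSim,
    build_wgrs,
    egger,
    f_statistic,
    funnel_data,
    ivw,
    log10_trait,
    median_estimators,
    or_change_units,
    or_per_unit,
    pleiotropy_filter,
    simulate_cohort,
    spike_pleiotropy,
    two_stage_ls,
    wald_ratio,
)

from conftest import make_cohort


def _weights(rows):
    return GRSWeights(pd.DataFrame(rows, columns=["id", "effect_allele", "weight"]))


def _summary(bx, sx, by, sy):
    m = len(bx)
    return MRSummarySet(pd.DataFrame({
        "id": [f"v{i}" for i in range(m)],
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy}))


class TestBuildWGRS:
    def test_single_variant_unit_weight(self):
        c = make_cohort({"v": np.tile([0.0, 1.0, 2.0], 10)})
        score = build_wgrs(c, _weights([("v", "G", 1.0)]))
        np.testing.assert_array_equal(score.to_numpy(), c.dosages["v"].to_numpy())

    def test_flip_identity(self):
        """Weight −w on the alt allele equals +w on the ref allele."""
        g = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        c = make_cohort({"v": g})
        neg = build_wgrs(c, _weights([("v", "G", -0.4)]))
        pos_ref = build_wgrs(c, _weights([("v", "A", 0.4)]))
        np.testing.assert_allclose(neg.to_numpy(), pos_ref.to_numpy())
        np.testing.assert_allclose(neg.to_numpy(), 0.4 * (2.0 - g))

    def test_missing_dosage_mean_imputed(self):
        g = np.tile([0.0, 1.0, 2.0, 1.0], 25).astype(float)
        g[0] = np.nan
        c = make_cohort({"v": g})
        aaf = c.variants.loc["v", "aaf"]
        score = build_wgrs(c, _weights([("v", "G", 1.0)]))
        assert score.iloc[0] == pytest.approx(2 * aaf)

    def test_unknown_variant_or_allele(self):
        c = make_cohort({"v": np.tile([0.0, 1.0], 10)})
        with pytest.raises(KeyError):
            build_wgrs(c, _weights([("w", "G", 1.0)]))
        with pytest.raises(ValueError, match="effect allele"):
            build_wgrs(c, _weights([("v", "T", 1.0)]))

    def test_first_stage_additivity(self, seven_variant_cohort):
        """Regressing the trait on a WGRS weighted by the true betas gives
        slope ≈ 1 and incremental r² ≈ Σ 2pqβ²/var (analytic additivity)."""
        c = seven_variant_cohort
        params = c.extras["params"]
        w = _weights([(v.id, v.alt, v.beta_log10_ldl) for v in params.variants])
        score = build_wgrs(c, w)
        y = log10_trait(c.phenotypes["ldl_mgdl"])
        from lipidmr import fit_linear

        fit = fit_linear(y, pd.DataFrame({"wgrs": score.to_numpy()}))
        assert fit.params["wgrs"] == pytest.approx(1.0, abs=4 * fit.bse["wgrs"])
        analytic = sum(2 * v.maf * (1 - v.maf) * v.beta_log10_ldl ** 2
                       for v in params.variants) / np.var(y)
        assert fit.partial_r2["wgrs"] == pytest.approx(analytic, rel=0.25)


class TestPleiotropyFilter:
    def test_alpha_zero_excludes_nothing(self, seven_variant_cohort):
        c = seven_variant_cohort
        kept, excluded = pleiotropy_filter(
            c, c.variant_ids, log10_trait(c.phenotypes["ldl_mgdl"]),
            c.phenotypes["dm"], alpha=0.0)
        assert excluded == []
        assert len(kept) == c.n_variants

    def test_mediated_variant_kept_direct_variant_excluded(self):
        variants = [VariantSim("mediated", 0.3, 0.06, pos=100),
                    VariantSim("direct", 0.2, 0.0, pos=200)]
        c = simulate_cohort(SimParams(n_samples=20000, variants=variants, seed=71))
        c = spike_pleiotropy(c, "direct", 0.3)
        trait = log10_trait(c.phenotypes["ldl_mgdl"])
        kept, excluded = pleiotropy_filter(c, ["mediated", "direct"], trait,
                                           c.phenotypes["dm"])
        assert [k for k, _ in kept] == ["mediated"]
        assert [(e[0], e[2]) for e in excluded] == [("direct", "outcome_associated")]

    def test_spike_power_across_replicates(self):
        """A 0.3 log-odds direct effect on a MAF-0.2 variant is flagged at
        p < 0.01 in nearly every replicate at n = 20,000."""
        flagged = 0
        reps = 20
        for s in range(reps):
            variants = [VariantSim("v", 0.2, 0.0, pos=100)]
            c = simulate_cohort(SimParams(n_samples=20000, variants=variants,
                                          seed=900 + s))
            c = spike_pleiotropy(c, "v", 0.3)
            _, excluded = pleiotropy_filter(c, ["v"],
                                            log10_trait(c.phenotypes["ldl_mgdl"]),
                                            c.phenotypes["dm"])
            flagged += bool(excluded)
        assert flagged >= int(0.95 * reps)


class TestTwoStageLS:
    def test_constant_instrument_rejected(self):
        c = make_cohort({"v": np.tile([0.0, 1.0], 50)})
        with pytest.raises(ValueError, match="constant"):
            two_stage_ls(c, np.ones(100), np.random.default_rng(0).normal(2, 0.1, 100),
                         c.phenotypes["dm"])

    def test_weak_instrument_warning(self):
        rng = np.random.default_rng(72)
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        c = make_cohort({"v": g}, ldl=10 ** rng.normal(2.08, 0.11, n),
                        dm=rng.binomial(1, 0.2, n))
        est = two_stage_ls(c, "v", log10_trait(c.phenotypes["ldl_mgdl"]),
                           c.phenotypes["dm"])
        assert est.f_statistic < 10
        assert any("weak instrument" in n_ for n_ in est.notes)

    def test_null_theta_calibrated(self):
        params = SimParams(n_samples=30000, theta_causal=0.0,
                           confounder_strength=0.0, dm_baseline_logodds=-2.5,
                           seed=73)
        c = simulate_cohort(params)
        w = _weights([(v.id, v.alt, v.beta_log10_ldl) for v in params.variants])
        est = two_stage_ls(c, build_wgrs(c, w),
                           log10_trait(c.phenotypes["ldl_mgdl"]), c.phenotypes["dm"])
        assert abs(est.beta) < 4 * est.se


class TestFStatistic:
    @pytest.mark.parametrize("r2, n, expected", [
        (0.0, 100, 0.0),
        (0.5, 4, 2.0),
        (0.00941, 75_441, 716.6),
    ])
    def test_formula(self, r2, n, expected):
        assert f_statistic(r2, n) == pytest.approx(expected, rel=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)
        with pytest.raises(ValueError):
            f_statistic(0.5, 2)

    @given(st.floats(0.0, 0.98), st.floats(0.0, 0.98))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_r2(self, a, b):
        lo, hi = sorted((a, b))
        assert f_statistic(lo, 1000) <= f_statistic(hi, 1000)


class TestWaldRatio:
    def test_published_wgrs_coefficients(self):
        est = wald_ratio(0.5599, 0.0301, -2.3685, 0.8918)
        assert est.beta == pytest.approx(-4.2294, rel=1e-3)
        assert est.se == pytest.approx(1.6, abs=0.1)
        assert est.ci95[0] < est.beta < est.ci95[1]

    def test_identity_instrument(self):
        est = wald_ratio(1.0, 0.0, -2.5, 0.7)
        assert est.beta == -2.5
        assert est.se == pytest.approx(0.7)

    def test_scale_invariance(self):
        a = wald_ratio(0.5, 0.03, -2.0, 0.8)
        b = wald_ratio(1.5, 0.09, -6.0, 2.4)
        assert a.beta == pytest.approx(b.beta)

    def test_zero_exposure_beta(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 1.0, 0.1)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        w = wald_ratio(0.5599, 0.0301, -2.3685, 0.8918)
        iv = ivw(_summary([0.5599], [0.0301], [-2.3685], [0.8918]))
        assert iv.beta == w.beta
        assert iv.se == w.se
        assert iv.p == w.p
        assert iv.q_statistic == 0.0 and iv.q_df == 0

    def test_identical_instruments_zero_q(self):
        iv = ivw(_summary([0.5] * 4, [0.03] * 4, [-2.0] * 4, [0.8] * 4))
        assert iv.beta == pytest.approx(-4.0)
        assert iv.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert iv.q_df == 3

    def test_q_reorder_invariant(self):
        rng = np.random.default_rng(80)
        bx = rng.uniform(0.1, 0.5, 8)
        by = -2.0 * bx + rng.normal(0, 0.1, 8)
        s = _summary(bx, np.full(8, 0.02), by, np.full(8, 0.1))
        perm = rng.permutation(8)
        s2 = MRSummarySet(s.table.iloc[perm].reset_index(drop=True))
        assert ivw(s).q_statistic == pytest.approx(ivw(s2).q_statistic)
        assert ivw(s).beta == pytest.approx(ivw(s2).beta)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(81)
        bx = rng.uniform(0.1, 0.5, 6)
        by = -1.5 * bx + rng.normal(0, 0.05, 6)
        s = _summary(bx, np.full(6, 0.02), by, np.full(6, 0.1))
        t = s.table.copy()
        t.loc[::2, ["beta_exp", "beta_out"]] *= -1.0  # flip alternate alleles
        flipped = MRSummarySet(t)
        assert ivw(flipped).beta == pytest.approx(ivw(s).beta)
        assert ivw(flipped).se == pytest.approx(ivw(s).se)
        slope_a, int_a = egger(s)
        slope_b, int_b = egger(flipped)
        assert slope_b.beta == pytest.approx(slope_a.beta)
        assert int_b.beta == pytest.approx(int_a.beta)


class TestEgger:
    def test_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        slope, intercept = egger(_summary(bx, [0.01] * 4, -3.0 * bx, [0.1] * 4))
        assert slope.beta == pytest.approx(-3.0, abs=1e-10)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)

    def test_planted_offset_in_intercept(self):
        rng = np.random.default_rng(82)
        reps = 200
        intercepts = np.empty(reps)
        slopes = np.empty(reps)
        for r in range(reps):
            bx = rng.uniform(0.1, 0.5, 12)
            by = -2.0 * bx + 0.15 + rng.normal(0, 0.08, 12)
            s = _summary(bx, np.full(12, 0.02), by, np.full(12, 0.08))
            sl, ic = egger(s)
            intercepts[r], slopes[r] = ic.beta, sl.beta
        mcse_i = intercepts.std(ddof=1) / np.sqrt(reps)
        mcse_s = slopes.std(ddof=1) / np.sqrt(reps)
        assert intercepts.mean() == pytest.approx(0.15, abs=3 * mcse_i)
        assert slopes.mean() == pytest.approx(-2.0, abs=3 * mcse_s)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(83)
        bx = rng.uniform(0.1, 0.6, 9)
        by = -1.2 * bx + rng.normal(0, 0.1, 9)
        sy = rng.uniform(0.05, 0.2, 9)
        s = _summary(bx, np.full(9, 0.02), by, sy)
        slope, intercept = egger(s)
        import statsmodels.api as sm

        wls = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy ** 2).fit()
        assert slope.beta == pytest.approx(wls.params[1], abs=1e-10)
        assert slope.se == pytest.approx(wls.bse[1], abs=1e-10)
        assert intercept.beta == pytest.approx(wls.params[0], abs=1e-10)
        assert intercept.p == pytest.approx(wls.pvalues[0], abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger(_summary([0.1, 0.2], [0.01] * 2, [0.3, 0.6], [0.1] * 2))


class TestMedians:
    def test_simple_median_of_three(self):
        s = _summary([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 9.0], [1.0] * 3)
        simple, _ = median_estimators(s, n_boot=50, seed=1)
        assert simple.beta == pytest.approx(2.0)

    def test_degenerate_weights_pick_one_instrument(self):
        # middle instrument carries virtually all IVW weight
        s = _summary([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 5.0, 9.0],
                     [100.0, 0.001, 100.0])
        _, weighted = median_estimators(s, n_boot=50, seed=1)
        assert weighted.beta == pytest.approx(5.0, abs=0.01)

    def test_bootstrap_seeded(self):
        s = _summary([0.3, 0.4, 0.5, 0.2], [0.02] * 4,
                     [-0.6, -0.9, -1.0, -0.5], [0.1] * 4)
        a = median_estimators(s, n_boot=200, seed=9)
        b = median_estimators(s, n_boot=200, seed=9)
        assert a[1].se == b[1].se

    def test_breakdown_under_minority_invalid(self):
        """With 4 of 10 equal-weight instruments shifted, the weighted
        median stays near the valid ratio while IVW is dragged away."""
        rng = np.random.default_rng(84)
        reps = 100
        wm = np.empty(reps)
        iv_b = np.empty(reps)
        for r in range(reps):
            bx = rng.uniform(0.3, 0.5, 10)
            by = -2.0 * bx + rng.normal(0, 0.005, 10)
            by[:4] += 1.0  # invalid minority
            s = _summary(bx, np.full(10, 0.01), by, np.full(10, 0.05))
            _, weighted = median_estimators(s, n_boot=2, seed=r)
            wm[r] = weighted.beta
            iv_b[r] = ivw(s).beta
        assert abs(wm.mean() + 2.0) < 0.35
        assert abs(iv_b.mean() + 2.0) > 0.7


class TestFunnel:
    def test_single_variant_single_row(self):
        out = funnel_data(_summary([0.5], [0.03], [-2.0], [0.8]))
        assert len(out) == 1
        assert out["ratio"].iloc[0] == pytest.approx(-4.0)

    def test_symmetric_set_flat(self):
        rng = np.random.default_rng(85)
        m = 400
        bx = rng.uniform(0.2, 0.6, m)
        sy = rng.uniform(0.05, 0.3, m)
        by = -2.0 * bx + rng.normal(0, sy)
        out = funnel_data(_summary(bx, np.full(m, 1e-6), by, sy))
        slope = np.polyfit(out["precision"], out["ratio"], 1)[0]
        resid_sd = out["ratio"].std()
        assert abs(slope) < 4 * resid_sd / (out["precision"].std() * np.sqrt(m))


class TestUnitConversion:
    def test_null_effect(self):
        assert or_per_unit(0.0, 120.9, "mgdl") == 1.0
        assert or_per_unit(0.0, 120.9, "mmol") == 1.0

    def test_published_per_mmol_to_per_mgdl(self):
        assert round(or_change_units(0.78, "mmol", "mgdl"), 2) == 0.99

    def test_iv_estimate_per_mgdl_reduction(self):
        or_down = 1.0 / or_per_unit(-4.2294, 120.9, "mgdl")
        assert or_down == pytest.approx(1.015, abs=0.002)
        assert 1.00 <= round(or_down, 2) <= 1.02

    def test_round_trip_through_log10_slope(self):
        beta = np.log(0.78) / (38.67 / (np.log(10) * 120.9))
        assert or_per_unit(beta, 120.9, "mmol") == pytest.approx(0.78)
        assert or_per_unit(beta, 120.9, "mgdl") == pytest.approx(
            or_change_units(0.78, "mmol", "mgdl"))

    def test_errors(self):
        with pytest.raises(ValueError):
            or_per_unit(1.0, -5.0)
        with pytest.raises(ValueError):
            or_per_unit(1.0, 100.0, "stone")
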