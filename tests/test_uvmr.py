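"""Univariable estimators against closed forms, oracles and invariants."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from mrmediate.exceptions import DataError, InsufficientInstruments
from mrmediate.simulate import SimulationConfig, simulate_study
from mrmediate.sumstats import HarmonizedPair, harmonize
from mrmediate.uvmr import (UnivariableMR, cochran_q, egger, ivw,
                            leave_one_out, max_likelihood, simple_median,
                            wald_ratio, weighted_median, weighted_mode)


def _pair(snp="rs1", bx=0.5, sx=0.05, by=0.1, sy=0.02):
    return HarmonizedPair(snp_id=snp, effect_allele="A", other_allele="G",
                          beta_exposure=bx, se_exposure=sx, eaf_exposure=0.5,
                          beta_outcome=by, se_outcome=sy, eaf_outcome=0.5,
                          action="kept")


class TestWaldRatio:
    def test_delta_method_arithmetic(self):
        r = wald_ratio(_pair(bx=0.5, sx=0.05, by=0.1, sy=0.02))
        assert r.theta_j == pytest.approx(0.2)
        assert r.se_j == pytest.approx(0.04)

    def test_null_outcome(self):
        r = wald_ratio(_pair(by=0.0))
        assert r.theta_j == 0.0 and r.se_j == pytest.approx(0.02 / 0.5)

    def test_double_sign_flip_invariant(self):
        a = wald_ratio(_pair(bx=0.5, by=0.1))
        b = wald_ratio(_pair(bx=-0.5, by=-0.1))
        assert a.theta_j == b.theta_j and a.se_j == b.se_j

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(DataError):
            wald_ratio(_pair(bx=0.0))


class TestIVW:
    def test_closed_form_micro_example(self, pairs_frame):
        est, het = ivw(pairs_frame([0.2, 0.3, 0.4], 0.1))
        assert est.theta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.1 / math.sqrt(3))
        assert het.q == pytest.approx(2.0) and het.df == 2
        assert het.p_value == pytest.approx(math.exp(-1))

    def test_single_pair_degenerates_to_wald(self):
        est, het = ivw([_pair()])
        w = wald_ratio(_pair())
        assert est.theta == pytest.approx(w.theta_j)
        assert est.se == pytest.approx(w.se_j)
        assert "wald" in est.method

    def test_homogeneous_ratios_random_equals_fixed(self, pairs_frame):
        frame = pairs_frame([0.25] * 4, 0.1)
        rand, _ = ivw(frame, "multiplicative_random")
        fixed, _ = ivw(frame, "fixed")
        assert rand.se == pytest.approx(fixed.se)

    def test_fixed_se_never_exceeds_random_se(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            j = rng.integers(2, 15)
            frame = pd.DataFrame({
                "snp_id": [f"s{i}" for i in range(j)],
                "beta_exposure": rng.uniform(0.05, 0.5, j),
                "se_exposure": 0.01,
                "beta_outcome": rng.normal(0, 0.1, j),
                "se_outcome": rng.uniform(0.01, 0.2, j)})
            assert ivw(frame, "fixed")[0].se <= ivw(frame, "multiplicative_random")[0].se + 1e-15

    def test_matches_wls_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            j = int(rng.integers(3, 25))
            bx = rng.normal(0.5, 0.8, j)
            bx[np.abs(bx) < 0.05] = 0.1
            sy = rng.uniform(0.02, 0.3, j)
            by = rng.normal(0.2 * bx, sy)
            frame = pd.DataFrame({"snp_id": [f"s{i}" for i in range(j)],
                                  "beta_exposure": bx, "se_exposure": 0.01,
                                  "beta_outcome": by, "se_outcome": sy})
            oracle = sm.WLS(by, bx[:, None], weights=1 / sy ** 2).fit().params[0]
            assert abs(ivw(frame)[0].theta - oracle) < 1e-10

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            ivw([])


class TestEgger:
    def test_exact_linear_fit(self):
        pairs = [_pair("a", 0.2, 0.01, 0.20, 0.1),
                 _pair("b", 0.3, 0.01, 0.25, 0.1),
                 _pair("c", 0.4, 0.01, 0.30, 0.1)]
        slope, intercept, het = egger(pairs)
        assert slope.theta == pytest.approx(0.5)
        assert intercept.intercept == pytest.approx(0.10)
        assert het.q == pytest.approx(0.0, abs=1e-20)

    def test_two_pairs_insufficient(self):
        with pytest.raises(InsufficientInstruments):
            egger([_pair("a"), _pair("b")])

    def test_orientation_negates_rows_not_result(self):
        pairs = [_pair("a", 0.2, 0.01, 0.20, 0.1),
                 _pair("b", -0.3, 0.01, -0.25, 0.1),
                 _pair("c", 0.4, 0.01, 0.30, 0.1)]
        slope, intercept, _ = egger(pairs)
        assert slope.theta == pytest.approx(0.5)
        assert intercept.intercept == pytest.approx(0.10)

    def test_intercept_unbiased_under_no_pleiotropy(self):
        """Mean intercept over seeded replicates is ~0 when none was planted."""
        intercepts = []
        for s in range(300):
            study = simulate_study(SimulationConfig(j_instruments=10, seed=s))
            pairs = harmonize(study.exposure, study.outcome).retained
            intercepts.append(egger(pairs)[1].intercept)
        assert abs(np.mean(intercepts)) < 0.004


class TestMedians:
    def test_weighted_median_interpolation_formula(self, pairs_frame):
        frame = pairs_frame([0.1, 0.2, 0.3], [1.0, 1.0, 1 / math.sqrt(8)])
        est = weighted_median(frame, n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.2 + 0.1 * (0.35 / 0.45))

    def test_odd_count_equal_weights(self, pairs_frame):
        est = weighted_median(pairs_frame([0.1, 0.2, 0.3], 0.1), n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.2)

    def test_simple_median_unsorted_input(self, pairs_frame):
        est = simple_median(pairs_frame([0.4, 0.1, 0.2], [0.3, 0.1, 0.2]),
                            n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.2)

    def test_two_ratios_interpolate_with_floor_disabled(self, pairs_frame):
        est = simple_median(pairs_frame([0.1, 0.3], 0.1), n_boot=50, seed=0,
                            min_snps=2)
        assert est.theta == pytest.approx(0.2)

    def test_identical_ratios_ignore_weights(self, pairs_frame):
        est = weighted_median(pairs_frame([0.7, 0.7, 0.7], [0.1, 0.5, 0.01]),
                              n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.7)

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=8))
    def test_equal_weights_weighted_equals_simple(self, ratios):
        theta = np.array(ratios)
        frame = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(len(theta))],
            "beta_exposure": np.ones_like(theta), "se_exposure": 1e-9,
            "beta_outcome": theta, "se_outcome": 0.1})
        wm = weighted_median(frame, n_boot=10, seed=1)
        sm_ = simple_median(frame, n_boot=10, seed=1)
        assert wm.theta == pytest.approx(sm_.theta)

    def test_floor_enforced(self, pairs_frame):
        with pytest.raises(InsufficientInstruments):
            weighted_median(pairs_frame([0.1, 0.2], 0.1))

    def test_bootstrap_reproducible(self, pairs_frame):
        frame = pairs_frame([0.1, 0.25, 0.3, 0.5], 0.1)
        a = weighted_median(frame, n_boot=200, seed=9)
        b = weighted_median(frame, n_boot=200, seed=9)
        assert a == b


class TestWeightedMode:
    def test_degenerate_bandwidth_returns_common_ratio(self, pairs_frame):
        est = weighted_mode(pairs_frame([0.2, 0.2, 0.2], 0.1), n_boot=20, seed=0)
        assert est.theta == pytest.approx(0.2)

    def test_majority_cluster_wins(self, pairs_frame):
        frame = pairs_frame([0.2, 0.2, 0.2, 0.8], 0.1)
        est = weighted_mode(frame, n_boot=20, seed=0)
        # independent KDE oracle on the stated bandwidth and grid
        theta = np.array([0.2, 0.2, 0.2, 0.8])
        sd = theta.std(ddof=1)
        iqr = np.subtract(*np.percentile(theta, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * 4 ** (-1 / 5)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 1024)
        dens = np.exp(-0.5 * ((grid[:, None] - theta) / h) ** 2).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert est.theta == pytest.approx(oracle, abs=1e-12)
        assert est.theta == pytest.approx(0.2, abs=0.02)

    def test_tiny_weight_dissent_cannot_move_mode(self, pairs_frame):
        # the dissenting ratio has a 100x larger SE, hence ~1e-4 the weight
        frame = pairs_frame([0.2, 0.21, 0.19, 0.8], [0.05, 0.05, 0.05, 5.0])
        est = weighted_mode(frame, n_boot=20, seed=0)
        assert est.theta == pytest.approx(0.2, abs=0.03)

    def test_floor_enforced(self, pairs_frame):
        with pytest.raises(InsufficientInstruments):
            weighted_mode(pairs_frame([0.1, 0.2], 0.1))


class TestMaxLikelihood:
    def test_single_pair_equals_wald(self):
        est = max_likelihood([_pair(bx=0.5, by=0.1)])
        assert est.theta == pytest.approx(0.2, abs=1e-8)

    def test_small_exposure_error_limit_equals_fixed_ivw(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(5)],
            "beta_exposure": rng.uniform(0.2, 0.6, 5),
            "se_exposure": 1e-8,
            "beta_outcome": rng.normal(0.1, 0.05, 5),
            "se_outcome": rng.uniform(0.05, 0.2, 5)})
        ml = max_likelihood(frame)
        fixed, _ = ivw(frame, "fixed")
        assert ml.theta == pytest.approx(fixed.theta, abs=1e-6)
        assert ml.se == pytest.approx(fixed.se, rel=1e-4)

    def test_close_to_ivw_on_strong_homogeneous_data(self):
        study = simulate_study(SimulationConfig(j_instruments=10, seed=123))
        pairs = harmonize(study.exposure, study.outcome).retained
        ml = max_likelihood(pairs)
        est, _ = ivw(pairs, "fixed")
        assert abs(ml.theta - est.theta) < 1e-3


class TestCochranQ:
    def test_identical_ratios_q_zero_p_one(self, pairs_frame):
        het = cochran_q(pairs_frame([0.3, 0.3, 0.3], 0.1), 0.3)
        assert het.q == pytest.approx(0.0) and het.p_value == pytest.approx(1.0)

    def test_reference_micro_example(self, pairs_frame):
        het = cochran_q(pairs_frame([0.2, 0.3, 0.4], 0.1), 0.3)
        assert het.q == pytest.approx(2.0)
        assert het.p_value == pytest.approx(math.exp(-1))

    def test_doubling_weights_doubles_q(self, pairs_frame):
        q1 = cochran_q(pairs_frame([0.2, 0.3, 0.4], 0.1), 0.3).q
        q2 = cochran_q(pairs_frame([0.2, 0.3, 0.4], 0.1 / math.sqrt(2)), 0.3).q
        assert q2 == pytest.approx(2 * q1)


class TestLeaveOneOut:
    def test_two_pairs_each_exclusion_is_other_wald(self):
        pairs = [_pair("a", 0.5, 0.05, 0.1, 0.02), _pair("b", 0.4, 0.05, 0.2, 0.02)]
        loo = leave_one_out(pairs)
        excl_a = loo[loo["excluded"] == "a"].iloc[0]
        assert excl_a["theta"] == pytest.approx(0.2 / 0.4)
        excl_b = loo[loo["excluded"] == "b"].iloc[0]
        assert excl_b["theta"] == pytest.approx(0.1 / 0.5)
        assert (loo["excluded"] == "none").sum() == 1

    def test_dominant_outlier_exclusion_shifts_most(self, pairs_frame):
        frame = pairs_frame([0.2, 0.21, 0.19, 0.2, 0.22, 2.0], 0.05)
        loo = leave_one_out(frame)
        full = loo.loc[loo["excluded"] == "none", "theta"].iloc[0]
        shifts = (loo[loo["excluded"] != "none"]
                  .assign(shift=lambda d: (d["theta"] - full).abs()))
        assert shifts.loc[shifts["shift"].idxmax(), "excluded"] == "s5"

    def test_homogeneous_loo_estimates_inside_full_ci(self):
        study = simulate_study(SimulationConfig(j_instruments=10, seed=77))
        pairs = harmonize(study.exposure, study.outcome).retained
        loo = leave_one_out(pairs)
        full = loo[loo["excluded"] == "none"].iloc[0]
        rest = loo[loo["excluded"] != "none"]
        assert ((rest["theta"] >= full["ci_low"]) & (rest["theta"] <= full["ci_high"])).all()


class TestModelSurface:
    def test_fit_all_runs_every_feasible_method(self, small_study):
        pairs = harmonize(small_study.exposure, small_study.outcome).retained
        results = UnivariableMR(pairs).fit_all(n_boot=50, seed=3)
        assert set(results.estimates) == {"ivw", "egger", "weighted_median",
                                          "simple_median", "weighted_mode",
                                          "max_likelihood"}
        assert results.heterogeneity is not None
        assert results.pleiotropy is not None
        assert len(results.loo) == len(pairs) + 1
        assert "ivw" in results.summary()

    def test_fit_all_downgrades_at_two_instruments(self):
        pairs = [_pair("a", 0.5, 0.05, 0.1, 0.02), _pair("b", 0.4, 0.05, 0.2, 0.02)]
        results = UnivariableMR(pairs).fit_all(n_boot=20, seed=3)
        assert "ivw" in results.estimates and "max_likelihood" in results.estimates
        assert set(results.unavailable) == {"egger", "weighted_median",
                                            "simple_median", "weighted_mode"}
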