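"""Seeded simulation studies validating the estimators' operating characteristics.

Each function runs a self-contained, fully seeded study against the
synthetic-data generator (or random regression instances) and returns the
measured quantity: agreement with independent weighted-least-squares
oracles, type-I error and confidence-interval coverage, robustness of the
weighted median under directional pleiotropy, Egger intercept recovery,
outlier-detection power and null calibration of the residual-sum-of-squares
test, and recovery of the mediation decomposition (total vs direct effect).

Default replicate counts are the package's reference study sizes; they are
also what ``scripts/acceptance.py`` reports.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .instruments import filter_genomewide
from .mvmr import build_mvmr_dataset, mvmr_ivw
from .instruments import combine_instruments_mvmr
from .pipeline import AnalysisConfig, classify_significance, select_instruments
from .presso import presso
from .simulate import (SimulationConfig, full_mediation_preset,
                       partial_mediation_preset, simulate_study)
from .sumstats import harmonize
from .uvmr import egger, ivw, weighted_median

Z95 = 1.959963984540054


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Oracle equivalence


def ivw_oracle_gap(n_instances: int = 200, seed: int = 0) -> float:
    """Max |IVW - WLS oracle| over random instances.

    The oracle is statsmodels WLS of outcome betas on exposure betas through
    the origin with weights 1/se_out^2 — an independent solver for the same
    normal equations.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        j = int(rng.integers(3, 31))
        bx = rng.normal(0.3, 1.0, j)
        bx[np.abs(bx) < 0.05] += 0.2  # keep ratios well-defined
        sy = rng.uniform(0.05, 0.5, j)
        by = rng.normal(0.3 * bx, sy)
        frame = pd.DataFrame({"snp_id": [f"s{i}" for i in range(j)],
                              "beta_exposure": bx, "se_exposure": 0.01,
                              "beta_outcome": by, "se_outcome": sy})
        est, _ = ivw(frame)
        oracle = sm.WLS(by, bx[:, None], weights=1.0 / sy ** 2).fit().params[0]
        worst = max(worst, abs(est.theta - oracle))
    return worst


def mvmr_oracle_gap(n_instances: int = 200, seed: int = 0) -> float:
    """Max |MVMR-IVW - WLS oracle| over random multi-exposure instances."""
    from .mvmr import MVMRDataset

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        k = int(rng.integers(2, 5))
        l = int(rng.integers(k + 2, 41))
        bx = rng.normal(0.0, 1.0, (l, k))
        sy = rng.uniform(0.05, 0.5, l)
        theta = rng.normal(0.0, 0.3, k)
        by = rng.normal(bx @ theta, sy)
        data = MVMRDataset(ids=[f"s{i}" for i in range(l)],
                           exposures=[f"x{i}" for i in range(k)],
                           bx=bx, sx=np.full((l, k), 0.01), by=by, sy=sy)
        fit = mvmr_ivw(data, compute_conditional_f=False)
        ours = np.array([e.theta for e in fit.estimates])
        oracle = sm.WLS(by, bx, weights=1.0 / sy ** 2).fit().params
        worst = max(worst, float(np.max(np.abs(ours - oracle))))
    return worst


# ---------------------------------------------------------------------------
# Per-replicate helpers


def _study_pairs(config: SimulationConfig):
    """Simulate one study and harmonize exposure vs outcome."""
    study = simulate_study(config)
    hset = harmonize(study.exposure, study.outcome)
    return study, hset.retained


def q_type1_rate(n_reps: int = 5000, seed: int = 0, alpha: float = 0.05,
                 j: int = 10) -> float:
    """Rejection rate of Cochran's Q under homogeneity (no pleiotropy).

    The null study sets the causal effect to zero so the chi-square
    calibration of Q is isolated from the second-order term contributed by
    exposure-side sampling noise.
    """
    seeds = _subseeds(seed, n_reps)
    hits = 0
    for s in seeds:
        config = SimulationConfig(j_instruments=j, theta_direct=0.0, seed=s)
        _, pairs = _study_pairs(config)
        _, het = ivw(pairs)
        hits += het.p_value < alpha
    return hits / n_reps


def ivw_coverage(n_reps: int = 1000, seed: int = 0, j: int = 10) -> float:
    """95% CI coverage of random-effects IVW under no pleiotropy."""
    seeds = _subseeds(seed, n_reps)
    hits = 0
    for s in seeds:
        config = SimulationConfig(j_instruments=j, seed=s)
        study, pairs = _study_pairs(config)
        est, _ = ivw(pairs)
        truth = config.theta_total
        hits += est.ci_low <= truth <= est.ci_high
    return hits / n_reps


def pleiotropy_bias(n_reps: int = 500, seed: int = 0, j: int = 10,
                    pleiotropy_frac: float = 0.4, mu_alpha: float = 0.05) -> dict:
    """Mean bias of IVW vs weighted median with directional pleiotropy.

    A fraction of instruments carries a strong positive pleiotropic outcome
    effect; the weighted median's majority-valid breakdown property should
    leave it far less biased than IVW.
    """
    seeds = _subseeds(seed, n_reps)
    err_ivw, err_wm = [], []
    for s in seeds:
        config = SimulationConfig(j_instruments=j, pleiotropy="directional",
                                  pleiotropy_frac=pleiotropy_frac,
                                  mu_alpha=mu_alpha, sigma_alpha=0.01, seed=s)
        _, pairs = _study_pairs(config)
        est, _ = ivw(pairs)
        wm = weighted_median(pairs, n_boot=64, seed=s)
        truth = config.theta_total
        err_ivw.append(est.theta - truth)
        err_wm.append(wm.theta - truth)
    return {"bias_ivw": float(np.mean(err_ivw)),
            "bias_weighted_median": float(np.mean(err_wm))}


def egger_intercept_recovery(n_reps: int = 500, seed: int = 0, j: int = 10,
                             mu_alpha: float = 0.02) -> dict:
    """Mean Egger intercept under directional pleiotropy on every instrument.

    With instrument strength independent of the pleiotropic effects, the
    intercept estimates the mean pleiotropy mu_alpha while IVW is biased.
    """
    seeds = _subseeds(seed, n_reps)
    intercepts, err_ivw = [], []
    for s in seeds:
        config = SimulationConfig(j_instruments=j, pleiotropy="directional",
                                  pleiotropy_frac=1.0, mu_alpha=mu_alpha,
                                  sigma_alpha=0.01, seed=s)
        _, pairs = _study_pairs(config)
        _, intercept, _ = egger(pairs)
        est, _ = ivw(pairs)
        intercepts.append(intercept.intercept)
        err_ivw.append(est.theta - config.theta_total)
    return {"mean_intercept": float(np.mean(intercepts)),
            "mu_alpha": mu_alpha,
            "bias_ivw": float(np.mean(err_ivw))}


# ---------------------------------------------------------------------------
# MR-PRESSO operating characteristics


def presso_detection_rate(n_seeds: int = 100, seed: int = 0, j: int = 11,
                          n_sim: int = 1000) -> float:
    """Fraction of runs flagging a planted gross outlier (ratio x10)."""
    seeds = _subseeds(seed, n_seeds)
    hits = 0
    for s in seeds:
        config = SimulationConfig(j_instruments=j, planted_outliers=1, seed=s)
        study, pairs = _study_pairs(config)
        planted = set(study.ground_truth["planted_outlier_ids"])
        result = presso(pairs, n_sim=n_sim, seed=s)
        hits += bool(planted & set(result.outliers))
    return hits / n_seeds


def presso_null_rate(n_seeds: int = 500, seed: int = 0, j: int = 10,
                     n_sim: int = 1000, alpha: float = 0.05) -> float:
    """Global-test rejection rate with no pleiotropy present."""
    seeds = _subseeds(seed, n_seeds)
    hits = 0
    for s in seeds:
        config = SimulationConfig(j_instruments=j, seed=s)
        _, pairs = _study_pairs(config)
        result = presso(pairs, n_sim=n_sim, seed=s)
        hits += result.global_p < alpha
    return hits / n_seeds


# ---------------------------------------------------------------------------
# Mediation recovery


def _joint_mvmr_estimate(study, config: AnalysisConfig):
    """Pooled-instrument multivariable IVW estimate for the exposure."""
    tables = [study.exposure, *study.mediators]
    iset = combine_instruments_mvmr(tables, study.outcome,
                                    p_threshold=config.p_iv,
                                    r2_threshold=config.clump_r2,
                                    window_bp=config.clump_window_bp)
    data = build_mvmr_dataset(tables, study.outcome, iset.ids)
    fit = mvmr_ivw(data, compute_conditional_f=False)
    return fit.estimate_for(study.exposure.trait_name)


def mediation_headline_rate(n_runs: int = 200, seed: int = 0) -> dict:
    """Full-mediation recovery: total effect significant, direct effect null.

    Under the full-mediation preset (no direct effect, two mediators carrying
    theta_total = -0.19) each run checks that (a) the univariable IVW
    estimate is classified significant under the three-exposure Bonferroni
    rule and (b) the joint two-mediator multivariable IVW estimate has
    p > 0.05.  Returns the joint rate and each margin.
    """
    seeds = _subseeds(seed, n_runs)
    aconfig = AnalysisConfig(seed=seed)
    both = uv_sig = mv_null = 0
    for s in seeds:
        study = simulate_study(full_mediation_preset(seed=s))
        pairs, _, _ = select_instruments(study.exposure, study.outcome, aconfig)
        uv, _ = ivw(pairs)
        mv = _joint_mvmr_estimate(study, aconfig)
        a = classify_significance(uv.p_value) == "significant"
        b = mv.p_value > 0.05
        uv_sig += a
        mv_null += b
        both += a and b
    return {"rate": both / n_runs, "uvmr_significant_rate": uv_sig / n_runs,
            "mvmr_null_rate": mv_null / n_runs}


def partial_mediation_coverage(n_runs: int = 200, seed: int = 0) -> float:
    """Joint-model CI coverage of the true direct effect (partial mediation)."""
    seeds = _subseeds(seed, n_runs)
    aconfig = AnalysisConfig(seed=seed)
    hits = 0
    for s in seeds:
        preset = partial_mediation_preset(seed=s)
        study = simulate_study(preset)
        mv = _joint_mvmr_estimate(study, aconfig)
        hits += mv.ci_low <= preset.theta_direct <= mv.ci_high
    return hits / n_runs
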