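"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

A simulation-based global test for horizontal pleiotropy, a per-variant
outlier test with Bonferroni adjustment, an outlier-corrected IVW estimate,
and a distortion test comparing the raw and corrected estimates against
random-removal re-estimates.  Empirical p-values use the +1 correction
p = (1 + #{sim >= obs}) / (n_sim + 1), so they are never exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InsufficientInstruments
from .uvmr import MREstimate, _as_arrays, ivw


@dataclass
class PressoResult:
    """Outcome of the MR-PRESSO procedure."""

    rss_observed: float
    global_p: float
    per_snp_p: dict[str, float]
    outliers: list[str]
    raw_estimate: MREstimate
    corrected_estimate: MREstimate
    distortion_p: Optional[float]
    n_sim: int

    def to_dict(self) -> dict:
        return {
            "rss_observed": self.rss_observed,
            "global_p": self.global_p,
            "per_snp_p": self.per_snp_p,
            "outliers": self.outliers,
            "raw_estimate": self.raw_estimate.to_dict(),
            "corrected_estimate": self.corrected_estimate.to_dict(),
            "distortion_p": self.distortion_p,
            "n_sim": self.n_sim,
        }


def _loo_thetas(bx: np.ndarray, by: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, closed form from running sums."""
    a = bx * by * wy
    b = bx * bx * wy
    return (a.sum() - a) / (b.sum() - b)


def presso(pairs, n_sim: int = 1000, seed: Optional[int] = None,
           outlier_alpha: float = 0.05, global_alpha: float = 0.05) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    (1) The observed residual sum of squares uses leave-one-out IVW
    predictions: RSS = sum_j w_j (b_yj - theta_(-j) b_xj)^2 with w = 1/se_y^2.
    (2) ``n_sim`` replicate datasets are drawn under the no-pleiotropy model
    b_yj* ~ N(theta_(-j) b_xj, se_yj), b_xj* ~ N(b_xj, se_xj); the global p
    is the +1-corrected fraction of replicate RSS >= observed.  (3) Per-SNP
    outlier p-values compare each observed residual term with its replicate
    distribution, Bonferroni-adjusted by J.  (4) With outliers present, the
    corrected estimate is random-effects IVW without them, and the distortion
    test compares the relative estimate change against re-estimates after
    removing equally many random variants.
    """
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < 4:
        raise InsufficientInstruments(f"presso needs >= 4 instruments, got {j}")
    rng = np.random.default_rng(seed)
    wy = 1.0 / sy ** 2

    theta_loo = _loo_thetas(bx, by, wy)
    resid = by - theta_loo * bx
    rss_j_obs = wy * resid ** 2
    rss_obs = float(rss_j_obs.sum())

    # replicate datasets under the null
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    a = bx_star * by_star * wy
    b = bx_star * bx_star * wy
    theta_loo_star = (a.sum(axis=1, keepdims=True) - a) / (b.sum(axis=1, keepdims=True) - b)
    resid_star = by_star - theta_loo_star * bx_star
    rss_j_star = wy * resid_star ** 2
    rss_star = rss_j_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_p_raw = (1 + np.sum(rss_j_star >= rss_j_obs[None, :], axis=0)) / (n_sim + 1)
    per_p_adj = np.minimum(1.0, per_p_raw * j)
    outlier_mask = per_p_adj < outlier_alpha
    outliers = [s for s, o in zip(ids, outlier_mask) if o]

    frame = pd.DataFrame({"snp_id": ids, "beta_exposure": bx, "se_exposure": sx,
                          "beta_outcome": by, "se_outcome": sy})
    raw, _ = ivw(frame)
    raw = _relabel(raw, "presso_raw")
    distortion_p = None
    if outliers:
        kept = frame.loc[~outlier_mask].reset_index(drop=True)
        corrected, _ = ivw(kept)
        corrected = _relabel(corrected, "presso_corrected")
        n_out = int(outlier_mask.sum())
        if n_out < j and raw.theta != 0:
            d_obs = (corrected.theta - raw.theta) / abs(raw.theta)
            a0 = bx * by * wy
            b0 = bx * bx * wy
            d_null = np.empty(n_sim)
            for k in range(n_sim):
                drop = rng.choice(j, size=n_out, replace=False)
                theta_b = (a0.sum() - a0[drop].sum()) / (b0.sum() - b0[drop].sum())
                d_null[k] = (theta_b - raw.theta) / abs(raw.theta)
            distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    else:
        corrected = _relabel(raw, "presso_corrected")

    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        per_snp_p={s: float(p) for s, p in zip(ids, per_p_adj)},
        outliers=outliers,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
    )


def _relabel(est: MREstimate, method: str) -> MREstimate:
    return MREstimate(method=method, theta=est.theta, se=est.se, ci_low=est.ci_low,
                      ci_high=est.ci_high, p_value=est.p_value, n_snp=est.n_snp)
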