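"""Univariable two-sample MR estimators and sensitivity analyses.

Implements the Wald ratio, inverse-variance-weighted (IVW) estimation with
multiplicative random effects, MR-Egger regression with its intercept
(pleiotropy) test, weighted/simple median, the mode-based estimate,
maximum likelihood, Cochran's Q heterogeneity statistic and leave-one-out
analysis.  All estimators consume harmonized exposure/outcome effect pairs;
ratio standard errors use the first-order delta method,
se_j = se_outcome / |beta_exposure|.

Confidence intervals are normal-theory 95% by default.  Every stochastic
operation (bootstrap standard errors) takes an explicit seed and is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConvergenceError, DataError, InsufficientInstruments
from .sumstats import HarmonizedPair, HarmonizedSet

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Data plumbing


def _as_arrays(pairs):
    """Extract (ids, bx, sx, by, sy) from pairs in any accepted form.

    Accepts a HarmonizedSet (retained pairs are used), a sequence of
    HarmonizedPair, or a DataFrame with the harmonized column names.
    """
    if isinstance(pairs, HarmonizedSet):
        pairs = pairs.retained
    if isinstance(pairs, pd.DataFrame):
        ids = [str(s) for s in pairs["snp_id"]] if "snp_id" in pairs else \
            [f"snp_{i}" for i in range(len(pairs))]
        return (ids,
                pairs["beta_exposure"].to_numpy(float),
                pairs["se_exposure"].to_numpy(float),
                pairs["beta_outcome"].to_numpy(float),
                pairs["se_outcome"].to_numpy(float))
    pairs = list(pairs)
    ids = [p.snp_id for p in pairs]
    bx = np.array([p.beta_exposure for p in pairs], float)
    sx = np.array([p.se_exposure for p in pairs], float)
    by = np.array([p.beta_outcome for p in pairs], float)
    sy = np.array([p.se_outcome for p in pairs], float)
    return ids, bx, sx, by, sy


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with first-order standard error."""

    snp_id: str
    theta_j: float
    se_j: float

    @property
    def weight(self) -> float:
        return self.se_j ** -2


@dataclass(frozen=True)
class MREstimate:
    """A method-labelled causal estimate on the outcome's beta scale."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snp: int

    @property
    def odds_ratio(self) -> float:
        """exp(theta); meaningful when the outcome is binary (log-odds)."""
        return math.exp(self.theta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_dict(self) -> dict:
        lo, hi = self.or_ci
        return {"method": self.method, "theta": self.theta, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p_value, "n_snp": self.n_snp,
                "odds_ratio": self.odds_ratio, "or_ci_low": lo, "or_ci_high": hi}

    def summary(self) -> str:
        lo, hi = self.or_ci
        return (f"{self.method}: theta={self.theta:.4f} (se {self.se:.4f}), "
                f"OR={self.odds_ratio:.3f} [{lo:.3f}-{hi:.3f}], "
                f"p={self.p_value:.3g}, n_snp={self.n_snp}")


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom and chi-square p-value."""

    q: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"Q": self.q, "df": self.df, "p": self.p_value}


@dataclass(frozen=True)
class PleiotropyTest:
    """MR-Egger intercept: directional-pleiotropy test."""

    intercept: float
    se: float
    p_value: float

    def to_dict(self) -> dict:
        return {"egger_intercept": self.intercept, "se": self.se, "p": self.p_value}


def _estimate(method: str, theta: float, se: float, n_snp: int) -> MREstimate:
    z = theta / se if se > 0 else math.inf * np.sign(theta or 1.0)
    p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 0.0
    return MREstimate(method=method, theta=float(theta), se=float(se),
                      ci_low=float(theta - Z95 * se), ci_high=float(theta + Z95 * se),
                      p_value=float(min(1.0, p)), n_snp=int(n_snp))


# ---------------------------------------------------------------------------
# Estimators


def wald_ratio(pair: HarmonizedPair) -> RatioEstimate:
    """Single-variant causal ratio beta_out/beta_exp with delta-method SE."""
    if pair.beta_exposure == 0:
        raise DataError(f"{pair.snp_id}: beta_exposure is 0; Wald ratio undefined")
    theta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return RatioEstimate(snp_id=pair.snp_id, theta_j=theta, se_j=se)


def ratio_estimates(pairs) -> list[RatioEstimate]:
    ids, bx, sx, by, sy = _as_arrays(pairs)
    if np.any(bx == 0):
        bad = [i for i, b in zip(ids, bx) if b == 0]
        raise DataError(f"zero exposure beta for {bad}; Wald ratio undefined")
    return [RatioEstimate(i, float(b), float(s))
            for i, b, s in zip(ids, by / bx, sy / np.abs(bx))]


def ivw(pairs, effects_model: str = "multiplicative_random"):
    """Inverse-variance-weighted estimate with Cochran's Q.

    theta_hat = sum(w theta_j)/sum(w) with w = 1/se_j^2 from the Wald ratios
    (equivalently weighted least squares of beta_out on beta_exp through the
    origin with weights 1/se_out^2).  The multiplicative random-effects SE
    inflates the fixed-effect SE by sqrt(max(1, Q/(J-1))).  With a single
    instrument the result degenerates to the Wald ratio (labelled).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise DataError(f"unknown effects_model {effects_model!r}")
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j == 0:
        raise DataError("ivw: empty input")
    theta_j = by / bx
    w = (bx / sy) ** 2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if j == 1:
        est = _estimate("wald_ratio (single SNP)", theta, se_fixed, 1)
        return est, HeterogeneityResult(q=0.0, df=0, p_value=1.0)
    q = float(np.sum(w * (theta_j - theta) ** 2))
    df = j - 1
    scale = math.sqrt(max(1.0, q / df)) if effects_model == "multiplicative_random" else 1.0
    label = "ivw_random" if effects_model == "multiplicative_random" else "ivw_fixed"
    est = _estimate(label, theta, se_fixed * scale, j)
    het = HeterogeneityResult(q=q, df=df, p_value=float(stats.chi2.sf(q, df)))
    return est, het


def cochran_q(pairs, theta_ref: float) -> HeterogeneityResult:
    """Cochran's Q about a reference effect: Q = sum w_j (theta_j - ref)^2."""
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < 2:
        raise DataError("cochran_q needs >= 2 pairs")
    theta_j = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (theta_j - theta_ref) ** 2))
    return HeterogeneityResult(q=q, df=j - 1, p_value=float(stats.chi2.sf(q, j - 1)))


def egger(pairs, t_dist: bool = False):
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Pairs are oriented so beta_exposure >= 0 (both betas negated together).
    Weights are 1/se_out^2; standard errors carry the multiplicative residual
    dispersion sqrt(max(1, RSS_w/(J-2))), never shrunk below 1.  The
    intercept is the directional-pleiotropy test.  Inference uses the normal
    reference by default (``t_dist=True`` switches to t with J-2 df).
    """
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < 3:
        raise InsufficientInstruments(f"egger needs >= 3 instruments, got {j}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy ** 2
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - x @ coef
    rss = float(np.sum(w * resid ** 2))
    df = j - 2
    phi = max(1.0, rss / df)
    cov = np.linalg.inv(xtwx) * phi
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    def pval(est, se):
        z = abs(est / se)
        return float(2 * (stats.t.sf(z, df) if t_dist else stats.norm.sf(z)))

    crit = stats.t.ppf(0.975, df) if t_dist else Z95
    slope = MREstimate(method="egger", theta=float(coef[1]), se=se_slope,
                       ci_low=float(coef[1] - crit * se_slope),
                       ci_high=float(coef[1] + crit * se_slope),
                       p_value=pval(coef[1], se_slope), n_snp=j)
    intercept = PleiotropyTest(intercept=float(coef[0]), se=se_int,
                               p_value=pval(coef[0], se_int))
    het = HeterogeneityResult(q=rss, df=df, p_value=float(stats.chi2.sf(rss, df)))
    return slope, intercept, het


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: positions p_j = (S_j - w_j/2)/S_J."""
    order = np.argsort(theta, kind="mergesort")
    th = theta[order]
    w = weights[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    return float(np.interp(0.5, p, th))


def _bootstrap_median_se(theta: np.ndarray, se: np.ndarray, weights: np.ndarray,
                         n_boot: int, seed: Optional[int]) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(n_boot, len(theta)))
    # vectorised weighted median over rows
    order = np.argsort(draws, axis=1, kind="mergesort")
    th = np.take_along_axis(draws, order, axis=1)
    w = weights[order]
    s = np.cumsum(w, axis=1)
    p = (s - 0.5 * w) / s[:, -1:]
    est = np.array([np.interp(0.5, p[i], th[i]) for i in range(n_boot)])
    return float(est.std(ddof=0))


def weighted_median(pairs, n_boot: int = 1000, seed: Optional[int] = None,
                    min_snps: int = 3) -> MREstimate:
    """Weighted median of the per-variant ratios (inverse-variance weights).

    Consistent when instruments contributing >50% of the weight are valid.
    The SE is the standard deviation of the estimate over ``n_boot``
    parametric-bootstrap resamples theta_j* ~ N(theta_j, se_j).
    """
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < min_snps:
        raise InsufficientInstruments(f"weighted_median needs >= {min_snps} instruments, got {j}")
    theta_j = by / bx
    se_j = sy / np.abs(bx)
    w = se_j ** -2
    theta = _weighted_median(theta_j, w)
    se = _bootstrap_median_se(theta_j, se_j, w, n_boot, seed)
    if se == 0:  # degenerate (identical ratios)
        se = float(np.min(se_j) / math.sqrt(j))
    return _estimate("weighted_median", theta, se, j)


def simple_median(pairs, n_boot: int = 1000, seed: Optional[int] = None,
                  min_snps: int = 3) -> MREstimate:
    """Weighted median with all weights equal."""
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < min_snps:
        raise InsufficientInstruments(f"simple_median needs >= {min_snps} instruments, got {j}")
    theta_j = by / bx
    se_j = sy / np.abs(bx)
    w = np.ones(j)
    theta = _weighted_median(theta_j, w)
    se = _bootstrap_median_se(theta_j, se_j, w, n_boot, seed)
    if se == 0:
        se = float(np.min(se_j) / math.sqrt(j))
    est = _estimate("simple_median", theta, se, j)
    return est


def _mode_estimate(theta: np.ndarray, weights: np.ndarray,
                   bandwidth_factor: float) -> float:
    """Argmax of the weighted normal-kernel density of the ratios."""
    j = len(theta)
    sd = float(np.std(theta, ddof=1)) if j > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * spread * j ** (-1 / 5)
    if h <= 0:
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 1024)
    dens = np.sum(weights[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2),
                  axis=1)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(pairs, bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: Optional[int] = None, min_snps: int = 3) -> MREstimate:
    """Mode-based estimate: densest cluster of ratio estimates.

    Normal-kernel weighted density with modified Silverman bandwidth
    h = phi * 0.9 * min(sd, IQR/1.349) * J^(-1/5); the estimate is the
    density argmax on a fixed fine grid spanning the ratio range.  When all
    ratios coincide the common ratio is returned directly.
    """
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < min_snps:
        raise InsufficientInstruments(f"weighted_mode needs >= {min_snps} instruments, got {j}")
    theta_j = by / bx
    se_j = sy / np.abs(bx)
    w = se_j ** -2
    w = w / w.sum()
    theta = _mode_estimate(theta_j, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta_j, se_j, size=(n_boot, j))
    boots = np.array([_mode_estimate(d, w, bandwidth_factor) for d in draws])
    se = float(boots.std(ddof=0))
    if se == 0:
        se = float(np.min(se_j) / math.sqrt(j))
    return _estimate("weighted_mode", theta, se, j)


def max_likelihood(pairs, tol: float = 1e-10) -> MREstimate:
    """Bivariate-normal maximum-likelihood estimate of the causal effect.

    Model: b_xj ~ N(xi_j, se_xj^2), b_yj ~ N(theta*xi_j, se_yj^2) with
    independent errors.  The profile objective in theta is
    g(theta) = sum (b_yj - theta b_xj)^2 / (se_yj^2 + theta^2 se_xj^2),
    minimised from a deterministic start at the IVW estimate.  The SE comes
    from the observed information for theta (Schur complement over the
    nuisance xi).
    """
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < 1:
        raise DataError("max_likelihood: empty input")

    def g(theta):
        return float(np.sum((by - theta * bx) ** 2 / (sy ** 2 + theta ** 2 * sx ** 2)))

    start = float(np.sum(bx * by / sy ** 2) / np.sum(bx ** 2 / sy ** 2))
    res = optimize.minimize(lambda t: g(t[0]), x0=[start], method="Nelder-Mead",
                            options={"xatol": tol, "fatol": tol, "maxiter": 10000})
    if not res.success:
        raise ConvergenceError(f"max_likelihood failed to converge: {res.message}")
    theta = float(res.x[0])
    # observed information for theta via Schur complement
    xi = (bx / sx ** 2 + theta * by / sy ** 2) / (1.0 / sx ** 2 + theta ** 2 / sy ** 2)
    h_tt = np.sum(xi ** 2 / sy ** 2)
    h_txi = (2 * theta * xi - by) / sy ** 2
    h_xixi = 1.0 / sx ** 2 + theta ** 2 / sy ** 2
    info = float(h_tt - np.sum(h_txi ** 2 / h_xixi))
    if info <= 0:
        raise ConvergenceError("max_likelihood: non-positive observed information")
    return _estimate("max_likelihood", theta, info ** -0.5, j)


def leave_one_out(pairs) -> pd.DataFrame:
    """Random-effects IVW re-estimated with each variant excluded in turn.

    Returns one row per excluded variant plus the all-variant estimate
    labelled ``"none"``.
    """
    ids, bx, sx, by, sy = _as_arrays(pairs)
    j = len(ids)
    if j < 2:
        raise DataError("leave_one_out needs >= 2 pairs")
    frame = pd.DataFrame({"snp_id": ids, "beta_exposure": bx, "se_exposure": sx,
                          "beta_outcome": by, "se_outcome": sy})
    rows = []
    for excl in range(j):
        sub = frame.drop(index=excl)
        est, _ = ivw(sub)
        rows.append({"excluded": ids[excl], **est.to_dict()})
    full, _ = ivw(frame)
    rows.append({"excluded": "none", **full.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / results wrappers (statsmodels-style surface)

_METHOD_MIN_SNPS = {"ivw": 1, "egger": 3, "weighted_median": 3,
                    "simple_median": 3, "weighted_mode": 3, "max_likelihood": 2}


class UnivariableMR:
    """Univariable two-sample MR model over a set of harmonized pairs.

    ``fit(method=...)`` returns a single :class:`MREstimate`; ``fit_all()``
    runs every method feasible at the available instrument count and returns
    a :class:`UVMRResults` bundle with heterogeneity, pleiotropy and
    leave-one-out diagnostics.
    """

    def __init__(self, pairs):
        self._pairs = pairs
        ids, bx, sx, by, sy = _as_arrays(pairs)
        self.snp_ids = ids
        self.n_snp = len(ids)

    @classmethod
    def from_harmonized(cls, hset: HarmonizedSet) -> "UnivariableMR":
        return cls(hset.retained)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "UnivariableMR":
        return cls(frame)

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        if method == "ivw":
            return ivw(self._pairs, **kwargs)[0]
        if method == "egger":
            return egger(self._pairs, **kwargs)[0]
        if method == "weighted_median":
            return weighted_median(self._pairs, **kwargs)
        if method == "simple_median":
            return simple_median(self._pairs, **kwargs)
        if method == "weighted_mode":
            return weighted_mode(self._pairs, **kwargs)
        if method == "max_likelihood":
            return max_likelihood(self._pairs, **kwargs)
        raise DataError(f"unknown method {method!r}")

    def heterogeneity(self) -> HeterogeneityResult:
        return ivw(self._pairs)[1]

    def egger_intercept(self) -> PleiotropyTest:
        return egger(self._pairs)[1]

    def leave_one_out(self) -> pd.DataFrame:
        return leave_one_out(self._pairs)

    def fit_all(self, n_boot: int = 1000, seed: Optional[int] = None) -> "UVMRResults":
        estimates: dict[str, MREstimate] = {}
        unavailable: dict[str, str] = {}
        seeds = _spawn_seeds(seed, 3)
        for method, floor in _METHOD_MIN_SNPS.items():
            if self.n_snp < floor:
                unavailable[method] = f"needs >= {floor} SNPs, have {self.n_snp}"
                continue
            kwargs = {}
            if method == "weighted_median":
                kwargs = {"n_boot": n_boot, "seed": seeds[0]}
            elif method == "simple_median":
                kwargs = {"n_boot": n_boot, "seed": seeds[1]}
            elif method == "weighted_mode":
                kwargs = {"n_boot": n_boot, "seed": seeds[2]}
            estimates[method] = self.fit(method, **kwargs)
        het = self.heterogeneity() if self.n_snp >= 2 else None
        pleio = self.egger_intercept() if self.n_snp >= 3 else None
        loo = self.leave_one_out() if self.n_snp >= 2 else None
        return UVMRResults(model=self, estimates=estimates, unavailable=unavailable,
                           heterogeneity=het, pleiotropy=pleio, loo=loo)


def _spawn_seeds(seed: Optional[int], n: int) -> list[Optional[int]]:
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


@dataclass
class UVMRResults:
    """Estimates from every feasible univariable method plus diagnostics."""

    model: UnivariableMR
    estimates: dict[str, MREstimate]
    unavailable: dict[str, str]
    heterogeneity: Optional[HeterogeneityResult]
    pleiotropy: Optional[PleiotropyTest]
    loo: Optional[pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(status="ok", **e.to_dict()) for e in self.estimates.values()]
        rows += [{"method": m, "status": f"unavailable ({why})"}
                 for m, why in self.unavailable.items()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Univariable MR ({self.model.n_snp} instruments)"]
        lines += ["  " + e.summary() for e in self.estimates.values()]
        for m, why in self.unavailable.items():
            lines.append(f"  {m}: unavailable ({why})")
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(f"  Cochran Q = {h.q:.3f} (df {h.df}), p = {h.p_value:.3g}")
        if self.pleiotropy is not None:
            pt = self.pleiotropy
            lines.append(f"  Egger intercept = {pt.intercept:.4f} (se {pt.se:.4f}), "
                         f"p = {pt.p_value:.3g}")
        return "\n".join(lines)
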