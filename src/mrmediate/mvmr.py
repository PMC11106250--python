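"""Multivariable MR: IVW, Egger and Lasso estimators with conditional F.

The multivariable model regresses outcome associations on an L x K matrix of
exposure associations (no intercept for IVW; an intercept for Egger), with
weights 1/se_outcome^2 and multiplicative overdispersion of the standard
errors, sqrt(max(1, Q/df)).  Exposure coefficients are direct effects
conditional on the other exposures in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (CollinearityError, ConfigurationError, DataError,
                         InsufficientInstruments, SelectionFailure)
from .sumstats import COMPLEMENT, SummaryStatsTable
from .uvmr import Z95, MREstimate, HeterogeneityResult, PleiotropyTest, _estimate


@dataclass
class MVMRDataset:
    """Aligned effects of L instruments on K exposures and one outcome.

    ``bx``/``sx`` are L x K arrays of exposure betas and SEs; ``by``/``sy``
    are length-L outcome arrays.  All effects refer to the same effect
    allele per row.  ``cross_cov`` optionally holds an assumed K x K
    cross-exposure sampling correlation (default: zero, non-overlapping
    samples).
    """

    ids: list[str]
    exposures: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    cross_cov: Optional[np.ndarray] = None

    def __post_init__(self):
        self.bx = np.asarray(self.bx, float)
        self.sx = np.asarray(self.sx, float)
        self.by = np.asarray(self.by, float)
        self.sy = np.asarray(self.sy, float)
        if self.bx.ndim == 1:
            self.bx = self.bx[:, None]
        if self.sx.ndim == 1:
            self.sx = self.sx[:, None]
        l, k = self.bx.shape
        if len(self.exposures) != k:
            raise ConfigurationError("exposure names do not match bx columns")
        if self.sx.shape != (l, k) or self.by.shape != (l,) or self.sy.shape != (l,):
            raise ConfigurationError("inconsistent MVMR array shapes")
        if len(self.ids) != l:
            raise ConfigurationError("ids length does not match rows")
        if (np.isnan(self.bx).any() or np.isnan(self.by).any()
                or np.isnan(self.sx).any() or np.isnan(self.sy).any()):
            raise DataError("MVMRDataset contains missing cells")
        if (self.sx <= 0).any() or (self.sy <= 0).any():
            raise DataError("all SEs must be > 0")

    @property
    def n_instruments(self) -> int:
        return self.bx.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]

    def subset(self, rows: Sequence[int]) -> "MVMRDataset":
        rows = list(rows)
        return MVMRDataset(ids=[self.ids[i] for i in rows], exposures=self.exposures,
                           bx=self.bx[rows], sx=self.sx[rows],
                           by=self.by[rows], sy=self.sy[rows], cross_cov=self.cross_cov)


def build_mvmr_dataset(exposure_tables: Sequence[SummaryStatsTable],
                       outcome: SummaryStatsTable,
                       ids: Sequence[str]) -> MVMRDataset:
    """Assemble an MVMRDataset for ``ids``, aligning all tables' alleles.

    The first exposure table's effect allele per variant is the reference;
    betas from other tables are negated when their alleles are swapped
    (directly or on the complementary strand).  Variants with incompatible
    alleles in any table are dropped.
    """
    ref = exposure_tables[0]
    kept, bx, sx, by, sy = [], [], [], [], []
    for snp in ids:
        if snp not in ref or snp not in outcome:
            continue
        ref_rec = ref.get(snp)
        row_b, row_s, ok = [], [], True
        for tab in exposure_tables:
            if snp not in tab:
                ok = False
                break
            sign = _allele_sign(ref_rec, tab.get(snp))
            if sign == 0:
                ok = False
                break
            rec = tab.get(snp)
            row_b.append(sign * rec.beta)
            row_s.append(rec.se)
        if not ok:
            continue
        sign = _allele_sign(ref_rec, outcome.get(snp))
        if sign == 0:
            continue
        out_rec = outcome.get(snp)
        kept.append(snp)
        bx.append(row_b)
        sx.append(row_s)
        by.append(sign * out_rec.beta)
        sy.append(out_rec.se)
    if not kept:
        raise DataError("build_mvmr_dataset: no alignable variants")
    return MVMRDataset(ids=kept, exposures=[t.trait_name for t in exposure_tables],
                       bx=np.array(bx), sx=np.array(sx),
                       by=np.array(by), sy=np.array(sy))


def _allele_sign(ref, other) -> int:
    """+1 if aligned, -1 if effect/other swapped (incl. strand), 0 if incompatible."""
    if other.effect_allele == ref.effect_allele:
        return 1
    if ref.other_allele is not None and other.effect_allele == ref.other_allele:
        return -1
    comp = COMPLEMENT[other.effect_allele]
    if comp == ref.effect_allele:
        return 1
    if ref.other_allele is not None and comp == ref.other_allele:
        return -1
    return 0


@dataclass
class MVMRResult:
    """Per-exposure direct-effect estimates from one multivariable method."""

    method: str
    exposures: list[str]
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult
    conditional_f: Optional[list[float]] = None
    intercept: Optional[PleiotropyTest] = None
    retained_ids: Optional[list[str]] = None
    lasso_lambda: Optional[float] = None

    def estimate_for(self, exposure: str) -> MREstimate:
        return self.estimates[self.exposures.index(exposure)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (name, est) in enumerate(zip(self.exposures, self.estimates)):
            row = dict(exposure=name, **est.to_dict())
            if self.conditional_f is not None:
                row["conditional_f"] = self.conditional_f[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"MVMR ({self.method}, L={self.estimates[0].n_snp} instruments)"]
        for name, est in zip(self.exposures, self.estimates):
            lines.append(f"  {name}: {est.summary()}")
        if self.intercept is not None:
            lines.append(f"  intercept = {self.intercept.intercept:.4f}, "
                         f"p = {self.intercept.p_value:.3g}")
        return "\n".join(lines)


def _check_rank(x: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name columns that are (nearly) linear combinations of the others
        offending = []
        for k in range(x.shape[1]):
            others = np.delete(x, k, axis=1)
            if others.shape[1] == 0:
                if np.allclose(x[:, k], 0):
                    offending.append(names[k])
                continue
            coef, res, rank, _ = np.linalg.lstsq(others, x[:, k], rcond=None)
            fitted = others @ coef
            ss_res = float(np.sum((x[:, k] - fitted) ** 2))
            ss_tot = float(np.sum(x[:, k] ** 2))
            if ss_tot == 0 or ss_res / ss_tot < 1e-10:
                offending.append(names[k])
        raise CollinearityError(offending or list(names))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, df: int):
    """Weighted LS with multiplicative overdispersion; returns (coef, se, q, phi)."""
    xtw = x.T * w
    xtwx = xtw @ x
    coef = np.linalg.solve(xtwx, xtw @ y)
    resid = y - x @ coef
    q = float(np.sum(w * resid ** 2))
    phi = max(1.0, q / df) if df > 0 else 1.0
    cov = np.linalg.inv(xtwx) * phi
    se = np.sqrt(np.diag(cov))
    return coef, se, q, phi


def mvmr_ivw(data: MVMRDataset, compute_conditional_f: bool = True) -> MVMRResult:
    """Multivariable IVW: WLS of outcome betas on the exposure-beta matrix.

    No intercept; weights 1/se_outcome^2; SEs inflated by
    sqrt(max(1, Q/(L-K))).  With K = 1 this is exactly univariable IVW.
    """
    l, k = data.bx.shape
    if l <= k:
        raise InsufficientInstruments(f"mvmr_ivw needs L > K, got L={l}, K={k}")
    _check_rank(data.bx, data.exposures)
    w = 1.0 / data.sy ** 2
    df = l - k
    coef, se, q, phi = _wls(data.bx, data.by, w, df)
    estimates = [_estimate(f"mvmr_ivw[{name}]", c, s, l)
                 for name, c, s in zip(data.exposures, coef, se)]
    het = HeterogeneityResult(q=q, df=df, p_value=float(stats.chi2.sf(q, df)))
    cf = [conditional_f(data, i) for i in range(k)] if compute_conditional_f else None
    return MVMRResult(method="ivw", exposures=list(data.exposures),
                      estimates=estimates, heterogeneity=het, conditional_f=cf)


def mvmr_egger(data: MVMRDataset, orient_index: int = 0,
               compute_conditional_f: bool = True) -> MVMRResult:
    """Multivariable MR-Egger: WLS with an intercept, rows sign-oriented.

    Every row is negated as a whole when the chosen exposure's beta is
    negative, so that column is >= 0; the intercept is the directional
    pleiotropy term.
    """
    l, k = data.bx.shape
    if l <= k + 1:
        raise InsufficientInstruments(f"mvmr_egger needs L > K+1, got L={l}, K={k}")
    sign = np.where(data.bx[:, orient_index] < 0, -1.0, 1.0)
    bx = data.bx * sign[:, None]
    by = data.by * sign
    _check_rank(bx, data.exposures)
    w = 1.0 / data.sy ** 2
    x = np.column_stack([np.ones(l), bx])
    df = l - k - 1
    coef, se, q, phi = _wls(x, by, w, df)
    estimates = [_estimate(f"mvmr_egger[{name}]", c, s, l)
                 for name, c, s in zip(data.exposures, coef[1:], se[1:])]
    z = abs(coef[0] / se[0])
    intercept = PleiotropyTest(intercept=float(coef[0]), se=float(se[0]),
                               p_value=float(2 * stats.norm.sf(z)))
    het = HeterogeneityResult(q=q, df=df, p_value=float(stats.chi2.sf(q, df)))
    cf = [conditional_f(data, i) for i in range(k)] if compute_conditional_f else None
    return MVMRResult(method="egger", exposures=list(data.exposures),
                      estimates=estimates, heterogeneity=het, conditional_f=cf,
                      intercept=intercept)


def mvmr_lasso(data: MVMRDataset, lambda_grid: Optional[np.ndarray] = None,
               heterogeneity_alpha: float = 0.05,
               compute_conditional_f: bool = True) -> MVMRResult:
    """MVMR-Lasso: L1-penalised per-variant intercepts flag pleiotropic SNPs.

    The IVW regression is augmented with one unpenalised slope per exposure
    and one L1-penalised intercept alpha_j per variant.  Over a decreasing
    lambda grid, variants with alpha_j = 0 form the candidate "valid" set;
    the largest valid set whose post-selection IVW heterogeneity Q is within
    the chi-square(1 - alpha) bound at its degrees of freedom is selected,
    and the final estimates are post-selection multivariable IVW on it.
    """
    l, k = data.bx.shape
    if l <= k:
        raise InsufficientInstruments(f"mvmr_lasso needs L > K, got L={l}, K={k}")
    _check_rank(data.bx, data.exposures)
    w = 1.0 / data.sy ** 2

    # lambda_max: smallest penalty at which all alpha_j stay zero
    coef0, _, _, _ = _wls(data.bx, data.by, w, l - k)
    resid0 = data.by - data.bx @ coef0
    lam_max = float(np.max(np.abs(resid0) * w))
    if lambda_grid is None:
        if lam_max <= 0:
            lambda_grid = np.array([1.0])
        else:
            lambda_grid = np.geomspace(lam_max * 1.0001, lam_max * 1e-4, 60)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    candidate_sets: dict[tuple, float] = {}  # valid-set -> largest lambda producing it
    full = tuple(range(l))
    candidate_sets[full] = float(lambda_grid[0])
    for lam in lambda_grid:
        alpha = _lasso_intercepts(data.bx, data.by, w, lam)
        valid = tuple(i for i in range(l) if alpha[i] == 0.0)
        if valid not in candidate_sets:
            candidate_sets[valid] = float(lam)

    # largest valid set passing the heterogeneity stopping rule
    for valid in sorted(candidate_sets, key=len, reverse=True):
        if len(valid) <= k:
            continue
        sub = data.subset(valid)
        try:
            fit = mvmr_ivw(sub, compute_conditional_f=False)
        except CollinearityError:
            continue
        bound = stats.chi2.ppf(1 - heterogeneity_alpha, len(valid) - k)
        if fit.heterogeneity.q <= bound:
            estimates = [_estimate(f"mvmr_lasso[{name}]", e.theta, e.se, len(valid))
                         for name, e in zip(data.exposures, fit.estimates)]
            cf = [conditional_f(data, i) for i in range(k)] if compute_conditional_f else None
            return MVMRResult(method="lasso", exposures=list(data.exposures),
                              estimates=estimates, heterogeneity=fit.heterogeneity,
                              conditional_f=cf,
                              retained_ids=[data.ids[i] for i in valid],
                              lasso_lambda=candidate_sets[valid])
    raise SelectionFailure("mvmr_lasso: no lambda admits a valid set of size > K "
                           "within the heterogeneity bound")


def _lasso_intercepts(bx: np.ndarray, by: np.ndarray, w: np.ndarray,
                      lam: float, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Coordinate descent for 0.5*sum w_j (y_j - x_j theta - a_j)^2 + lam*sum|a_j|."""
    l, k = bx.shape
    alpha = np.zeros(l)
    for _ in range(max_iter):
        xtw = bx.T * w
        theta = np.linalg.solve(xtw @ bx, xtw @ (by - alpha))
        r = by - bx @ theta
        new_alpha = np.sign(r) * np.maximum(0.0, np.abs(r) - lam / w)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha


def conditional_f(data: MVMRDataset, exposure_index: int,
                  cross_cov: Optional[np.ndarray] = None) -> float:
    """Conditional instrument-strength F for one exposure in the MVMR model.

    Weighted no-intercept regression of the target exposure's instrument
    betas on the other exposures' betas (weights from the target exposure's
    SEs, combined with the assumed cross-exposure sampling correlation when
    given); F = Q_x / (L - K + 1) with Q_x the weighted residual sum of
    squares.  With K = 1 this reduces to the mean per-variant (beta/SE)^2.
    """
    l, k = data.bx.shape
    if l <= k:
        raise InsufficientInstruments(f"conditional_f needs L > K, got L={l}, K={k}")
    target = data.bx[:, exposure_index]
    s_target = data.sx[:, exposure_index]
    others = np.delete(data.bx, exposure_index, axis=1)
    if cross_cov is None and data.cross_cov is not None:
        cross_cov = data.cross_cov
    w = 1.0 / s_target ** 2
    if others.shape[1] == 0:
        q_x = float(np.sum(w * target ** 2))
        return q_x / (l - k + 1)
    xtw = others.T * w
    gram = xtw @ others
    if np.linalg.matrix_rank(others) < others.shape[1]:
        coef, *_ = np.linalg.lstsq(others * np.sqrt(w)[:, None],
                                   target * np.sqrt(w), rcond=None)
    else:
        coef = np.linalg.solve(gram, xtw @ target)
    if cross_cov is not None:
        # refine weights with the delta-method variance of the residual
        s_others = np.delete(data.sx, exposure_index, axis=1)
        corr = np.asarray(cross_cov, float)
        idx = [i for i in range(k) if i != exposure_index]
        var = s_target ** 2
        for a, ia in enumerate(idx):
            var = var + coef[a] ** 2 * s_others[:, a] ** 2
            var = var - 2 * coef[a] * corr[exposure_index, ia] * s_target * s_others[:, a]
        w = 1.0 / np.maximum(var, 1e-300)
        xtw = others.T * w
        try:
            coef = np.linalg.solve(xtw @ others, xtw @ target)
        except np.linalg.LinAlgError:
            pass
    resid = target - others @ coef
    q_x = float(np.sum(w * resid ** 2))
    return q_x / (l - k + 1)


class MultivariableMR:
    """Multivariable MR model over an :class:`MVMRDataset`.

    ``fit(method=...)`` dispatches to IVW (default), Egger or Lasso and
    returns an :class:`MVMRResult`.
    """

    def __init__(self, data: MVMRDataset):
        self.data = data

    @classmethod
    def from_tables(cls, exposure_tables: Sequence[SummaryStatsTable],
                    outcome: SummaryStatsTable, ids: Sequence[str]) -> "MultivariableMR":
        return cls(build_mvmr_dataset(exposure_tables, outcome, ids))

    def fit(self, method: str = "ivw", **kwargs) -> MVMRResult:
        if method == "ivw":
            return mvmr_ivw(self.data, **kwargs)
        if method == "egger":
            return mvmr_egger(self.data, **kwargs)
        if method == "lasso":
            return mvmr_lasso(self.data, **kwargs)
        raise DataError(f"unknown MVMR method {method!r}")

    def conditional_f(self, exposure_index: int, **kwargs) -> float:
        return conditional_f(self.data, exposure_index, **kwargs)
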