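"""Seeded generator of two-sample GWAS summary statistics under mediation.

The generator draws per-variant effects under an explicit causal diagram

    instruments -> exposure -> mediators -> binary outcome
                      \\__________direct__________/

with configurable direct effect, exposure->mediator and mediator->outcome
effects, instrument strength and horizontal pleiotropy.  Only summary-level
data are generated: observed betas are the true per-allele effects plus
independent normal noise at analytic standard errors,
se = 1/sqrt(2 n p (1-p)) for standardized continuous traits and
se = 1/sqrt(2 n p (1-p) v (1-v)) for a binary outcome with case fraction v
(betas on the log-odds scale).  Exposure, mediator and outcome noise are
mutually independent (non-overlapping samples).

Defaults mirror a blood-proteome exposure study (n = 35,892), a glycaemic
mediator consortium (n = 200,622) and a case-control dementia outcome
(n = 63,926, 34.4% cases), with instrument strength spanning per-variant
F of roughly 30-450.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .sumstats import LDReference, SummaryStatsTable, _FIELDS

#: non-palindromic effect/other allele pairs used for generated variants
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                 ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]

PLEIOTROPY_MODELS = ("none", "balanced", "directional", "inside_violating")


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic two-sample MR study.

    ``j_instruments`` variants affect the exposure (true effect
    gamma_j = z_j * se_exposure_j with z drawn from ``instrument_z_range``,
    effect alleles oriented exposure-increasing); each of ``k_mediators``
    additionally has ``j_mediator_instruments`` variants of its own.
    ``theta_direct`` is the direct exposure->outcome effect (log-odds per
    unit exposure); ``tau``/``rho`` are the exposure->mediator and
    mediator->outcome effects, so the total effect is
    theta_direct + sum_k tau_k * rho_k.

    Pleiotropy adds a per-variant outcome effect alpha_j to a fraction
    ``pleiotropy_frac`` of the exposure instruments: balanced
    (N(0, sigma_alpha^2)), directional (N(mu_alpha, sigma_alpha^2)) or
    InSIDE-violating (alpha correlated with gamma via ``inside_slope``).
    ``planted_outliers`` variants instead get their ratio multiplied by
    ``outlier_multiplier`` (a gross single-variant violation, for outlier-
    detection studies).  ``noise_scale=0`` yields noise-free betas.
    """

    j_instruments: int = 10
    k_mediators: int = 0
    j_mediator_instruments: int = 15
    eaf_range: tuple = (0.1, 0.9)
    instrument_z_range: tuple = (5.5, 21.0)
    n_exposure: int = 35_892
    n_mediator: int = 200_622
    n_outcome: int = 63_926
    case_fraction: float = 0.344
    theta_direct: float = -0.19
    tau: tuple = ()
    rho: tuple = ()
    pleiotropy: str = "none"
    pleiotropy_frac: float = 1.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    inside_slope: float = 0.5
    planted_outliers: int = 0
    outlier_multiplier: float = 10.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.tau = tuple(self.tau)
        self.rho = tuple(self.rho)
        self.validate()

    def validate(self) -> None:
        bad = []
        if self.j_instruments < 1:
            bad.append("j_instruments must be >= 1")
        if self.k_mediators < 0:
            bad.append("k_mediators must be >= 0")
        if len(self.tau) != self.k_mediators or len(self.rho) != self.k_mediators:
            bad.append("tau and rho must each have k_mediators entries")
        if not (0 < self.eaf_range[0] <= self.eaf_range[1] < 1):
            bad.append("eaf_range must lie inside (0,1)")
        if min(self.n_exposure, self.n_outcome) <= 0 or \
                (self.k_mediators and self.n_mediator <= 0):
            bad.append("sample sizes must be positive")
        if not (0 < self.case_fraction < 1):
            bad.append("case_fraction must be in (0,1)")
        if self.pleiotropy not in PLEIOTROPY_MODELS:
            bad.append(f"pleiotropy must be one of {PLEIOTROPY_MODELS}")
        if not (0 <= self.pleiotropy_frac <= 1):
            bad.append("pleiotropy_frac must be in [0,1]")
        if self.planted_outliers > self.j_instruments:
            bad.append("planted_outliers cannot exceed j_instruments")
        if self.noise_scale < 0:
            bad.append("noise_scale must be >= 0")
        if self.seed is None:
            bad.append("seed must be set")
        if bad:
            raise ConfigurationError("invalid SimulationConfig: " + "; ".join(bad))

    @property
    def theta_total(self) -> float:
        """Total exposure->outcome effect implied by the mediation diagram."""
        return self.theta_direct + sum(t * r for t, r in zip(self.tau, self.rho))


@dataclass
class SyntheticStudy:
    """Generated summary statistics plus the ground truth behind them."""

    exposure: SummaryStatsTable
    mediators: list[SummaryStatsTable]
    outcome: SummaryStatsTable
    ld: Optional[LDReference]
    ground_truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exposure.to_tsv(out / "exposure.tsv")
        for m in self.mediators:
            m.to_tsv(out / f"mediator_{m.trait_name}.tsv")
        self.outcome.to_tsv(out / "outcome.tsv")
        if self.ld is not None:
            self.ld.to_tsv(out / "ld.tsv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)


def _p_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _table(trait: str, trait_type: str, ids, chrom, bp, ea, oa, eaf, beta, se, n) -> SummaryStatsTable:
    frame = pd.DataFrame({
        "snp_id": ids, "chromosome": chrom, "base_position": bp,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "p_value": _p_from_z(beta, se),
        "n": n,
    }, columns=_FIELDS)
    return SummaryStatsTable(trait, trait_type, frame)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate one synthetic multi-trait summary-statistics study.

    Returns exposure, mediator and outcome tables sharing one variant panel,
    plus ``ground_truth`` with the config and the realised instrument
    effects, pleiotropy effects and total effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.j_instruments
    k = config.k_mediators
    jm = config.j_mediator_instruments
    m_total = j + k * jm

    ids = [f"rs{900000 + i}" for i in range(m_total)]
    chrom = [str(i % 22 + 1) for i in range(m_total)]
    bp = [1_000_000 + (i // 22) * 20_000_000 for i in range(m_total)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m_total)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    eaf = rng.uniform(config.eaf_range[0], config.eaf_range[1], m_total)

    het = 2.0 * eaf * (1.0 - eaf)
    v = config.case_fraction
    se_exp = 1.0 / np.sqrt(het * config.n_exposure)
    se_med = 1.0 / np.sqrt(het * config.n_mediator)
    se_out = 1.0 / np.sqrt(het * config.n_outcome * v * (1.0 - v))

    # true per-allele effects
    z = rng.uniform(*config.instrument_z_range, m_total)
    gamma = np.zeros(m_total)
    gamma[:j] = z[:j] * se_exp[:j]  # exposure-increasing orientation
    delta = np.zeros((m_total, k))
    for ki in range(k):
        block = slice(j + ki * jm, j + (ki + 1) * jm)
        delta[block, ki] = z[block] * se_med[block]

    bm_true = gamma[:, None] * np.array(config.tau)[None, :] + delta if k else \
        np.zeros((m_total, 0))

    alpha = np.zeros(m_total)
    if config.pleiotropy != "none":
        n_pleio = int(math.ceil(config.pleiotropy_frac * j))
        which = rng.permutation(j)[:n_pleio]
        if config.pleiotropy == "balanced":
            alpha[which] = rng.normal(0.0, config.sigma_alpha, n_pleio)
        elif config.pleiotropy == "directional":
            alpha[which] = rng.normal(config.mu_alpha, config.sigma_alpha, n_pleio)
        else:  # inside_violating
            centred = gamma[which] - gamma[:j].mean()
            alpha[which] = (config.mu_alpha + config.inside_slope * centred
                            + rng.normal(0.0, config.sigma_alpha, n_pleio))
    if config.planted_outliers:
        planted = np.arange(j - config.planted_outliers, j)
        alpha[planted] = (config.outlier_multiplier - 1.0) * config.theta_total * gamma[planted]
    else:
        planted = np.array([], dtype=int)

    by_true = (config.theta_direct * gamma
               + (bm_true @ np.array(config.rho) if k else 0.0)
               + alpha)

    ns = config.noise_scale
    b_exp = gamma + ns * rng.normal(0.0, se_exp)
    b_out = by_true + ns * rng.normal(0.0, se_out)
    b_med = bm_true + ns * rng.normal(0.0, np.broadcast_to(se_med[:, None], (m_total, k))) \
        if k else bm_true

    exposure = _table("exposure", "continuous", ids, chrom, bp, ea, oa, eaf,
                      b_exp, se_exp, config.n_exposure)
    mediators = [
        _table(f"mediator_{ki + 1}", "continuous", ids, chrom, bp, ea, oa, eaf,
               b_med[:, ki], se_med, config.n_mediator)
        for ki in range(k)
    ]
    outcome = _table("outcome", "binary", ids, chrom, bp, ea, oa, eaf,
                     b_out, se_out, config.n_outcome)

    ground_truth = {
        "config": _config_dict(config),
        "gamma": gamma[:j].tolist(),
        "alpha": alpha[:j].tolist(),
        "planted_outlier_ids": [ids[i] for i in planted],
        "theta_total": config.theta_total,
    }
    return SyntheticStudy(exposure=exposure, mediators=mediators, outcome=outcome,
                          ld=None, ground_truth=ground_truth)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    for key in ("eaf_range", "instrument_z_range", "tau", "rho"):
        d[key] = list(d[key])
    return d


def simulate_ld_block(ids_with_positions, decay: float) -> LDReference:
    """AR(1)-style LD block: r2 between i-th and j-th variant = decay^|i-j|.

    ``ids_with_positions`` is a sequence of (variant id, base position) in
    rank order.  ``decay`` in [0,1]; 0 gives independent variants, 1 a block
    in complete LD.
    """
    if not (0 <= decay <= 1):
        raise ConfigurationError(f"decay must be in [0,1], got {decay}")
    items = list(ids_with_positions)
    ld = LDReference(positions={str(i): int(p) for i, p in items})
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            r2 = decay ** (b - a)
            if r2 > 0:
                ld.set_r2(str(items[a][0]), str(items[b][0]), r2)
    return ld


def simulate_outcome(donor: SummaryStatsTable, theta: float, n: int,
                     case_fraction: float, seed: int,
                     noise_scale: float = 1.0,
                     trait_name: str = "synthetic_outcome") -> SummaryStatsTable:
    """Synthetic binary outcome for an existing exposure table's variants.

    Treats the donor's observed betas as the true exposure effects; the true
    outcome effect per variant is ``theta`` times that, observed with noise
    at se = 1/sqrt(2 n p (1-p) v (1-v)).  Variants with missing EAF use
    p = 0.3.  Desk-scale plumbing for pairing real instrument tables with a
    controlled outcome.
    """
    rng = np.random.default_rng(seed)
    frame = donor.frame
    eaf = frame["eaf"].astype(float).fillna(0.3).to_numpy()
    het = 2.0 * eaf * (1.0 - eaf)
    se = 1.0 / np.sqrt(het * n * case_fraction * (1.0 - case_fraction))
    beta_true = theta * frame["beta"].astype(float).to_numpy()
    beta = beta_true + noise_scale * rng.normal(0.0, se)
    return _table(trait_name, "binary", frame["snp_id"], frame["chromosome"],
                  frame["base_position"], frame["effect_allele"],
                  frame["other_allele"], frame["eaf"], beta, se, n)


# ---------------------------------------------------------------------------
# Named presets (the study conditions used throughout the test-bed)


def full_mediation_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """No direct effect; two mediators carry the whole effect.

    theta_total = 0 + (-0.40)(0.25) + (-0.45)(0.20) = -0.19, matching an
    odds ratio of 0.83 per unit exposure.  Adjusting either mediator alone
    leaves a non-significant remainder; adjusting both nulls the effect.
    """
    base = dict(k_mediators=2, theta_direct=0.0, tau=(-0.40, -0.45),
                rho=(0.25, 0.20), seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


def partial_mediation_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """A direct effect of -0.10 plus two mediated paths (total -0.205)."""
    base = dict(k_mediators=2, theta_direct=-0.10, tau=(-0.40, -0.45),
                rho=(0.15, 0.10), seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)
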