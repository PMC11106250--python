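"""End-to-end two-sample MR mediation workflow.

For each exposure source and outcome dataset: instrument selection
(genome-wide filter, LD clumping, proxy substitution, harmonization,
Steiger directionality filter), the full univariable method panel with
sensitivity tests, then a per-mediator multivariable scan, putative-mediator
selection by attenuation, and a joint multivariable model with all selected
mediators.  Every filtering stage logs and records its in/out counts so the
instrument accounting is reproducible on any input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import (CollinearityError, DataError, InsufficientInstruments,
                         SelectionFailure)
from .instruments import (clump, combine_instruments_mvmr, f_statistic,
                          filter_genomewide, steiger_filter)
from .mvmr import MVMRResult, build_mvmr_dataset, conditional_f, mvmr_egger, mvmr_ivw, mvmr_lasso
from .presso import PressoResult, presso
from .sumstats import LDReference, SummaryStatsTable, find_proxy, harmonize
from .uvmr import UnivariableMR, _spawn_seeds

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_exposures: int = 3) -> float:
    """Multiple-comparison significance threshold, rounded to 3 decimals.

    0.05 divided by the number of exposures (0.017 for three).
    """
    return round(0.05 / n_exposures, 3)


def classify_significance(p: float, n_exposures: int = 3) -> str:
    """Partition p-values into significant / suggestive / null.

    ``significant`` below the Bonferroni threshold, ``suggestive`` below
    0.05, ``null`` otherwise (strict inequalities).
    """
    if not (0 < p <= 1):
        raise DataError(f"p must be in (0,1], got {p}")
    if p < bonferroni_threshold(n_exposures):
        return "significant"
    if p < 0.05:
        return "suggestive"
    return "null"


@dataclass
class AnalysisConfig:
    """Thresholds and reproducibility settings for the whole workflow."""

    p_iv: float = 5e-8
    clump_r2: float = 0.01
    clump_window_bp: int = 10_000_000
    proxy_min_r2: float = 1.0
    palindrome_maf_limit: float = 0.30
    steiger: bool = True
    n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    n_exposures_for_bonferroni: int = 3
    mediator_alpha: float = 0.05
    mediator_rule: str = "attenuation"  # or "mediator_outcome"
    snp_subset: Optional[tuple] = None

    def __post_init__(self):
        if not (0 < self.p_iv < 1):
            raise DataError(f"p_iv out of range: {self.p_iv}")
        if not (0 <= self.clump_r2 <= 1):
            raise DataError(f"clump_r2 out of range: {self.clump_r2}")
        if not (0 < self.proxy_min_r2 <= 1):
            raise DataError(f"proxy_min_r2 out of range: {self.proxy_min_r2}")
        if not (0 <= self.palindrome_maf_limit <= 0.5):
            raise DataError(f"palindrome_maf_limit out of range: {self.palindrome_maf_limit}")
        if self.mediator_rule not in ("attenuation", "mediator_outcome"):
            raise DataError(f"unknown mediator_rule {self.mediator_rule!r}")
        if self.seed is None:
            raise DataError("seed is mandatory")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["snp_subset"] is not None:
            d["snp_subset"] = list(d["snp_subset"])
        return d


@dataclass
class UVMRPanel:
    """One exposure-outcome univariable analysis: methods + diagnostics."""

    exposure: str
    outcome: str
    counts: dict
    instrument_ids: list[str]
    f_stats: dict[str, float]
    methods: pd.DataFrame
    heterogeneity: pd.DataFrame
    loo: Optional[pd.DataFrame]
    presso: Optional[dict]
    status: str = "ok"


def select_instruments(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
                       config: AnalysisConfig, ld: Optional[LDReference] = None):
    """Filter -> clump -> proxy-substitute -> harmonize -> Steiger.

    Returns ``(retained_pairs, counts, f_stats)`` where counts records the
    in/out size of every stage.
    """
    ld = ld or LDReference()
    counts = {"input": len(exposure)}
    table = exposure
    if config.snp_subset is not None:
        table = table.subset(config.snp_subset)
        counts["subset"] = len(table)
    sig = filter_genomewide(table, config.p_iv)
    counts["genomewide"] = len(sig)
    if len(sig) == 0:
        return [], counts, {}
    clumped = clump(sig, ld, config.clump_r2, config.clump_window_bp)
    counts["clumped"] = len(clumped)

    # proxy substitution for instruments missing from the outcome
    ids = []
    n_proxied = 0
    for snp in clumped.ids:
        if snp in outcome:
            ids.append(snp)
            continue
        proxy = find_proxy(snp, outcome, ld, config.proxy_min_r2)
        if proxy is not None and proxy in exposure and proxy not in ids:
            logger.info("select_instruments: %s replaced by proxy %s", snp, proxy)
            ids.append(proxy)
            n_proxied += 1
        else:
            logger.info("select_instruments: %s missing from outcome, no proxy", snp)
    counts["proxied"] = n_proxied
    counts["matched"] = len(ids)
    if not ids:
        return [], counts, {}

    hset = harmonize(exposure.subset(ids), outcome, config.palindrome_maf_limit)
    counts.update({f"harmonize_{k}": v for k, v in hset.counts().items()})
    retained = hset.retained
    counts["harmonized"] = len(retained)
    if config.steiger and retained:
        retained, _ = steiger_filter(retained, exposure.trait_type, outcome.trait_type)
        counts["steiger"] = len(retained)
    f_stats = {p.snp_id: f_statistic(p.beta_exposure, p.se_exposure) for p in retained}
    return retained, counts, f_stats


def run_uvmr_suite(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
                   config: AnalysisConfig,
                   ld: Optional[LDReference] = None) -> UVMRPanel:
    """Univariable panel: all feasible methods at the available J.

    J = 1 leaves only the Wald ratio; medians/mode/Egger need J >= 3 and the
    outlier test J >= 4; infeasible methods appear as rows marked
    unavailable, never silently dropped.
    """
    pairs, counts, f_stats = select_instruments(exposure, outcome, config, ld)
    j = len(pairs)
    if j == 0:
        return UVMRPanel(exposure=exposure.trait_name, outcome=outcome.trait_name,
                         counts=counts, instrument_ids=[], f_stats={},
                         methods=pd.DataFrame(), heterogeneity=pd.DataFrame(),
                         loo=None, presso=None, status="no_instruments")
    model = UnivariableMR(pairs)
    results = model.fit_all(n_boot=config.n_boot, seed=config.seed)
    methods = results.to_frame()

    presso_result = None
    if j >= 4:
        presso_result = presso(pairs, n_sim=config.n_sim,
                               seed=_spawn_seeds(config.seed, 4)[3])
        row = dict(status="ok",
                   **(presso_result.corrected_estimate if presso_result.outliers
                      else presso_result.raw_estimate).to_dict())
        row["method"] = "presso"
        row["outliers"] = ",".join(presso_result.outliers) or ""
        methods = pd.concat([methods, pd.DataFrame([row])], ignore_index=True)
    else:
        methods = pd.concat([methods, pd.DataFrame(
            [{"method": "presso", "status": f"unavailable (needs >= 4 SNPs, have {j})"}])],
            ignore_index=True)

    n_exp = config.n_exposures_for_bonferroni
    methods["significance"] = [
        classify_significance(p, n_exp) if pd.notna(p) else None
        for p in methods.get("p", pd.Series([np.nan] * len(methods)))
    ]

    het_rows = []
    if results.heterogeneity is not None:
        het_rows.append({"test": "cochran_q_ivw", **results.heterogeneity.to_dict()})
    if results.pleiotropy is not None:
        het_rows.append({"test": "egger_intercept", **results.pleiotropy.to_dict()})
    if presso_result is not None:
        het_rows.append({"test": "presso_global", "p": presso_result.global_p,
                         "Q": presso_result.rss_observed, "df": None})

    return UVMRPanel(
        exposure=exposure.trait_name, outcome=outcome.trait_name, counts=counts,
        instrument_ids=[p.snp_id for p in pairs], f_stats=f_stats,
        methods=methods, heterogeneity=pd.DataFrame(het_rows),
        loo=results.loo, presso=presso_result.to_dict() if presso_result else None,
    )


def _mvmr_rows(exposure_tables, outcome, config, ld, mediator_label):
    """IVW/Egger/Lasso rows for one multivariable model, Table-2 style."""
    rows = []
    primary = exposure_tables[0].trait_name
    try:
        iset = combine_instruments_mvmr(exposure_tables, outcome, ld,
                                        config.p_iv, config.clump_r2,
                                        config.clump_window_bp, config.proxy_min_r2)
        data = build_mvmr_dataset(exposure_tables, outcome, iset.ids)
    except (DataError, InsufficientInstruments) as exc:
        return [{"exposure": primary, "mediators": mediator_label,
                 "outcome": outcome.trait_name, "method": m,
                 "status": f"unavailable ({exc})"}
                for m in ("ivw", "egger", "lasso")]
    fitters = {"ivw": mvmr_ivw, "egger": mvmr_egger, "lasso": mvmr_lasso}
    cond_f = None
    for method, fit in fitters.items():
        try:
            res = fit(data)
        except (InsufficientInstruments, CollinearityError, SelectionFailure) as exc:
            rows.append({"exposure": primary, "mediators": mediator_label,
                         "outcome": outcome.trait_name, "method": method,
                         "status": f"unavailable ({exc})"})
            continue
        if cond_f is None:
            cond_f = res.conditional_f
        est = res.estimate_for(exposure_tables[0].trait_name)
        row = {"exposure": primary, "mediators": mediator_label,
               "outcome": outcome.trait_name, "status": "ok",
               **est.to_dict(), "method": method}
        row["significance"] = classify_significance(est.p_value,
                                                    config.n_exposures_for_bonferroni)
        for i, tab in enumerate(exposure_tables):
            row[f"conditional_f_{tab.trait_name}"] = res.conditional_f[i] \
                if res.conditional_f else None
        # co-exposure estimates, for the alternative mediator rule
        for tab in exposure_tables[1:]:
            co = res.estimate_for(tab.trait_name)
            row[f"theta_{tab.trait_name}"] = co.theta
            row[f"p_{tab.trait_name}"] = co.p_value
        rows.append(row)
    return rows


def run_mediator_scan(exposure: SummaryStatsTable,
                      mediators: Sequence[SummaryStatsTable],
                      outcomes: Sequence[SummaryStatsTable],
                      config: AnalysisConfig,
                      ld: Optional[LDReference] = None) -> pd.DataFrame:
    """Per-mediator multivariable models: exposure adjusted for one mediator.

    For each mediator and outcome the pooled instrument set is rebuilt
    (union of both exposures' significant variants, clumped, completeness-
    filtered), and IVW/Egger/Lasso estimates plus conditional F statistics
    are reported for the exposure of interest.
    """
    rows = []
    for mediator in mediators:
        for outcome in outcomes:
            rows.extend(_mvmr_rows([exposure, mediator], outcome, config, ld,
                                   mediator.trait_name))
    return pd.DataFrame(rows)


def select_putative_mediators(scan: pd.DataFrame, unadjusted: pd.DataFrame,
                              alpha: float = 0.05,
                              rule: str = "attenuation") -> list[str]:
    """Flag mediators whose adjustment explains the exposure-outcome effect.

    ``attenuation`` (default): a mediator is putative when, in at least one
    outcome dataset, the unadjusted exposure IVW estimate is significant
    (p < alpha) but the mediator-adjusted IVW estimate is not (p >= alpha).
    ``mediator_outcome``: the mediator's own direct effect on the outcome in
    the two-exposure model is significant (p < alpha).

    ``unadjusted`` needs columns (outcome, p) for the primary IVW estimates.
    """
    if scan.empty:
        return []
    ivw_rows = scan[(scan["method"] == "ivw") & (scan["status"] == "ok")]
    unadj_p = dict(zip(unadjusted["outcome"], unadjusted["p"]))
    flagged = []
    for mediator, sub in ivw_rows.groupby("mediators", sort=True):
        for _, row in sub.iterrows():
            if rule == "attenuation":
                p0 = unadj_p.get(row["outcome"])
                if p0 is not None and p0 < alpha and row["p"] >= alpha:
                    flagged.append(mediator)
                    break
            else:
                p_med = row.get(f"p_{mediator}")
                if p_med is not None and pd.notna(p_med) and p_med < alpha:
                    flagged.append(mediator)
                    break
    return sorted(set(flagged))


def run_joint_mvmr(exposure: SummaryStatsTable,
                   mediators: Sequence[SummaryStatsTable],
                   outcomes: Sequence[SummaryStatsTable],
                   config: AnalysisConfig,
                   ld: Optional[LDReference] = None) -> pd.DataFrame:
    """One multivariable model with the exposure and all selected mediators."""
    if not mediators:
        raise DataError("run_joint_mvmr: no mediators selected")
    label = "+".join(m.trait_name for m in mediators)
    rows = []
    for outcome in outcomes:
        rows.extend(_mvmr_rows([exposure, *mediators], outcome, config, ld, label))
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """Everything one workflow run produced, serializable and re-loadable."""

    uvmr: pd.DataFrame
    heterogeneity: pd.DataFrame
    loo: pd.DataFrame
    presso: dict
    mvmr_scan: pd.DataFrame
    mvmr_joint: pd.DataFrame
    selected_mediators: list[str]
    counts: dict
    provenance: dict

    def to_json_dict(self) -> dict:
        def df(d):
            return d.to_dict(orient="records") if d is not None else []

        return {
            "uvmr": df(self.uvmr),
            "heterogeneity": df(self.heterogeneity),
            "loo": df(self.loo),
            "presso": self.presso,
            "mvmr_scan": df(self.mvmr_scan),
            "mvmr_joint": df(self.mvmr_joint),
            "selected_mediators": self.selected_mediators,
            "counts": self.counts,
            "provenance": self.provenance,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "StudyReport":
        return cls(
            uvmr=pd.DataFrame(d["uvmr"]),
            heterogeneity=pd.DataFrame(d["heterogeneity"]),
            loo=pd.DataFrame(d["loo"]),
            presso=d["presso"],
            mvmr_scan=pd.DataFrame(d["mvmr_scan"]),
            mvmr_joint=pd.DataFrame(d["mvmr_joint"]),
            selected_mediators=list(d["selected_mediators"]),
            counts=d["counts"],
            provenance=d["provenance"],
        )


def run_pipeline(exposures: Sequence[SummaryStatsTable],
                 outcomes: Sequence[SummaryStatsTable],
                 mediators: Sequence[SummaryStatsTable] = (),
                 config: Optional[AnalysisConfig] = None,
                 ld: Optional[LDReference] = None) -> StudyReport:
    """The complete workflow over all exposure sources and outcome datasets.

    Univariable panels for every (exposure, outcome) pair; the mediator scan
    and the joint model use the first exposure table as the trait of
    interest.
    """
    config = config or AnalysisConfig()
    uvmr_rows, het_rows, loo_rows, presso_all, counts = [], [], [], {}, {}
    primary_unadjusted = []
    for exposure in exposures:
        for outcome in outcomes:
            panel = run_uvmr_suite(exposure, outcome, config, ld)
            key = f"{panel.exposure}|{panel.outcome}"
            counts[key] = panel.counts
            if panel.status != "ok":
                uvmr_rows.append(pd.DataFrame(
                    [{"exposure": panel.exposure, "outcome": panel.outcome,
                      "status": panel.status}]))
                continue
            m = panel.methods.copy()
            m.insert(0, "exposure", panel.exposure)
            m.insert(1, "outcome", panel.outcome)
            uvmr_rows.append(m)
            h = panel.heterogeneity.copy()
            h.insert(0, "exposure", panel.exposure)
            h.insert(1, "outcome", panel.outcome)
            het_rows.append(h)
            if panel.loo is not None:
                lo = panel.loo.copy()
                lo.insert(0, "exposure", panel.exposure)
                lo.insert(1, "outcome", panel.outcome)
                loo_rows.append(lo)
            if panel.presso is not None:
                presso_all[key] = panel.presso
            if exposure is exposures[0]:
                ivw_row = m[(m["method"].isin(["ivw_random", "wald_ratio (single SNP)"]))
                            & (m["status"] == "ok")]
                if len(ivw_row):
                    primary_unadjusted.append({"outcome": panel.outcome,
                                               "p": float(ivw_row["p"].iloc[0])})

    uvmr = pd.concat(uvmr_rows, ignore_index=True) if uvmr_rows else pd.DataFrame()
    het = pd.concat(het_rows, ignore_index=True) if het_rows else pd.DataFrame()
    loo = pd.concat(loo_rows, ignore_index=True) if loo_rows else pd.DataFrame()

    scan = pd.DataFrame()
    joint = pd.DataFrame()
    selected: list[str] = []
    if mediators:
        scan = run_mediator_scan(exposures[0], mediators, outcomes, config, ld)
        unadjusted = pd.DataFrame(primary_unadjusted)
        selected = select_putative_mediators(scan, unadjusted, config.mediator_alpha,
                                             config.mediator_rule)
        chosen = [m for m in mediators if m.trait_name in selected]
        if chosen:
            joint = run_joint_mvmr(exposures[0], chosen, outcomes, config, ld)

    provenance = {
        "package": "mrmediate",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "exposures": [t.trait_name for t in exposures],
        "outcomes": [t.trait_name for t in outcomes],
        "mediators": [t.trait_name for t in mediators],
    }
    return StudyReport(uvmr=uvmr, heterogeneity=het, loo=loo, presso=presso_all,
                       mvmr_scan=scan, mvmr_joint=joint,
                       selected_mediators=selected, counts=counts,
                       provenance=provenance)


def write_report(report: StudyReport, out_dir) -> list[Path]:
    """Emit the report as TSV tables, a JSON bundle and a provenance sidecar.

    Output is deterministic byte-for-byte given an identical report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def tsv(frame: pd.DataFrame, name: str):
        path = out / name
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
        written.append(path)

    tsv(report.uvmr, "uvmr_results.tsv")
    tsv(report.heterogeneity, "heterogeneity.tsv")
    tsv(report.loo, "loo.tsv")
    tsv(report.mvmr_scan, "mvmr_scan.tsv")
    tsv(report.mvmr_joint, "mvmr_joint.tsv")
    for name, payload in (("presso.json", report.presso),
                          ("report.json", report.to_json_dict()),
                          ("provenance.json", report.provenance)):
        path = out / name
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    return written
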