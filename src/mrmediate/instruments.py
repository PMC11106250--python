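"""Instrument selection for two-sample MR.

Genome-wide significance filtering, greedy LD clumping, per-variant
instrument strength F = (beta/SE)^2, Steiger directionality filtering, and
the instrument-pooling rule used to assemble multivariable MR datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .sumstats import (HarmonizedPair, HarmonizedSet, LDReference,
                       SummaryStatsTable, VariantAssociation, find_proxy)

logger = logging.getLogger(__name__)

GENOMEWIDE_P = 5e-8
CLUMP_R2 = 0.01
CLUMP_WINDOW_BP = 10_000_000
PROXY_MIN_R2 = 1.0


def filter_genomewide(table: SummaryStatsTable,
                      p_threshold: float = GENOMEWIDE_P) -> SummaryStatsTable:
    """Keep variants with p strictly below the significance threshold."""
    if not (0 < p_threshold < 1):
        raise ConfigurationError(f"p_threshold must be in (0,1), got {p_threshold}")
    frame = table.frame
    kept = frame.loc[frame["p_value"].astype(float) < p_threshold]
    out = SummaryStatsTable(table.trait_name, table.trait_type,
                            kept.reset_index(drop=True), table.build)
    logger.info("filter_genomewide(%s): %d -> %d at p<%g",
                table.trait_name, len(table), len(out), p_threshold)
    return out


def _sort_key(frame: pd.DataFrame) -> pd.DataFrame:
    """Total order: ascending p, then base position, then id (deterministic)."""
    key = frame.assign(
        _p=frame["p_value"].astype(float),
        _bp=frame["base_position"].fillna(np.inf).astype(float),
        _id=frame["snp_id"].astype(str),
    )
    return key.sort_values(["_p", "_bp", "_id"], kind="mergesort")


def clump(table: SummaryStatsTable, ld: Optional[LDReference] = None,
          r2_threshold: float = CLUMP_R2,
          window_bp: int = CLUMP_WINDOW_BP) -> SummaryStatsTable:
    """Greedy LD clumping: retain index variants, discard their LD partners.

    Variants are visited in ascending p order (ties by position then id);
    each retained index variant removes all remaining variants on the same
    chromosome within ``window_bp`` whose r2 to it is >= ``r2_threshold``.
    Variants absent from the LD reference are treated as r2 = 0 to all.
    """
    if ld is None:
        ld = LDReference()
    ordered = _sort_key(table.frame)
    alive = dict.fromkeys(ordered["snp_id"], True)
    chrom = dict(zip(ordered["snp_id"], ordered["chromosome"]))
    pos = dict(zip(ordered["snp_id"], ordered["base_position"]))
    retained: list[str] = []
    for snp in ordered["snp_id"]:
        if not alive[snp]:
            continue
        retained.append(snp)
        alive[snp] = False
        for other, live in alive.items():
            if not live:
                continue
            if chrom.get(snp) != chrom.get(other):
                continue
            p1, p2 = pos.get(snp), pos.get(other)
            if p1 is None or p2 is None or math.isnan(float(p1)) or math.isnan(float(p2)):
                continue
            if abs(float(p1) - float(p2)) > window_bp:
                continue
            if ld.r2(snp, other) >= r2_threshold:
                alive[other] = False
    out = table.subset(retained)
    logger.info("clump(%s): %d -> %d (r2<%g within %d bp)",
                table.trait_name, len(table), len(out), r2_threshold, window_bp)
    return out


def f_statistic(beta: float, se: float) -> float:
    """Per-variant instrument strength F = (beta/SE)^2."""
    if se <= 0:
        raise DataError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


LOGISTIC_VARIANCE = math.pi ** 2 / 3.0


def variance_explained(assoc: VariantAssociation, trait_type: str,
                       case_fraction: Optional[float] = None) -> float:
    """Variance in the trait explained by one variant.

    Continuous (standardized) traits: r2 = 2*EAF*(1-EAF)*beta^2.  Binary
    traits (beta on the log-odds scale): pseudo-r2 on the latent logistic
    scale, x / (x + pi^2/3) with x = 2*EAF*(1-EAF)*beta^2.  ``case_fraction``
    is accepted for interface symmetry but the latent-scale formula does not
    use it.
    """
    if assoc.eaf is None:
        raise DataError(f"{assoc.snp_id}: eaf required to score variance explained")
    x = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta ** 2
    if trait_type == "binary":
        return x / (x + LOGISTIC_VARIANCE)
    return x


def naive_variance_explained(assoc: VariantAssociation) -> float:
    """Sensitivity alternative: 2p(1-p)beta^2 regardless of trait type."""
    if assoc.eaf is None:
        raise DataError(f"{assoc.snp_id}: eaf required")
    return 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta ** 2


@dataclass(frozen=True)
class SteigerRecord:
    """Per-variant directionality record: variance explained on each side."""

    snp_id: str
    r2_exposure: float
    r2_outcome: float

    @property
    def retained(self) -> bool:
        return self.r2_exposure > self.r2_outcome


def steiger_filter(pairs, exposure_type: str, outcome_type: str,
                   binary_scale: str = "latent"):
    """Keep pairs explaining strictly more variance in the exposure.

    ``binary_scale`` selects the latent-logistic pseudo-r2 (default) or the
    naive 2p(1-p)beta^2 on the log-odds scale for binary traits.  Pairs with
    no usable EAF on either side are excluded with a warning.  Returns
    ``(retained_pairs, records)`` with one record per scoreable pair.
    """
    pair_list = pairs.retained if isinstance(pairs, HarmonizedSet) else list(pairs)
    retained, records = [], []
    for p in pair_list:
        eaf_exp = p.eaf_exposure
        eaf_out = p.eaf_outcome if p.eaf_outcome is not None else p.eaf_exposure
        if eaf_exp is None:
            logger.warning("steiger_filter: %s has no eaf; excluded", p.snp_id)
            continue

        def r2(eaf, beta, trait_type):
            x = 2.0 * eaf * (1.0 - eaf) * beta ** 2
            if trait_type == "binary" and binary_scale == "latent":
                return x / (x + LOGISTIC_VARIANCE)
            return x

        rec = SteigerRecord(
            snp_id=p.snp_id,
            r2_exposure=r2(eaf_exp, p.beta_exposure, exposure_type),
            r2_outcome=r2(eaf_out, p.beta_outcome, outcome_type),
        )
        records.append(rec)
        if rec.retained:
            retained.append(p)
    logger.info("steiger_filter: %d -> %d", len(pair_list), len(retained))
    return retained, records


@dataclass
class InstrumentSet:
    """A selected instrument panel with provenance.

    For multivariable analyses ``associations`` maps each trait name
    (exposures first, outcome last) to a :class:`SummaryStatsTable`
    restricted and ordered to ``ids``.
    """

    exposures: list[str]
    ids: list[str]
    f_stats: dict[str, float]
    provenance: dict = field(default_factory=dict)
    associations: dict[str, SummaryStatsTable] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.ids,
                             "f_statistic": [self.f_stats[s] for s in self.ids]})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def combine_instruments_mvmr(exposure_tables: Sequence[SummaryStatsTable],
                             outcome: SummaryStatsTable,
                             ld: Optional[LDReference] = None,
                             p_threshold: float = GENOMEWIDE_P,
                             r2_threshold: float = CLUMP_R2,
                             window_bp: int = CLUMP_WINDOW_BP,
                             proxy_min_r2: float = PROXY_MIN_R2) -> InstrumentSet:
    """Pool instruments across exposures for multivariable MR.

    The union of each exposure's genome-wide-significant variants is scored
    by its minimum p across exposures and clumped once; retained variants
    must be present (or proxy-resolvable at ``proxy_min_r2``) in every
    exposure table and in the outcome.
    """
    if len(exposure_tables) < 2:
        raise ConfigurationError("combine_instruments_mvmr needs >= 2 exposure tables")
    if ld is None:
        ld = LDReference()

    # union of significant variants, each represented by its min-p row
    best_rows: dict[str, pd.Series] = {}
    for tab in exposure_tables:
        sig = filter_genomewide(tab, p_threshold)
        for _, row in sig.frame.iterrows():
            snp = row["snp_id"]
            if snp not in best_rows or float(row["p_value"]) < float(best_rows[snp]["p_value"]):
                best_rows[snp] = row
    if not best_rows:
        raise DataError("combine_instruments_mvmr: no genome-wide-significant variants")
    union = SummaryStatsTable(
        "mvmr_union", exposure_tables[0].trait_type,
        pd.DataFrame(list(best_rows.values())).reset_index(drop=True))
    clumped = clump(union, ld, r2_threshold, window_bp)

    all_tables = list(exposure_tables) + [outcome]
    kept, dropped = [], []
    for snp in clumped.ids:
        if all(snp in t for t in all_tables):
            kept.append(snp)
            continue
        # try a proxy present in every table
        replacement = None
        if snp in ld.variants:
            pos = ld.positions.get(snp)
            cands = []
            for cand, r2 in ld.partners(snp, proxy_min_r2):
                if all(cand in t for t in all_tables):
                    cand_pos = ld.positions.get(cand)
                    dist = (abs(cand_pos - pos)
                            if pos is not None and cand_pos is not None else math.inf)
                    cands.append((-r2, dist, cand))
            if cands:
                cands.sort()
                replacement = cands[0][2]
        if replacement is not None and replacement not in kept:
            logger.info("combine_instruments_mvmr: %s replaced by proxy %s", snp, replacement)
            kept.append(replacement)
        else:
            logger.info("combine_instruments_mvmr: %s missing from a table, no proxy; dropped", snp)
            dropped.append(snp)
    if not kept:
        raise DataError("combine_instruments_mvmr: empty instrument set after completeness filter")

    primary = exposure_tables[0]
    f_stats = {s: f_statistic(primary.get(s).beta, primary.get(s).se)
               for s in kept if s in primary}
    associations = {t.trait_name: t.subset(kept) for t in all_tables}
    return InstrumentSet(
        exposures=[t.trait_name for t in exposure_tables],
        ids=kept,
        f_stats=f_stats,
        provenance={"p_threshold": p_threshold, "r2_threshold": r2_threshold,
                    "window_bp": window_bp, "proxy_min_r2": proxy_min_r2},
        associations=associations,
        dropped=dropped,
    )
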