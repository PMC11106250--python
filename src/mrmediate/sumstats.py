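"""GWAS summary-statistics data model, I/O, harmonization and LD proxies.

The unit of data is one variant's association with one trait (beta, SE, P,
effect-allele frequency, sample size).  Tables of such associations are
matched between an exposure study and an outcome study by rsID and aligned
to a common effect allele ("harmonization") before any causal estimation.
Positions are 1-based GRCh38 throughout; no liftover is attempted.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

VALID_BASES = {"A", "C", "G", "T"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical on-disk header (TSV default)
CANONICAL_HEADER = ["SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]

#: internal column names, in canonical order
_FIELDS = [
    "snp_id",
    "chromosome",
    "base_position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p_value",
    "n",
]

_HEADER_TO_FIELD = dict(zip(CANONICAL_HEADER, _FIELDS))

#: columns that must be present (and mapped) in any input file
MANDATORY = ["snp_id", "effect_allele", "beta", "se", "p_value"]


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if isinstance(x, str) and x.strip().upper() in {"", "NA", "NAN", "."}:
        return True
    return False


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is in trait units for continuous traits and log-odds for binary
    ones.  ``eaf``, ``other_allele`` and ``n`` may be missing (None).
    """

    snp_id: str
    chromosome: Optional[str]
    base_position: Optional[int]
    effect_allele: str
    other_allele: Optional[str]
    eaf: Optional[float]
    beta: float
    se: float
    p_value: float
    n: Optional[int] = None

    def __post_init__(self):
        if self.se <= 0:
            raise DataError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.p_value <= 1):
            raise DataError(f"{self.snp_id}: p_value must be in (0,1], got {self.p_value}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise DataError(f"{self.snp_id}: eaf must be in [0,1], got {self.eaf}")
        if self.effect_allele not in VALID_BASES:
            raise DataError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele is not None:
            if self.other_allele not in VALID_BASES:
                raise DataError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
            if self.other_allele == self.effect_allele:
                raise DataError(f"{self.snp_id}: effect and other allele are identical")

    @property
    def is_palindromic(self) -> bool:
        return (
            self.other_allele is not None
            and COMPLEMENT[self.effect_allele] == self.other_allele
        )


class SummaryStatsTable:
    """A GWAS summary-statistics dataset: one trait, one row per variant.

    Backed by a pandas DataFrame with canonical internal columns; variant
    ids are unique.  ``trait_type`` is ``"continuous"`` or ``"binary"``
    (betas on the log-odds scale for binary traits).
    """

    def __init__(self, trait_name: str, trait_type: str, frame: pd.DataFrame,
                 build: str = "GRCh38"):
        if trait_type not in ("continuous", "binary"):
            raise ConfigurationError(f"trait_type must be continuous|binary, got {trait_type}")
        missing = [c for c in _FIELDS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"frame missing columns: {missing}")
        if frame["snp_id"].duplicated().any():
            dups = frame.loc[frame["snp_id"].duplicated(), "snp_id"].tolist()
            raise DataError(f"duplicate snp_id in table {trait_name!r}: {dups}")
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.build = build
        self._frame = frame[_FIELDS].reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self._frame["snp_id"])}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @property
    def ids(self) -> list[str]:
        return list(self._frame["snp_id"])

    @property
    def frame(self) -> pd.DataFrame:
        """A copy of the underlying canonical frame."""
        return self._frame.copy()

    def get(self, snp_id: str) -> VariantAssociation:
        if snp_id not in self._index:
            raise KeyError(snp_id)
        row = self._frame.iloc[self._index[snp_id]]
        return _row_to_record(row)

    def records(self) -> list[VariantAssociation]:
        return [_row_to_record(r) for _, r in self._frame.iterrows()]

    def subset(self, ids: Iterable[str]) -> "SummaryStatsTable":
        wanted = [s for s in ids if s in self._index]
        sub = self._frame.iloc[[self._index[s] for s in wanted]]
        return SummaryStatsTable(self.trait_name, self.trait_type,
                                 sub.reset_index(drop=True), self.build)

    @classmethod
    def from_records(cls, trait_name: str, trait_type: str,
                     records: Sequence[VariantAssociation],
                     build: str = "GRCh38") -> "SummaryStatsTable":
        frame = pd.DataFrame(
            [{f: getattr(r, f) for f in _FIELDS} for r in records], columns=_FIELDS
        )
        return cls(trait_name, trait_type, frame, build)

    def to_tsv(self, path) -> None:
        out = self._frame.copy()
        out.columns = CANONICAL_HEADER
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    def __repr__(self) -> str:  # pragma: no cover - debug helper
        return (f"SummaryStatsTable({self.trait_name!r}, {self.trait_type}, "
                f"{len(self)} variants)")


def _row_to_record(row) -> VariantAssociation:
    def opt(v):
        return None if _is_missing(v) else v

    bp = opt(row["base_position"])
    n = opt(row["n"])
    return VariantAssociation(
        snp_id=str(row["snp_id"]),
        chromosome=None if _is_missing(row["chromosome"]) else str(row["chromosome"]),
        base_position=None if bp is None else int(bp),
        effect_allele=str(row["effect_allele"]),
        other_allele=None if _is_missing(row["other_allele"]) else str(row["other_allele"]),
        eaf=None if _is_missing(row["eaf"]) else float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        p_value=float(row["p_value"]),
        n=None if n is None else int(n),
    )


# ---------------------------------------------------------------------------
# Reading


def _detect_sep(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return r"\s+"


def read_summary_stats(path, trait_name: str, trait_type: str,
                       column_map: Optional[Mapping[str, str]] = None,
                       strict: bool = True) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a :class:`SummaryStatsTable`.

    ``column_map`` maps canonical header names (``SNP``, ``CHR``, ``BP``,
    ``EA``, ``NEA``, ``EAF``, ``BETA``, ``SE``, ``P``, ``N``) to the file's
    actual header names; omitted entries default to the canonical name.
    Delimiter is auto-detected among tab/comma/whitespace; scientific
    notation and unicode minus signs are accepted.

    In strict mode malformed rows and duplicate ids raise :class:`DataError`;
    in lenient mode they are skipped and counted on the returned table's
    ``n_rejected`` / ``n_duplicates`` attributes.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    # normalise unicode minus to ASCII before parsing numerics
    text = text.replace("−", "-")
    lines = text.splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    sep = _detect_sep(lines[0])
    raw = pd.read_csv(io.StringIO(text), sep=sep, dtype=str,
                      na_values=["NA", "NaN", "nan", "."], keep_default_na=True)
    cmap = dict(column_map or {})
    rename = {}
    for canon, field_name in _HEADER_TO_FIELD.items():
        src = cmap.get(canon, canon)
        if src in raw.columns:
            rename[src] = field_name
    raw = raw.rename(columns=rename)
    missing = [f for f in MANDATORY if f not in raw.columns]
    if missing:
        canon_missing = [c for c, f in _HEADER_TO_FIELD.items() if f in missing]
        raise ConfigurationError(
            f"{path}: mandatory columns not found/mapped: {canon_missing}")
    for f in _FIELDS:
        if f not in raw.columns:
            raw[f] = None
    if len(raw) == 0:
        raise DataError(f"{path}: no data rows")

    # duplicates
    n_duplicates = int(raw["snp_id"].duplicated().sum())
    if n_duplicates:
        if strict:
            dups = raw.loc[raw["snp_id"].duplicated(), "snp_id"].unique().tolist()
            raise DataError(f"{path}: duplicate snp_id(s): {dups}")
        raw = raw.drop_duplicates(subset="snp_id", keep="first")

    records, n_rejected = [], 0
    for _, row in raw.iterrows():
        try:
            rec = VariantAssociation(
                snp_id=str(row["snp_id"]).strip(),
                chromosome=None if _is_missing(row["chromosome"]) else str(row["chromosome"]).strip(),
                base_position=None if _is_missing(row["base_position"]) else int(float(row["base_position"])),
                effect_allele=str(row["effect_allele"]).strip().upper() if not _is_missing(row["effect_allele"]) else "",
                other_allele=None if _is_missing(row["other_allele"]) else str(row["other_allele"]).strip().upper(),
                eaf=None if _is_missing(row["eaf"]) else float(row["eaf"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                p_value=float(row["p_value"]),
                n=None if _is_missing(row["n"]) else int(float(row["n"])),
            )
        except (DataError, ValueError, TypeError) as exc:
            if strict:
                raise DataError(f"{path}: invalid row for {row['snp_id']!r}: {exc}") from exc
            n_rejected += 1
            continue
        records.append(rec)
    if not records:
        raise DataError(f"{path}: no valid records")
    table = SummaryStatsTable.from_records(trait_name, trait_type, records)
    table.n_rejected = n_rejected
    table.n_duplicates = n_duplicates if not strict else 0
    logger.info("read %d variants for %s (%d rejected, %d duplicates dropped)",
                len(table), trait_name, n_rejected, table.n_duplicates)
    return table


# ---------------------------------------------------------------------------
# Harmonization

ACTION_KEPT = "kept"
ACTION_FLIPPED = "flipped"
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_INCOMPATIBLE = "dropped_incompatible"
RETAINED_ACTIONS = (ACTION_KEPT, ACTION_FLIPPED)


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one variant on a common effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: Optional[str]
    beta_exposure: float
    se_exposure: float
    eaf_exposure: Optional[float]
    beta_outcome: float
    se_outcome: float
    eaf_outcome: Optional[float]
    action: str
    low_confidence: bool = False

    @property
    def retained(self) -> bool:
        return self.action in RETAINED_ACTIONS


@dataclass
class HarmonizedSet:
    """All matched pairs (with their action) plus unmatched exposure ids."""

    pairs: list[HarmonizedPair] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if p.retained]

    def counts(self) -> dict:
        out = {a: 0 for a in (ACTION_KEPT, ACTION_FLIPPED,
                              ACTION_DROPPED_PALINDROMIC, ACTION_DROPPED_INCOMPATIBLE)}
        for p in self.pairs:
            out[p.action] += 1
        out["unmatched"] = len(self.unmatched)
        return out

    def to_frame(self, retained_only: bool = False) -> pd.DataFrame:
        pairs = self.retained if retained_only else self.pairs
        return pd.DataFrame(
            [
                {
                    "snp_id": p.snp_id,
                    "effect_allele": p.effect_allele,
                    "other_allele": p.other_allele,
                    "beta_exposure": p.beta_exposure,
                    "se_exposure": p.se_exposure,
                    "eaf_exposure": p.eaf_exposure,
                    "beta_outcome": p.beta_outcome,
                    "se_outcome": p.se_outcome,
                    "eaf_outcome": p.eaf_outcome,
                    "action": p.action,
                    "low_confidence": p.low_confidence,
                }
                for p in pairs
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def _harmonize_record(exp: VariantAssociation, out: VariantAssociation,
                      palindrome_maf_limit: float) -> HarmonizedPair:
    """Harmonize one matched exposure/outcome record pair."""

    def pair(beta_o, eaf_o, action, low_confidence=False):
        return HarmonizedPair(
            snp_id=exp.snp_id,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            eaf_exposure=exp.eaf,
            beta_outcome=beta_o,
            se_outcome=out.se,
            eaf_outcome=eaf_o,
            action=action,
            low_confidence=low_confidence,
        )

    def flipped_eaf(e):
        return None if e is None else 1.0 - e

    # allele information incomplete on either side: match on EA only
    if exp.other_allele is None or out.other_allele is None:
        if out.effect_allele == exp.effect_allele:
            return pair(out.beta, out.eaf, ACTION_KEPT, low_confidence=True)
        if exp.other_allele is not None and out.effect_allele == exp.other_allele:
            return pair(-out.beta, flipped_eaf(out.eaf), ACTION_FLIPPED, low_confidence=True)
        return pair(out.beta, out.eaf, ACTION_DROPPED_INCOMPATIBLE, low_confidence=True)

    same = (out.effect_allele == exp.effect_allele
            and out.other_allele == exp.other_allele)
    swapped = (out.effect_allele == exp.other_allele
               and out.other_allele == exp.effect_allele)

    if exp.is_palindromic:
        if not (same or swapped):
            return pair(out.beta, out.eaf, ACTION_DROPPED_INCOMPATIBLE)
        # alleles alone cannot resolve strand; use frequencies
        if exp.eaf is None or out.eaf is None:
            return pair(out.beta, out.eaf, ACTION_DROPPED_PALINDROMIC)
        maf_exp = min(exp.eaf, 1 - exp.eaf)
        maf_out = min(out.eaf, 1 - out.eaf)
        if maf_exp > palindrome_maf_limit or maf_out > palindrome_maf_limit:
            return pair(out.beta, out.eaf, ACTION_DROPPED_PALINDROMIC)
        # for a palindromic variant an allele swap is indistinguishable from a
        # strand flip: align purely by frequency side
        if (exp.eaf - 0.5) * (out.eaf - 0.5) < 0:
            return pair(-out.beta, flipped_eaf(out.eaf), ACTION_FLIPPED)
        return pair(out.beta, out.eaf, ACTION_KEPT)

    if same:
        return pair(out.beta, out.eaf, ACTION_KEPT)
    if swapped:
        return pair(-out.beta, flipped_eaf(out.eaf), ACTION_FLIPPED)
    # try the complementary strand
    comp_ea = COMPLEMENT[out.effect_allele]
    comp_oa = COMPLEMENT[out.other_allele]
    if comp_ea == exp.effect_allele and comp_oa == exp.other_allele:
        return pair(out.beta, out.eaf, ACTION_KEPT)
    if comp_ea == exp.other_allele and comp_oa == exp.effect_allele:
        return pair(-out.beta, flipped_eaf(out.eaf), ACTION_FLIPPED)
    return pair(out.beta, out.eaf, ACTION_DROPPED_INCOMPATIBLE)


def harmonize(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
              palindrome_maf_limit: float = 0.30) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    For each variant present in both tables: identical allele pairs are kept;
    swapped pairs have the outcome beta negated and EAF reflected; palindromic
    (A/T, C/G) pairs are resolved by allele frequency when unambiguous
    (min(EAF, 1-EAF) <= ``palindrome_maf_limit`` in both studies) and dropped
    otherwise; incompatible allele pairs are dropped.  Exposure variants
    missing from the outcome are reported in ``unmatched`` for proxy search.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise DataError("harmonize: both tables must be non-empty")
    pairs, unmatched = [], []
    for snp_id in exposure.ids:
        if snp_id not in outcome:
            unmatched.append(snp_id)
            continue
        pairs.append(_harmonize_record(exposure.get(snp_id), outcome.get(snp_id),
                                       palindrome_maf_limit))
    result = HarmonizedSet(pairs=pairs, unmatched=unmatched)
    logger.info("harmonize %s vs %s: %s", exposure.trait_name, outcome.trait_name,
                result.counts())
    return result


# ---------------------------------------------------------------------------
# LD reference and proxies


class LDReference:
    """Pairwise LD (r-squared) lookup with variant positions.

    Symmetric; r2(v, v) = 1; absent pairs are treated as r2 = 0.
    """

    def __init__(self, positions: Optional[Mapping[str, int]] = None):
        self.positions: dict[str, int] = dict(positions or {})
        self._r2: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ConfigurationError(f"r2 must be in [0,1], got {r2}")
        if a != b:
            self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    @property
    def variants(self) -> set[str]:
        return set(self.positions)

    def partners(self, snp_id: str, min_r2: float) -> list[tuple[str, float]]:
        """All variants with r2 >= min_r2 to ``snp_id`` (excluding itself)."""
        out = []
        for (a, b), v in self._r2.items():
            if v >= min_r2:
                if a == snp_id:
                    out.append((b, v))
                elif b == snp_id:
                    out.append((a, v))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"SNP_A": a, "POS_A": self.positions.get(a), "SNP_B": b,
             "POS_B": self.positions.get(b), "R2": v}
            for (a, b), v in sorted(self._r2.items())
        ]
        return pd.DataFrame(rows, columns=["SNP_A", "POS_A", "SNP_B", "POS_B", "R2"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LDReference":
        ld = cls()
        for row in frame.itertuples(index=False):
            if not _is_missing(row.POS_A):
                ld.positions[str(row.SNP_A)] = int(row.POS_A)
            if not _is_missing(row.POS_B):
                ld.positions[str(row.SNP_B)] = int(row.POS_B)
            ld.set_r2(str(row.SNP_A), str(row.SNP_B), float(row.R2))
        return ld

    @classmethod
    def from_tsv(cls, path) -> "LDReference":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def find_proxy(missing_id: str, donor: SummaryStatsTable, ld: LDReference,
               min_r2: float = 1.0) -> Optional[str]:
    """Best proxy for ``missing_id`` among the donor table's variants.

    Returns the donor variant with maximal r2 >= ``min_r2``; ties are broken
    by smaller base-position distance, then lexicographic id.  Returns None
    when nothing qualifies (including when ``missing_id`` is unknown to the
    LD reference).
    """
    if not (0 < min_r2 <= 1):
        raise ConfigurationError(f"min_r2 must be in (0,1], got {min_r2}")
    if missing_id not in ld.variants:
        logger.info("find_proxy: %s absent from LD reference", missing_id)
        return None
    pos = ld.positions.get(missing_id)
    candidates = []
    for cand, r2 in ld.partners(missing_id, min_r2):
        if cand == missing_id or cand not in donor:
            continue
        cand_pos = ld.positions.get(cand)
        dist = abs(cand_pos - pos) if (pos is not None and cand_pos is not None) else math.inf
        candidates.append((-r2, dist, cand))
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][2]
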