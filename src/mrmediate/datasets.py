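"""Packaged reference data: the blood-osteocalcin instrument table.

Thirteen independent variants (r2 < 0.01) associated with blood osteocalcin
levels at genome-wide significance, pooled from three blood-proteome GWAS
(tagged ELDJARN, n~35.7k; GUDJONSSON, n=5368; SUN, n=3301).  Positions are
1-based GRCh38.  ``F_REPORTED`` is the source publication's printed
F-statistic, computed there from unrounded effect sizes; it will not equal
(BETA/SE)^2 of the rounded columns and is carried for reference only.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sumstats import SummaryStatsTable, _FIELDS

SOURCES = ("ELDJARN", "GUDJONSSON", "SUN")

#: variants in gene regions suggestively linked to bone homeostasis
BONE_HOMEOSTASIS_SNPS = ("rs1831272", "rs2019727", "rs3830076", "rs61803031")


def _fixture_frame() -> pd.DataFrame:
    with resources.files("mrmediate.data").joinpath(
            "ocn_instruments_grch38.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_ocn_instruments(source: str | None = None) -> SummaryStatsTable:
    """The packaged osteocalcin instrument table as a SummaryStatsTable.

    ``source`` restricts to one of ``ELDJARN``, ``GUDJONSSON`` or ``SUN``;
    None returns all 13 rows.
    """
    raw = _fixture_frame()
    if source is not None:
        if source not in SOURCES:
            raise ValueError(f"unknown source {source!r}; expected one of {SOURCES}")
        raw = raw[raw["SOURCE"] == source]
    frame = pd.DataFrame({
        "snp_id": raw["SNP"].astype(str),
        "chromosome": raw["CHR"].astype(str),
        "base_position": raw["BP"].astype(int),
        "effect_allele": raw["EA"],
        "other_allele": raw["NEA"],
        "eaf": raw["EAF"],
        "beta": raw["BETA"].astype(float),
        "se": raw["SE"].astype(float),
        "p_value": raw["P"].astype(float),
        "n": raw["N"].astype(int),
    }, columns=_FIELDS).reset_index(drop=True)
    name = "blood_osteocalcin" + (f"_{source.lower()}" if source else "")
    return SummaryStatsTable(name, "continuous", frame)


def reported_f_statistics(source: str | None = None) -> pd.Series:
    """The printed per-variant F column, indexed by rsID (reference only)."""
    raw = _fixture_frame()
    if source is not None:
        raw = raw[raw["SOURCE"] == source]
    return raw.set_index("SNP")["F_REPORTED"]
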