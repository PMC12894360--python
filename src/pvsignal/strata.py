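"""Stratified screening: dechallenge/rechallenge subsets, reporter
classes, and ATC first-level drug classes.

Each stratified analysis re-runs the full 2x2 screening with the
stratum as its own background (N is recomputed within the stratum) and
the unchanged conjunctive signal criterion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from . import dispro

logger = logging.getLogger(__name__)

__all__ = [
    "AtcMapping",
    "ATC_LEVEL1_NAMES",
    "load_toy_atc",
    "dechal_rechal_subset",
    "reporter_strata",
    "atc_screen",
]

_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]{1,2}(\d{2})?)?)?$")

ATC_LEVEL1_NAMES = {
    "A": "Alimentary tract and metabolism",
    "B": "Blood and blood forming organs",
    "C": "Cardiovascular system",
    "D": "Dermatologicals",
    "G": "Genitourinary system and sex hormones",
    "H": "Systemic hormonal preparations, excl. sex hormones and insulins",
    "J": "Antiinfectives for systemic use",
    "L": "Antineoplastic and immunomodulating agents",
    "M": "Musculo-skeletal system",
    "N": "Nervous system",
    "P": "Antiparasitic products, insecticides and repellents",
    "R": "Respiratory system",
    "S": "Sensory organs",
    "V": "Various",
}


@dataclass(frozen=True)
class AtcMapping:
    """Standardized drug name -> list of ATC codes (a drug may belong to
    several classes; level 1 is the first letter)."""
    table: pd.DataFrame  # columns: drug, atc_code

    def __post_init__(self):
        if self.table.empty:
            raise ValueError("empty ATC mapping")
        bad = self.table.loc[
            ~self.table["atc_code"].str.match(_ATC_RE), "atc_code"]
        if len(bad):
            raise ValueError(f"invalid ATC codes: {sorted(bad.unique())[:5]}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AtcMapping":
        df = pd.read_csv(path, dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        df["drug"] = df["drug"].str.strip().str.upper()
        df["atc_code"] = df["atc_code"].str.strip().str.upper()
        return cls(df[["drug", "atc_code"]])

    def level1(self) -> pd.DataFrame:
        """Distinct (drug, level-1 class letter) pairs."""
        out = self.table.assign(atc_class=self.table["atc_code"].str[0])
        return out[["drug", "atc_class"]].drop_duplicates().reset_index(drop=True)


def load_toy_atc() -> AtcMapping:
    """The packaged toy mapping (screened drugs plus decoys), for tests
    and synthetic runs; real analyses supply their own table."""
    with resources.as_file(
            resources.files("pvsignal.data") / "atc_toy.csv") as p:
        return AtcMapping.from_csv(p)


def dechal_rechal_subset(units: pd.DataFrame, which: str) -> pd.DataFrame:
    """Restrict counting units to those whose suspect-drug row carries a
    positive (Y) dechallenge or rechallenge code.

    Downstream screening then uses the subset as its own background.
    Only FAERS-derived units carry these codes; an input without the
    column (an EV-derived table) is an error.
    """
    if which not in ("dechal", "rechal"):
        raise ValueError(f"which must be 'dechal' or 'rechal', got {which!r}")
    if which not in units.columns:
        raise ValueError(
            f"units lack a {which!r} column (EV-style records have no "
            "dechallenge/rechallenge information; this analysis is "
            "FAERS-only)")
    sub = units[units[which].fillna("").str.upper() == "Y"]
    logger.info("%s=Y subset: %d of %d units", which, len(sub), len(units))
    return sub.reset_index(drop=True)


def reporter_strata(cases: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a case table by reporter class; cases with an
    unspecified reporter belong to neither stratum."""
    out = {}
    for stratum in ("consumer", "healthcare_professional"):
        out[stratum] = cases[cases["reporter"] == stratum].reset_index(drop=True)
    n_un = int((cases["reporter"] == "unspecified").sum())
    logger.info("reporter strata: %d consumer, %d healthcare_professional, "
                "%d unspecified (excluded)",
                len(out["consumer"]), len(out["healthcare_professional"]), n_un)
    return out


def atc_screen(units: pd.DataFrame, mapping: AtcMapping,
               criterion: dispro.SignalCriterion = dispro.SignalCriterion(),
               **screen_kwargs) -> pd.DataFrame:
    """Screen ATC first-level classes instead of individual drugs.

    Every counting unit expands to one unit per distinct level-1 class
    of its drug (a multi-class drug contributes to each of its
    classes); units whose drug is absent from the mapping are logged
    and excluded.  The per-class 2x2 treats class membership as the
    "drug", with the expanded table as background.
    """
    lvl1 = mapping.level1()
    mapped = units.merge(lvl1, on="drug", how="left")
    unmapped = mapped.loc[mapped["atc_class"].isna(), "drug"].unique()
    if len(unmapped):
        logger.warning("ATC mapping misses %d drugs (%d units excluded)",
                       len(unmapped),
                       int(mapped["atc_class"].isna().sum()))
    mapped = mapped.dropna(subset=["atc_class"])
    if mapped.empty:
        raise ValueError("ATC mapping covers no unit's drug")
    expanded = mapped.rename(columns={"drug": "drug_name",
                                      "atc_class": "drug"})
    out = dispro.screen(expanded, criterion, **screen_kwargs)
    out = out.rename(columns={"drug": "atc_class"})
    out.insert(1, "atc_name", out["atc_class"].map(ATC_LEVEL1_NAMES))
    return out
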