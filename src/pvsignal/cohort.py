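"""Case definition and analysis-dataset construction.

Turns deduplicated raw reports (FAERS packages or EV-style listings)
into a normalised :class:`CaseData` container, applies the case
definition — male sex, at least one reaction exactly matching the
target MedDRA PT screening list, and at least one suspect drug
(role PS in FAERS, "Suspected" in EV) — and produces the drug-event
record table plus descriptive summaries.

Matching is exact: a reaction matches when its PT code equals a listed
code, or, when the code is absent, its name equals a listed name
case-insensitively after trimming.  No substring or fuzzy matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import faers_io

logger = logging.getLogger(__name__)

__all__ = [
    "EventTermList",
    "CaseData",
    "load_default_terms",
    "match_event_terms",
    "from_faers",
    "from_ev",
    "standardize_drug_names",
    "select_cases",
    "screening_units",
    "describe_cohort",
]

_CODE_RE = re.compile(r"^\d{8}$")

# age-unit conversion to years
AGE_UNIT_YEARS = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12, "WK": 1 / 52.18,
                  "DY": 1 / 365.25, "HR": 1 / 8766}

AGE_GROUPS = ["<18", "18-44", "45-64", ">=65", "Not specified"]

# FAERS occupation codes -> reporter class
_REPORTER_MAP = {"CN": "consumer", "LW": "consumer",
                 "MD": "healthcare_professional",
                 "PH": "healthcare_professional",
                 "OT": "healthcare_professional",
                 "HP": "healthcare_professional"}
_EV_REPORTER_MAP = {"Non Healthcare Professional": "consumer",
                    "Healthcare Professional": "healthcare_professional"}

# raw occupation labels for descriptive reporting (finer than the
# two-class analysis grouping)
_OCCUPATION_LABELS = {"CN": "Consumer", "LW": "Lawyer", "MD": "Physician",
                      "PH": "Pharmacist", "OT": "Other health-professional",
                      "HP": "Health professional"}


def _norm_name(s: str) -> str:
    return str(s).strip().casefold()


@dataclass(frozen=True)
class EventTermList:
    """The target-event screening list: (PT code, PT name) entries."""
    entries: tuple

    def __post_init__(self):
        codes = [c for c, _ in self.entries]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate PT codes in term list")
        if not self.entries:
            raise ValueError("empty term list")

    @property
    def codes(self) -> set:
        return {c for c, _ in self.entries}

    def name_index(self) -> dict:
        return {_norm_name(n): c for c, n in self.entries}

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTermList":
        df = pd.read_csv(path, dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(tuple(zip(df.iloc[:, 0].str.strip(),
                             df.iloc[:, 1].str.strip())))


def load_default_terms() -> EventTermList:
    """The packaged 13-term reproductive-toxicity screening list."""
    with resources.as_file(
            resources.files("pvsignal.data") / "meddra_terms.csv") as p:
        return EventTermList.from_csv(p)


def match_event_terms(reactions, terms: EventTermList) -> set:
    """Matched PT codes for one case.

    ``reactions`` is an iterable of (pt_code, pt_name) pairs; either
    element may be empty/None.  A reaction matches iff its code equals a
    listed code, or — when the code is absent — its trimmed name equals
    a listed name case-insensitively.
    """
    by_name = terms.name_index()
    codes = terms.codes
    matched = set()
    for code, name in reactions:
        code = "" if code is None or pd.isna(code) else str(code).strip()
        if code:
            if code in codes:
                matched.add(code)
            continue
        hit = by_name.get(_norm_name(name or ""))
        if hit:
            matched.add(hit)
    return matched


@dataclass
class CaseData:
    """Normalised one-row-per-case container shared by both sources.

    cases:     caseid, source, sex, age_years, age_group, reporter,
               serious, event_date, year
    drugs:     caseid, drug, role, dechal, rechal, start_full, has_start
    reactions: caseid, pt_code, pt_name
    """
    cases: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    source: str = "FAERS"


def _age_to_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    v = pd.to_numeric(age, errors="coerce")
    factor = age_cod.str.strip().str.upper().map(AGE_UNIT_YEARS)
    # missing unit on a present value: treat as years (FAERS convention)
    factor = factor.where(~(factor.isna() & v.notna()), 1.0)
    return v * factor


def _age_group(age_years: pd.Series) -> pd.Series:
    bins = [-np.inf, 18, 45, 65, np.inf]
    grp = pd.cut(age_years, bins=bins, right=False,
                 labels=["<18", "18-44", "45-64", ">=65"])
    out = grp.astype(object)
    out[age_years.isna()] = "Not specified"
    return out


def from_faers(pkg: faers_io.FaersPackage, source: str = "FAERS") -> CaseData:
    """Build CaseData from an already deduplicated package."""
    demo = pkg.demo
    sex = demo["sex"].str.strip().str.upper().map(
        {"M": "male", "F": "female"}).fillna("unknown")
    age_years = _age_to_years(demo["age"], demo["age_cod"])
    occ = demo["occp_cod"].str.strip().str.upper()
    reporter = occ.map(_REPORTER_MAP).fillna("unspecified")
    serious_pids = set(pkg.outc["primaryid"])
    cases = pd.DataFrame({
        "caseid": demo["caseid"],
        "source": source,
        "sex": sex,
        "age_years": age_years,
        "age_group": _age_group(age_years),
        "reporter": reporter,
        "occupation": occ.map(_OCCUPATION_LABELS).fillna("Not specified"),
        "serious": demo["primaryid"].isin(serious_pids),
        "event_date": demo["event_dt"].fillna("").str.strip(),
        "year": pd.to_numeric(demo["fda_dt"].str[:4], errors="coerce"),
    })
    pid2case = demo.set_index("primaryid")["caseid"]

    drug = pkg.drug[pkg.drug["primaryid"].isin(pid2case.index)].copy()
    ther = pkg.ther[pkg.ther["primaryid"].isin(pid2case.index)].copy()
    ther["start_dt"] = ther["start_dt"].fillna("").str.strip()
    full = ther[ther["start_dt"].str.fullmatch(r"\d{8}")].copy()
    full["start_full"] = pd.to_numeric(full["start_dt"])
    starts = full.groupby(["primaryid", "dsg_drug_seq"], as_index=False)[
        "start_full"].min()
    any_start = ther[ther["start_dt"] != ""][
        ["primaryid", "dsg_drug_seq"]].drop_duplicates()
    any_start["has_start"] = True
    drug = drug.merge(starts, left_on=["primaryid", "drug_seq"],
                      right_on=["primaryid", "dsg_drug_seq"], how="left")
    drug = drug.merge(any_start, left_on=["primaryid", "drug_seq"],
                      right_on=["primaryid", "dsg_drug_seq"], how="left")
    drugs = pd.DataFrame({
        "caseid": drug["primaryid"].map(pid2case),
        "drug": drug["drugname"].fillna("").str.strip().str.upper(),
        "role": drug["role_cod"].fillna("").str.strip().str.upper(),
        "dechal": drug["dechal"].fillna("").str.strip().str.upper(),
        "rechal": drug["rechal"].fillna("").str.strip().str.upper(),
        "start_full": drug["start_full"].astype("Float64"),
        "has_start": drug["has_start"].eq(True),
    })

    reac = pkg.reac[pkg.reac["primaryid"].isin(pid2case.index)]
    pt = reac["pt"].fillna("").str.strip()
    is_code = pt.str.fullmatch(r"\d{8}")
    reactions = pd.DataFrame({
        "caseid": reac["primaryid"].map(pid2case),
        "pt_code": pt.where(is_code, ""),
        "pt_name": pt.where(~is_code, ""),
    })
    return CaseData(cases.reset_index(drop=True),
                    drugs.reset_index(drop=True),
                    reactions.reset_index(drop=True), source=source)


def from_ev(listing: pd.DataFrame | str | Path, source: str = "EV") -> CaseData:
    """Build CaseData from a consolidated EV-style listing (CSV columns:
    case_id, qualification, sex, age_group, suspected_drugs,
    reaction_pts, serious, region[, receive_year])."""
    if not isinstance(listing, pd.DataFrame):
        listing = pd.read_csv(listing, dtype=str)
    df = listing.copy()
    if df["case_id"].duplicated().any():
        raise ValueError("EV listing has duplicate case ids")
    grp_map = {"<18": "<18", "18-44": "18-44", "45-64": "45-64",
               ">=65": ">=65", "≥65": ">=65"}
    age_group = df["age_group"].fillna("").str.strip().map(grp_map).fillna(
        "Not specified")
    year = pd.to_numeric(df.get("receive_year"), errors="coerce") \
        if "receive_year" in df else pd.Series(np.nan, index=df.index)
    cases = pd.DataFrame({
        "caseid": df["case_id"].astype(str),
        "source": source,
        "sex": df["sex"].fillna("").str.strip().str.lower().map(
            {"male": "male", "female": "female"}).fillna("unknown"),
        "age_years": np.nan,
        "age_group": age_group,
        "reporter": df["qualification"].fillna("").str.strip().map(
            _EV_REPORTER_MAP).fillna("unspecified"),
        "occupation": df["qualification"].fillna("").str.strip().replace(
            "", "Not specified"),
        "serious": df["serious"].fillna("").str.strip().str.upper() == "Y",
        "event_date": "",
        "year": year,
    })
    drugs = df.assign(drug=df["suspected_drugs"].fillna("").str.split(";")) \
        .explode("drug")
    drugs = pd.DataFrame({
        "caseid": drugs["case_id"].astype(str),
        "drug": drugs["drug"].fillna("").str.strip().str.upper(),
        "role": "SUSPECT",
        "dechal": "", "rechal": "",
        "start_full": pd.array([pd.NA] * len(drugs), dtype="Float64"),
        "has_start": False,
    })
    drugs = drugs[drugs["drug"] != ""]
    reac = df.assign(pt=df["reaction_pts"].fillna("").str.split(";")) \
        .explode("pt")
    pt = reac["pt"].fillna("").str.strip()
    is_code = pt.str.fullmatch(r"\d{8}")
    reactions = pd.DataFrame({
        "caseid": reac["case_id"].astype(str),
        "pt_code": pt.where(is_code, ""),
        "pt_name": pt.where(~is_code, ""),
    })
    reactions = reactions[(reactions["pt_code"] != "") |
                          (reactions["pt_name"] != "")]
    return CaseData(cases.reset_index(drop=True),
                    drugs.reset_index(drop=True),
                    reactions.reset_index(drop=True), source=source)


# ---------------------------------------------------------------------------
# drug-name standardization
# ---------------------------------------------------------------------------

def _resolve_mapping(table: dict) -> dict:
    """Follow verbatim -> preferred chains to a terminal name; a cycle
    is a configuration error."""
    resolved = {}
    for start in table:
        seen = [start]
        cur = start
        while cur in table:
            cur = table[cur]
            if cur in seen:
                raise ValueError(f"cyclic synonym mapping: {' -> '.join(seen + [cur])}")
            seen.append(cur)
        resolved[start] = cur
    return resolved


def standardize_drug_names(data, synonym_table) -> "CaseData | pd.DataFrame":
    """Map verbatim drug names to preferred names.

    ``synonym_table`` is a two-column frame/CSV/dict (verbatim ->
    preferred).  Unmapped names pass through upper-cased and trimmed;
    coverage is logged.  Accepts a CaseData (returns a copy with
    standardized drugs) or any DataFrame with a ``drug`` column.
    """
    if isinstance(synonym_table, (str, Path)):
        synonym_table = pd.read_csv(synonym_table, dtype=str)
    if isinstance(synonym_table, pd.DataFrame):
        synonym_table = dict(zip(
            synonym_table.iloc[:, 0].str.strip().str.upper(),
            synonym_table.iloc[:, 1].str.strip().str.upper()))
    else:
        synonym_table = {str(k).strip().upper(): str(v).strip().upper()
                         for k, v in synonym_table.items()}
    mapping = _resolve_mapping(synonym_table)

    def apply(col: pd.Series) -> pd.Series:
        clean = col.fillna("").str.strip().str.upper()
        mapped = clean.map(mapping)
        n_hit = int(mapped.notna().sum())
        misses = clean[mapped.isna() & (clean != "")].unique()
        if len(misses):
            logger.warning("synonym table left %d verbatim names unmapped "
                           "(passed through)", len(misses))
        logger.info("drug standardization: %d/%d rows mapped",
                    n_hit, len(clean))
        return mapped.fillna(clean)

    if isinstance(data, CaseData):
        drugs = data.drugs.copy()
        drugs["drug"] = apply(drugs["drug"])
        return CaseData(data.cases, drugs, data.reactions, source=data.source)
    out = data.copy()
    out["drug"] = apply(out["drug"])
    return out


# ---------------------------------------------------------------------------
# case selection & counting units
# ---------------------------------------------------------------------------

_QUALIFYING_ROLES = {"PS", "SUSPECT"}


def _matched_codes_per_case(cd: CaseData, terms: EventTermList) -> pd.DataFrame:
    """(caseid, pt_code) rows for every matched reaction."""
    r = cd.reactions
    by_name = terms.name_index()
    code_hit = r["pt_code"].isin(terms.codes)
    name_norm = r["pt_name"].map(_norm_name)
    name_hit = (r["pt_code"] == "") & name_norm.isin(by_name)
    matched = pd.concat([
        r.loc[code_hit, ["caseid", "pt_code"]],
        pd.DataFrame({"caseid": r.loc[name_hit, "caseid"],
                      "pt_code": name_norm[name_hit].map(by_name)}),
    ], ignore_index=True).drop_duplicates()
    return matched


def select_cases(cd: CaseData, terms: EventTermList | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the case definition; returns (case table, drug-event
    record table).

    Retained cases are male AND have >=1 matched target PT AND >=1
    suspect-role drug.  One record per (case, qualifying drug, matched
    PT).
    """
    if terms is None:
        terms = load_default_terms()
    matched = _matched_codes_per_case(cd, terms)
    male_ids = set(cd.cases.loc[cd.cases["sex"] == "male", "caseid"])
    qual = cd.drugs[cd.drugs["role"].isin(_QUALIFYING_ROLES) &
                    (cd.drugs["drug"] != "")]
    qual = qual.drop_duplicates(["caseid", "drug"])
    eligible = (set(matched["caseid"]) & male_ids) & set(qual["caseid"])

    case_table = cd.cases[cd.cases["caseid"].isin(eligible)].reset_index(drop=True)
    records = qual[qual["caseid"].isin(eligible)].merge(
        matched[matched["caseid"].isin(eligible)], on="caseid")
    records = records[["caseid", "drug", "pt_code", "role", "dechal",
                       "rechal"]].sort_values(
        ["caseid", "drug", "pt_code"], kind="mergesort").reset_index(drop=True)
    logger.info("case selection (%s): %d cases, %d drug-event records",
                cd.source, len(case_table), len(records))
    return case_table, records


def screening_units(cd: CaseData, terms: EventTermList | None = None,
                    *, events_as_records: bool = False) -> pd.DataFrame:
    """Counting units for disproportionality screening.

    One row per unique (male case, suspect drug) pair over the whole
    male background, with ``event`` flagging target-event membership of
    the case, plus the reporter class, seriousness, and the drug row's
    dechallenge/rechallenge codes.

    With ``events_as_records=True`` every matched PT of an event case
    yields its own unit (the drug-event-record counting convention);
    non-event units stay one per pair.
    """
    if terms is None:
        terms = load_default_terms()
    matched = _matched_codes_per_case(cd, terms)
    male = cd.cases[cd.cases["sex"] == "male"]
    qual = cd.drugs[cd.drugs["role"].isin(_QUALIFYING_ROLES) &
                    (cd.drugs["drug"] != "")]
    units = qual.drop_duplicates(["caseid", "drug"]).merge(
        male[["caseid", "reporter", "serious"]], on="caseid")
    event_ids = set(matched["caseid"])
    units["event"] = units["caseid"].isin(event_ids)
    if events_as_records:
        ev = units[units["event"]].merge(matched, on="caseid")
        units = pd.concat([ev, units[~units["event"]]], ignore_index=True)
    units = units.sort_values(["caseid", "drug"],
                              kind="mergesort").reset_index(drop=True)
    cols = ["caseid", "drug", "event", "dechal", "rechal", "reporter",
            "serious"]
    if events_as_records:
        cols.insert(3, "pt_code")
    return units[cols]


def describe_cohort(case_table: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by sex, age group, raw reporter
    occupation, and the collapsed reporter class.

    Percentages are 100*count/total cases, rounded to 2 decimals.
    """
    total = len(case_table)
    if total == 0:
        out = pd.DataFrame(columns=["characteristic", "level", "count", "pct"])
        out.attrs["total"] = 0
        return out
    blocks = []
    specs = [
        ("sex", ["male", "female", "unknown"]),
        ("age_group", AGE_GROUPS),
        ("reporter", ["consumer", "healthcare_professional", "unspecified"]),
    ]
    if "occupation" in case_table.columns:
        specs.insert(2, ("occupation",
                         sorted(case_table["occupation"].unique())))
    for colname, levels in specs:
        if total:
            counts = case_table[colname].value_counts()
        else:
            counts = pd.Series(dtype=int)
        for level in levels:
            c = int(counts.get(level, 0))
            pct = round(100.0 * c / total, 2) if total else 0.0
            blocks.append({"characteristic": colname, "level": level,
                           "count": c, "pct": pct})
    out = pd.DataFrame(blocks,
                       columns=["characteristic", "level", "count", "pct"])
    out.attrs["total"] = total
    return out
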