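"""Reading FAERS-dialect quarterly packages and case-level cleaning.

A package directory holds, per quarter, five ``$``-delimited ASCII
tables (DEMO, DRUG, REAC, THER, OUTC, named like ``DEMO23Q1.txt`` with a
header line) plus an optional one-caseid-per-line deletion list
(``DELETED23Q1.txt``).  Fields containing the delimiter are
double-quoted; embedded quotes are doubled.

Cleaning follows the standard spontaneous-report workflow: report
versions sharing a CASEID are collapsed to the most recent one (maximum
FDA_DT, ties broken by the maximum PRIMARYID), then cases named on the
deletion lists are removed.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_FIELDS",
    "FaersPackage",
    "CaseKey",
    "RawCaseVersion",
    "ParseReport",
    "write_table",
    "write_deletion_list",
    "read_faers_package",
    "deduplicate",
    "apply_deletion_lists",
]

DELIM = "$"

TABLE_FIELDS: dict[str, list[str]] = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname",
             "dechal", "rechal"],
    "REAC": ["primaryid", "caseid", "pt"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
}

_QUARTER_RE = re.compile(r"^DEMO(\d{2}Q[1-4])\.txt$", re.IGNORECASE)


def table_filename(table: str, quarter: str) -> str:
    """``("DEMO", "2023Q1") -> "DEMO23Q1.txt"``."""
    return f"{table}{quarter[2:4]}Q{quarter[-1]}.txt"


def deletion_filename(quarter: str) -> str:
    return f"DELETED{quarter[2:4]}Q{quarter[-1]}.txt"


class CaseKey(NamedTuple):
    caseid: str
    fda_dt: int
    primaryid: str


@dataclass
class RawCaseVersion:
    """One report version: the unit FAERS stores per (primaryid, caseid)."""
    key: CaseKey
    demo: dict
    drugs: list[dict] = field(default_factory=list)
    reactions: list[dict] = field(default_factory=list)
    therapies: list[dict] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)


@dataclass
class ParseReport:
    n_lines: dict = field(default_factory=dict)
    n_malformed: dict = field(default_factory=dict)
    n_rejected_demo: int = 0

    def total_malformed(self) -> int:
        return sum(self.n_malformed.values())


@dataclass
class FaersPackage:
    """All rows of a quarterly package span, as one DataFrame per table."""
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    deleted_ids: set = field(default_factory=set)
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)
    report: ParseReport = field(default_factory=ParseReport)

    def filter_primaryids(self, primaryids: Iterable[str]) -> "FaersPackage":
        keep = set(primaryids)
        return FaersPackage(
            demo=self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            drug=self.drug[self.drug["primaryid"].isin(keep)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(keep)].reset_index(drop=True),
            ther=self.ther[self.ther["primaryid"].isin(keep)].reset_index(drop=True),
            outc=self.outc[self.outc["primaryid"].isin(keep)].reset_index(drop=True),
            deleted_ids=set(self.deleted_ids),
            rejects=self.rejects,
            report=self.report,
        )

    def versions(self) -> list[RawCaseVersion]:
        """Materialise per-version records (intended for small inputs)."""
        drugs = {k: g.to_dict("records") for k, g in self.drug.groupby("primaryid")}
        reacs = {k: g.to_dict("records") for k, g in self.reac.groupby("primaryid")}
        thers = {k: g.to_dict("records") for k, g in self.ther.groupby("primaryid")}
        outcs = {k: g["outc_cod"].tolist() for k, g in self.outc.groupby("primaryid")}
        out = []
        for row in self.demo.to_dict("records"):
            pid = row["primaryid"]
            out.append(RawCaseVersion(
                key=CaseKey(row["caseid"], int(row["fda_dt"]), pid),
                demo=row,
                drugs=drugs.get(pid, []),
                reactions=reacs.get(pid, []),
                therapies=thers.get(pid, []),
                outcomes=outcs.get(pid, []),
            ))
        return out


# ---------------------------------------------------------------------------
# writing (the dialect's reference writer; synth_srs uses it)
# ---------------------------------------------------------------------------

def write_table(path: Path, table: str, df: pd.DataFrame) -> None:
    fields = TABLE_FIELDS[table]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=DELIM, quoting=csv.QUOTE_MINIMAL,
                       lineterminator="\n")
        w.writerow(fields)
        for row in df[fields].itertuples(index=False):
            w.writerow(["" if pd.isna(v) else str(v) for v in row])


def write_deletion_list(path: Path, caseids: Iterable[str]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for cid in caseids:
            fh.write(f"{cid}\n")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _decode_lines(path: Path) -> Iterable[str]:
    """UTF-8 with per-line Latin-1 fallback (real files mix encodings)."""
    with open(path, "rb") as fh:
        for raw in fh:
            try:
                yield raw.decode("utf-8")
            except UnicodeDecodeError:
                yield raw.decode("latin-1")


def _read_table(path: Path, table: str, report: ParseReport) -> pd.DataFrame:
    fields = TABLE_FIELDS[table]
    lines = _decode_lines(path)
    reader = csv.reader(lines, delimiter=DELIM)
    header = next(reader, None)
    if header is None:
        raise ValueError(f"{path}: empty table")
    header = [h.strip().lower() for h in header]
    if header != fields:
        raise ValueError(
            f"{path}: header mismatch — expected {fields}, found {header}")
    rows, bad = [], 0
    for rec in reader:
        if len(rec) != len(fields):
            bad += 1
            logger.warning("%s: malformed line with %d fields (expected %d)",
                           path.name, len(rec), len(fields))
            continue
        rows.append(rec)
    report.n_lines[path.name] = len(rows)
    if bad:
        report.n_malformed[path.name] = bad
    return pd.DataFrame(rows, columns=fields)


def discover_quarters(path: Path) -> list[str]:
    quarters = []
    for p in sorted(Path(path).iterdir()):
        m = _QUARTER_RE.match(p.name)
        if m:
            yy = m.group(1)[:2]
            quarters.append(f"20{yy}Q{m.group(1)[-1]}")
    return quarters


def read_faers_package(path: str | Path, quarters: list[str] | None = None,
                       *, malformed_tolerance: float = 0.01) -> FaersPackage:
    """Read a package directory into one FaersPackage.

    Malformed lines (field-count mismatches) are logged and counted; the
    read fails only when their fraction in any table exceeds
    ``malformed_tolerance``.
    """
    path = Path(path)
    if quarters is None:
        quarters = discover_quarters(path)
    if not quarters:
        raise FileNotFoundError(f"no DEMO tables found under {path}")
    report = ParseReport()
    frames: dict[str, list[pd.DataFrame]] = {t: [] for t in TABLE_FIELDS}
    deleted: set[str] = set()
    for q in quarters:
        for table in TABLE_FIELDS:
            f = path / table_filename(table, q)
            if not f.exists():
                raise FileNotFoundError(f"missing mandatory table {f}")
            frames[table].append(_read_table(f, table, report))
        dl = path / deletion_filename(q)
        if dl.exists():
            deleted.update(l.strip() for l in _decode_lines(dl) if l.strip())
    for name, bad in report.n_malformed.items():
        total = report.n_lines.get(name, 0) + bad
        if total and bad / total > malformed_tolerance:
            raise ValueError(
                f"{name}: {bad}/{total} malformed lines exceeds tolerance "
                f"{malformed_tolerance}")
    tables = {t: pd.concat(fl, ignore_index=True) for t, fl in frames.items()}

    demo = tables["DEMO"]
    bad_key = (demo["caseid"].str.strip() == "") | \
              (~demo["fda_dt"].str.fullmatch(r"\d{8}").fillna(False))
    rejects = demo[bad_key].reset_index(drop=True)
    if len(rejects):
        logger.warning("quarantined %d DEMO rows missing caseid/fda_dt",
                       len(rejects))
    report.n_rejected_demo = int(len(rejects))
    demo = demo[~bad_key].reset_index(drop=True)

    pkg = FaersPackage(demo=demo, drug=tables["DRUG"], reac=tables["REAC"],
                       ther=tables["THER"], outc=tables["OUTC"],
                       deleted_ids=deleted, rejects=rejects, report=report)
    logger.info("read %d quarters: %d versions, %d deletion-list ids",
                len(quarters), len(demo), len(deleted))
    return pkg


# ---------------------------------------------------------------------------
# deduplication & deletion lists
# ---------------------------------------------------------------------------

def _pid_sort_key(primaryid: pd.Series) -> pd.Series:
    """Numeric ordering when the id parses as an integer, else the id is
    ranked below all numeric ids and compared lexicographically (real
    FAERS primaryids are numeric strings of varying length)."""
    return pd.to_numeric(primaryid, errors="coerce")


def _dedup_keys(demo: pd.DataFrame) -> pd.DataFrame:
    df = demo.copy()
    df["_fda"] = pd.to_numeric(df["fda_dt"], errors="coerce")
    df["_pidn"] = _pid_sort_key(df["primaryid"])
    df = df.sort_values(
        ["caseid", "_fda", "_pidn", "primaryid"],
        kind="mergesort", na_position="first")
    kept = df.drop_duplicates("caseid", keep="last")
    return kept.drop(columns=["_fda", "_pidn"]).sort_values(
        "caseid", kind="mergesort").reset_index(drop=True)


def deduplicate(data):
    """Collapse report versions to one per caseid.

    Selection keeps the maximum FDA_DT, ties broken by the maximum
    primaryid; output is sorted by caseid.  Accepts a FaersPackage, a
    DEMO-like DataFrame, or a list of RawCaseVersion.
    """
    if isinstance(data, FaersPackage):
        kept = _dedup_keys(data.demo)
        dropped = len(data.demo) - len(kept)
        logger.info("deduplicate: %d versions -> %d cases (%d duplicate "
                    "versions dropped)", len(data.demo), len(kept), dropped)
        return data.filter_primaryids(kept["primaryid"])
    if isinstance(data, pd.DataFrame):
        return _dedup_keys(data)
    versions = list(data)
    if not versions:
        return []
    demo = pd.DataFrame(
        {"caseid": [v.key.caseid for v in versions],
         "fda_dt": [str(v.key.fda_dt) for v in versions],
         "primaryid": [v.key.primaryid for v in versions]})
    kept_pids = set(_dedup_keys(demo)["primaryid"])
    out = [v for v in versions if v.key.primaryid in kept_pids]
    return sorted(out, key=lambda v: v.key.caseid)


def apply_deletion_lists(data, deleted_ids: Iterable[str]):
    """Drop cases whose caseid appears on a deletion list."""
    deleted = {str(x) for x in deleted_ids}
    if isinstance(data, FaersPackage):
        keep = data.demo.loc[~data.demo["caseid"].isin(deleted), "primaryid"]
        removed = len(data.demo) - len(keep)
        logger.info("deletion lists: removed %d of %d cases",
                    removed, len(data.demo))
        out = data.filter_primaryids(keep)
        return out
    if isinstance(data, pd.DataFrame):
        present = data["caseid"].isin(deleted)
        n_hit = int(present.sum())
        missing = deleted - set(data["caseid"])
        if missing:
            logger.warning("%d deletion-list ids not present in data",
                           len(missing))
        logger.info("deletion lists: removed %d of %d cases", n_hit, len(data))
        return data[~present].reset_index(drop=True)
    versions = list(data)
    kept = [v for v in versions if v.key.caseid not in deleted]
    logger.info("deletion lists: removed %d of %d cases",
                len(versions) - len(kept), len(versions))
    return kept
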