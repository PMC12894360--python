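"""Cross-database validation, result export, and the end-to-end
pipeline.

A signal positive in both databases independently is designated
high-confidence: the two systems differ in population, reporting
practice and coding, so their intersection mitigates single-source
reporting biases.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort, dispro, faers_io, strata, synth, timecourse

logger = logging.getLogger(__name__)

__all__ = [
    "intersect_signals",
    "annual_counts",
    "export_results",
    "PipelineConfig",
    "run_pipeline",
]


def _check_name_standardization(names) -> None:
    seen: dict[str, str] = {}
    for name in names:
        key = str(name).strip().casefold()
        if key in seen and seen[key] != name:
            raise ValueError(
                f"same drug under two spellings: {seen[key]!r} vs {name!r}; "
                "apply one synonym table to both databases before "
                "cross-validation")
        seen[key] = name


def intersect_signals(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      labels: tuple[str, str] = ("faers", "ev"),
                      ) -> pd.DataFrame:
    """Join two screening tables on the standardized drug name.

    One row per drug positive in at least one database; the
    ``high_confidence`` flag marks the intersection (positive in both).
    """
    la, lb = labels
    _check_name_standardization(
        list(table_a["drug"]) + list(table_b["drug"]))
    pos_a = table_a[table_a["positive"].astype(bool)]
    pos_b = table_b[table_b["positive"].astype(bool)]
    keep = ["drug", "n", "ror", "ror_low", "ror_high", "prr", "chi2", "ic",
            "ic025", "ebgm", "ebgm05", "positive"]
    merged = pos_a[keep].merge(pos_b[keep], on="drug", how="outer",
                               suffixes=(f"_{la}", f"_{lb}"))
    merged["high_confidence"] = (merged[f"positive_{la}"].eq(True)
                                 & merged[f"positive_{lb}"].eq(True))
    merged = merged.sort_values(
        ["high_confidence", "drug"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    n_both = int(merged["high_confidence"].sum())
    n_a = int(merged[f"positive_{la}"].eq(True).sum()) - n_both
    n_b = int(merged[f"positive_{lb}"].eq(True).sum()) - n_both
    logger.info("cross-validation: %d %s-only, %d %s-only, %d in both "
                "(high-confidence)", n_a, la, n_b, lb, n_both)
    return merged


def annual_counts(faers_cases: pd.DataFrame | None,
                  ev_cases: pd.DataFrame | None) -> pd.DataFrame:
    """Selected-case counts per receipt year and database."""
    frames = []
    for label, cases in (("faers", faers_cases), ("ev", ev_cases)):
        if cases is None or cases.empty:
            continue
        years = pd.to_numeric(cases["year"], errors="coerce").dropna()
        vc = years.astype(int).value_counts().sort_index()
        frames.append(vc.rename(label))
    if not frames:
        return pd.DataFrame(columns=["year", "faers", "ev"])
    out = pd.concat(frames, axis=1).fillna(0).astype(int)
    out.index.name = "year"
    out = out.reset_index()
    for col in ("faers", "ev"):
        if col not in out:
            out[col] = 0
    return out[["year", "faers", "ev"]]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

EXPORT_FILES = [
    "cohort_summary.csv", "signals_faers.csv", "signals_ev.csv",
    "crossval.csv", "dechal.csv", "rechal.csv", "strata_consumer.csv",
    "strata_healthcare_professional.csv", "atc.csv", "tto.csv",
    "km_curve.csv", "annual_counts.csv",
]


def export_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                   run_info: dict | None = None) -> list[Path]:
    """Write the deterministic result file set plus ``run_log.json``.

    Every name in the canonical set is written; a missing or empty
    table yields a header-only file.  Identical inputs produce
    byte-identical outputs (no timestamps; stable row order is the
    caller's contract).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    defaults = {name: pd.DataFrame(columns=dispro.SIGNAL_COLUMNS)
                for name in EXPORT_FILES}
    defaults["cohort_summary.csv"] = pd.DataFrame(
        columns=["characteristic", "level", "count", "pct"])
    defaults["tto.csv"] = pd.DataFrame(columns=["caseid", "days", "serious"])
    defaults["km_curve.csv"] = pd.DataFrame(
        columns=["time", "cdf", "n_at_risk"])
    defaults["annual_counts.csv"] = pd.DataFrame(
        columns=["year", "faers", "ev"])
    for name in EXPORT_FILES:
        df = tables.get(name.removesuffix(".csv"), defaults[name])
        path = out_dir / name
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    log_path = out_dir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(run_info or {}, fh, indent=1, sort_keys=True)
    written.append(log_path)
    logger.info("exported %d result files to %s", len(written), out_dir)
    return written


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``synthetic`` (generate both databases) or input paths
    (``faers_dir`` and/or ``ev_listing``) must be provided.
    """
    seed: int = 0
    synthetic: synth.SyntheticConfig | dict | None = None
    faers_dir: str | None = None
    ev_listing: str | None = None
    terms_file: str | None = None      # packaged 13-term default when None
    synonyms_file: str | None = None
    atc_file: str | None = None        # packaged toy mapping when None
    criterion: dict = field(default_factory=dict)
    min_reports: int = 1
    events_as_records_for_atc: bool = True
    chi2_correction: bool = True
    ic025_method: str = "normal"

    def __post_init__(self):
        if isinstance(self.synthetic, dict):
            self.synthetic = synth.SyntheticConfig(**self.synthetic)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def signal_criterion(self) -> dispro.SignalCriterion:
        return dispro.SignalCriterion(**self.criterion)


def _load_terms(config: PipelineConfig) -> cohort.EventTermList:
    if config.terms_file is None:
        return cohort.load_default_terms()
    p = Path(config.terms_file)
    if not p.exists():
        raise FileNotFoundError(f"terms file not found: {p}")
    return cohort.EventTermList.from_csv(p)


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 ) -> dict[str, pd.DataFrame]:
    """Execute ingest -> cohort -> screening -> strata -> time course ->
    cross-validation -> export; returns the result tables that were
    written.

    Every stage logs its record counts; any stage failure propagates
    with a stage-tagged message.
    """
    out_dir = Path(out_dir)
    stage = "configure"
    counts: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}
    config_snapshot = _config_snapshot(config)
    try:
        terms = _load_terms(config)
        criterion = config.signal_criterion()
        screen_kw = dict(min_reports=config.min_reports,
                         chi2_correction=config.chi2_correction,
                         ic025_method=config.ic025_method)

        stage = "simulate"
        faers_cd = ev_cd = None
        if config.synthetic is not None:
            scfg = dataclasses.replace(config.synthetic, seed=config.seed)
            out_dir.mkdir(parents=True, exist_ok=True)
            synth.generate_faers_package(scfg, out_dir / "synthetic_faers")
            ev_cfg = dataclasses.replace(scfg, seed=scfg.seed + 1)
            listing, _ = synth.generate_ev_listing(
                ev_cfg, out_dir / "synthetic_ev.csv")
            config = dataclasses.replace(
                config, faers_dir=str(out_dir / "synthetic_faers"))
            ev_df = listing
        elif config.ev_listing is not None:
            ev_df = pd.read_csv(config.ev_listing, dtype=str)
        else:
            ev_df = None

        stage = "ingest"
        if config.faers_dir is not None:
            pkg = faers_io.read_faers_package(config.faers_dir)
            counts["faers_versions"] = len(pkg.demo)
            pkg = faers_io.deduplicate(pkg)
            counts["faers_cases_deduplicated"] = len(pkg.demo)
            pkg = faers_io.apply_deletion_lists(pkg, pkg.deleted_ids)
            counts["faers_cases_after_deletion"] = len(pkg.demo)
            faers_cd = cohort.from_faers(pkg)
        if ev_df is not None:
            ev_cd = cohort.from_ev(ev_df)
            counts["ev_master_cases"] = len(ev_cd.cases)
        if faers_cd is None and ev_cd is None:
            raise ValueError("no input: provide synthetic, faers_dir or "
                             "ev_listing")

        stage = "standardize"
        if config.synonyms_file is not None:
            if faers_cd is not None:
                faers_cd = cohort.standardize_drug_names(
                    faers_cd, config.synonyms_file)
            if ev_cd is not None:
                ev_cd = cohort.standardize_drug_names(
                    ev_cd, config.synonyms_file)

        stage = "cohort"
        faers_cases = faers_units = ev_cases = ev_units = None
        if faers_cd is not None:
            faers_cases, faers_records = cohort.select_cases(faers_cd, terms)
            counts["faers_selected_cases"] = len(faers_cases)
            counts["faers_drug_event_records"] = len(faers_records)
            faers_units = cohort.screening_units(faers_cd, terms)
            counts["faers_units"] = len(faers_units)
            tables["cohort_summary"] = cohort.describe_cohort(faers_cases)
        if ev_cd is not None:
            ev_cases, ev_records = cohort.select_cases(ev_cd, terms)
            counts["ev_selected_cases"] = len(ev_cases)
            ev_units = cohort.screening_units(ev_cd, terms)
            counts["ev_units"] = len(ev_units)

        stage = "screen"
        sig_f = sig_e = None
        if faers_units is not None:
            sig_f = dispro.screen(faers_units, criterion, **screen_kw)
            tables["signals_faers"] = sig_f
        if ev_units is not None:
            sig_e = dispro.screen(ev_units, criterion, **screen_kw)
            tables["signals_ev"] = sig_e

        stage = "strata"
        if faers_units is not None:
            for which in ("dechal", "rechal"):
                sub = strata.dechal_rechal_subset(faers_units, which)
                tables[which] = dispro.screen(sub, criterion, **screen_kw)
            atc = (strata.load_toy_atc() if config.atc_file is None
                   else strata.AtcMapping.from_csv(config.atc_file))
            atc_units = (cohort.screening_units(
                faers_cd, terms, events_as_records=True)
                if config.events_as_records_for_atc else faers_units)
            tables["atc"] = strata.atc_screen(atc_units, atc, criterion,
                                              **screen_kw)
        for stratum in ("consumer", "healthcare_professional"):
            parts = []
            for label, units in (("faers", faers_units), ("ev", ev_units)):
                if units is None:
                    continue
                sub = units[units["reporter"] == stratum]
                if sub.empty:
                    continue
                t = dispro.screen(sub, criterion, **screen_kw)
                t.insert(0, "source", label)
                parts.append(t)
            if parts:
                tables[f"strata_{stratum}"] = pd.concat(parts,
                                                        ignore_index=True)

        stage = "timecourse"
        if faers_cd is not None:
            obs, tto_report = timecourse.compute_tto(faers_cd, terms)
            tables["tto"] = obs
            counts.update({f"tto_{k}": v for k, v in tto_report.items()
                           if isinstance(v, int)})
            curve, median, iqr = timecourse.km_cdf(obs)
            tables["km_curve"] = curve
            counts["tto_median_days"] = None if pd.isna(median) else int(median)
            if len(obs) and obs["serious"].nunique() == 2:
                stat, pval = timecourse.compare_seriousness(obs)
                counts["wilcoxon_p_seriousness"] = round(pval, 6)

        stage = "crossval"
        if sig_f is not None and sig_e is not None:
            tables["crossval"] = intersect_signals(sig_f, sig_e)
            counts["high_confidence_drugs"] = int(
                tables["crossval"]["high_confidence"].sum())
        tables["annual_counts"] = annual_counts(faers_cases, ev_cases)

        stage = "export"
        run_info = {
            "seed": config.seed,
            "counts": counts,
            "criterion": dataclasses.asdict(criterion),
            "config": config_snapshot,
        }
        export_results(tables, out_dir, run_info)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return tables


def _config_snapshot(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
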