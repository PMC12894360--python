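"""Time-to-onset analysis.

Time-to-onset (TTO) is the number of days from the first administration
of a qualifying suspect drug to the reported event.  Only full 8-digit
start and event dates enter the analysis; partial dates and negative
intervals are excluded and accounted for in a completeness report.  The
cumulative onset distribution is built with the Kaplan-Meier estimator
(all observations are events — spontaneous reports record occurred
reactions — so the KM CDF coincides with the empirical CDF, but the
machinery admits censored extensions), and onset timing is compared
across seriousness strata with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import CaseData, EventTermList, load_default_terms, \
    _matched_codes_per_case, _QUALIFYING_ROLES

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tto",
    "segment_distribution",
    "km_cdf",
    "compare_seriousness",
    "DEFAULT_BINS",
]

# closed bins in days: early / intermediate / late
DEFAULT_BINS = [(0, 30), (31, 360), (361, None)]


def compute_tto(cd: CaseData, terms: EventTermList | None = None,
                ) -> tuple[pd.DataFrame, dict]:
    """Per-case time-to-onset for the selected cohort.

    days = event date minus the earliest full start date over the
    case's qualifying suspect drug rows.  Returns the observation table
    (caseid, days, serious) and a completeness report counting the
    exclusions.
    """
    if terms is None:
        terms = load_default_terms()
    matched_ids = set(_matched_codes_per_case(cd, terms)["caseid"])
    male = cd.cases[cd.cases["sex"] == "male"]
    cases = male[male["caseid"].isin(matched_ids)].copy()

    qual = cd.drugs[cd.drugs["role"].isin(_QUALIFYING_ROLES)]
    qual = qual[qual["caseid"].isin(set(cases["caseid"]))]
    starts = qual.dropna(subset=["start_full"]).groupby("caseid")[
        "start_full"].min()

    cases["event_full"] = cases["event_date"].str.fullmatch(r"\d{8}")
    cases["start_full"] = cases["caseid"].map(starts)

    report = {"n_cases": int(len(cases))}
    complete = cases[cases["event_full"] & cases["start_full"].notna()].copy()
    report["n_partial_or_missing_dates"] = int(len(cases) - len(complete))

    ev = pd.to_datetime(complete["event_date"], format="%Y%m%d")
    st = pd.to_datetime(complete["start_full"].astype(int).astype(str),
                        format="%Y%m%d")
    complete["days"] = (ev - st).dt.days
    negative = complete["days"] < 0
    report["n_negative_interval"] = int(negative.sum())
    obs = complete.loc[~negative, ["caseid", "days", "serious"]]
    obs = obs.reset_index(drop=True)
    report["n_observations"] = int(len(obs))
    report["completeness"] = round(len(obs) / len(cases), 4) if len(cases) else 0.0
    logger.info("time-to-onset: %d of %d cases with computable interval "
                "(%d partial/missing, %d negative)", len(obs), len(cases),
                report["n_partial_or_missing_dates"],
                report["n_negative_interval"])
    return obs, report


def segment_distribution(observations: pd.DataFrame,
                         bins=DEFAULT_BINS) -> pd.DataFrame:
    """Counts and percentages of observations per closed day-range bin."""
    edges = []
    for lo, hi in bins:
        hi_v = np.inf if hi is None else hi
        if hi_v < lo:
            raise ValueError(f"bin ({lo}, {hi}) is empty")
        edges.append((lo, hi_v))
    for (l1, h1), (l2, h2) in zip(edges, edges[1:]):
        if l2 <= h1:
            raise ValueError("overlapping bins")
    days = observations["days"].to_numpy() if len(observations) else \
        np.array([], dtype=int)
    total = len(days)
    rows = []
    for (lo, hi), (blo, bhi) in zip(edges, bins):
        n = int(((days >= lo) & (days <= hi)).sum())
        label = f"{blo}-{'inf' if bhi is None else bhi}"
        pct = round(100.0 * n / total, 2) if total else 0.0
        rows.append({"bin": label, "count": n, "pct": pct})
    out = pd.DataFrame(rows, columns=["bin", "count", "pct"])
    if total and out["count"].sum() != total:
        logger.warning("%d observations fall outside the configured bins",
                       total - int(out["count"].sum()))
    return out


def km_cdf(observations: pd.DataFrame,
           ) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Kaplan-Meier cumulative onset distribution.

    Returns (curve, median, (q25, q75)).  The curve has one row per
    distinct time with columns time, cdf, n_at_risk; with no censoring
    it equals the empirical CDF.  Quantiles are the smallest times at
    which the CDF reaches the target level.
    """
    days = observations["days"].to_numpy()
    if len(days) == 0:
        empty = pd.DataFrame(columns=["time", "cdf", "n_at_risk"])
        return empty, float("nan"), (float("nan"), float("nan"))
    kmf = KaplanMeierFitter()
    kmf.fit(days, event_observed=np.ones_like(days))
    sf = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    curve = pd.DataFrame({
        "time": sf.index.to_numpy(dtype=float),
        "cdf": 1.0 - sf.to_numpy(),
        "n_at_risk": at_risk.to_numpy(dtype=int),
    })
    curve = curve[curve["time"] >= 0].reset_index(drop=True)

    def quantile(level: float) -> float:
        # tolerance absorbs product-form rounding in the KM estimate
        hit = curve[curve["cdf"] >= level - 1e-9]
        return float(hit["time"].iloc[0]) if len(hit) else float("nan")

    median = quantile(0.5)
    iqr = (quantile(0.25), quantile(0.75))
    return curve, median, iqr


def compare_seriousness(observations: pd.DataFrame,
                        exact_max_n: int = 20) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of onset times
    between serious and non-serious reports.

    Exact enumeration when both strata have at most ``exact_max_n``
    observations, otherwise the tie-corrected normal approximation.
    Returns (U statistic for the serious stratum, two-sided p).
    """
    serious = observations.loc[observations["serious"].astype(bool), "days"]
    nonserious = observations.loc[~observations["serious"].astype(bool), "days"]
    if len(serious) == 0 or len(nonserious) == 0:
        raise ValueError("both seriousness strata must be non-empty")
    method = ("exact" if max(len(serious), len(nonserious)) <= exact_max_n
              else "asymptotic")
    res = stats.mannwhitneyu(serious, nonserious, alternative="two-sided",
                             method=method)
    return float(res.statistic), float(res.pvalue)
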