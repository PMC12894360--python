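"""Disproportionality statistics for spontaneous-report screening.

Implements the four classical signal-detection measures on a 2x2
contingency table of reporting counts — reporting odds ratio (ROR),
proportional reporting ratio (PRR), the Bayesian information component
(IC, the BCPNN statistic), and the empirical-Bayes geometric mean
(EBGM, the MGPS statistic in its unshrunk relative-reporting-ratio
form) — together with the conjunctive positive-signal criterion used to
flag a drug-event pair.

The table cells are, within one stratum of counting units::

    a  : units with the target drug AND the target event
    b  : units with the target drug, other events
    c  : units with other drugs, the target event
    d  : units with other drugs, other events

Closed forms
------------
ROR  = a*d / (b*c), 95% CI = exp(ln ROR +- 1.96*s),
       s = sqrt(1/a + 1/b + 1/c + 1/d)
PRR  = [a/(a+b)] / [c/(c+d)], 95% CI via
       s_PRR = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))
chi2 = Pearson statistic on the 2x2 (Yates-corrected by default)
RRR  = a*N / ((a+b)*(a+c))        (relative reporting ratio)
EBGM = RRR;  EBGM05 = EBGM * exp(-1.96*s)   (log-normal lower bound)
IC   = log2(RRR); IC025 per the configured variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "SignalCriterion",
    "DisproportionalityResult",
    "DegenerateTableError",
    "build_contingency",
    "compute_stats",
    "evaluate_signal",
    "screen",
    "reconstruct_table",
]

Z95 = 1.959963984540054  # exact two-sided 95% normal quantile
LN2 = math.log(2.0)


class DegenerateTableError(ValueError):
    """A table cell/marginal pattern for which a statistic is undefined."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 reporting-count table for one drug (or drug class) vs. the
    target event set, within one stratum of counting units."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("empty table (N=0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class SignalCriterion:
    """Conjunctive positive-signal thresholds.

    A drug is flagged positive only when every condition holds
    simultaneously: a >= min_a, ROR lower CI > ror_low_gt,
    PRR >= prr_ge with chi2 >= chi2_ge, IC025 > ic025_gt and
    EBGM05 > ebgm05_gt.
    """

    min_a: int = 3
    ror_low_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass
class DisproportionalityResult:
    drug: str
    a: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    positive: bool = False

    def as_dict(self) -> dict:
        d = asdict(self)
        d["n"] = d["a"]
        return d


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_contingency(units: pd.DataFrame, drug: str,
                      drug_col: str = "drug",
                      event_col: str = "event") -> ContingencyTable:
    """Tabulate one drug against the target event over a stratum of
    counting units.

    ``units`` holds one row per counting unit (by convention a unique
    case-drug pair) with a boolean ``event`` column marking target-event
    membership.  The whole frame is the stratum background: N = len(units).
    """
    if units.empty:
        raise DegenerateTableError("empty stratum")
    is_drug = units[drug_col].to_numpy() == drug
    if not is_drug.any():
        raise DegenerateTableError(f"drug {drug!r} absent from stratum (a+b=0)")
    ev = units[event_col].to_numpy().astype(bool)
    a = int((is_drug & ev).sum())
    b = int((is_drug & ~ev).sum())
    c = int((~is_drug & ev).sum())
    d = int((~is_drug & ~ev).sum())
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _ic025_bate(a: float, ab: float, ac: float, n: float) -> float:
    """Closed-form BCPNN lower bound (posterior moment approximation).

    Uses the standard hyperparameters alpha1 = beta1 = 1, alpha = beta = 2,
    with gamma chosen so the prior IC expectation is 0.
    """
    alpha1 = beta1 = 1.0
    alpha = beta = 2.0
    gamma11 = 1.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((ab + alpha1) * (ac + beta1))
    e_ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (ab + alpha1) * (ac + beta1))
    )
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - ab + alpha - alpha1) / ((ab + alpha1) * (1 + n + alpha))
        + (n - ac + beta - beta1) / ((ac + beta1) * (1 + n + beta))
    ) / (LN2 ** 2)
    return e_ic - 2.0 * math.sqrt(v_ic)


def _ic025_mc(a: int, b: int, c: int, d: int,
              draws: int, rng: np.random.Generator) -> float:
    """Monte-Carlo 2.5th percentile of the posterior relative reporting
    ratio under a Jeffreys Dirichlet(1/2,...) prior on the cell
    probabilities."""
    p = rng.dirichlet([a + 0.5, b + 0.5, c + 0.5, d + 0.5], size=draws)
    rrr = p[:, 0] / ((p[:, 0] + p[:, 1]) * (p[:, 0] + p[:, 2]))
    return float(np.log2(np.quantile(rrr, 0.025)))


def compute_stats(table: ContingencyTable, drug: str = "",
                  *,
                  chi2_correction: bool = True,
                  zero_cell_correction: bool = True,
                  ic025_method: str = "normal",
                  mc_draws: int = 20000,
                  rng: np.random.Generator | None = None,
                  ) -> DisproportionalityResult:
    """Evaluate all four disproportionality statistics on one table.

    Parameters
    ----------
    chi2_correction:
        Apply the Yates continuity correction to the Pearson statistic
        (the classical PRR-criterion usage).  Set False for the raw
        statistic.
    zero_cell_correction:
        With a zero cell, apply the Haldane-Anscombe +0.5 correction to
        all four cells for the ROR/PRR point and interval computations.
        When False, a zero in b or c raises ``DegenerateTableError``.
    ic025_method:
        "normal" (default): IC - 1.96*s/ln2 with s the log-ROR standard
        error; "bate": closed-form posterior moment approximation;
        "mc": Monte-Carlo posterior percentile (needs ``rng``).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    nan = float("nan")
    if a + b == 0 or a + c == 0:
        # drug or event absent: every measure undefined
        return DisproportionalityResult(drug, a, *[nan] * 12)

    has_zero = min(a, b, c, d) == 0
    if has_zero and not zero_cell_correction:
        raise DegenerateTableError(
            f"zero cell in table ({a},{b},{c},{d}) with correction disabled")
    # corrected cells drive ROR/PRR (point + CI) and the shared log-SE
    ca, cb, cc, cd = (x + 0.5 for x in (a, b, c, d)) if has_zero else (a, b, c, d)

    s = math.sqrt(1 / ca + 1 / cb + 1 / cc + 1 / cd)
    ror = (ca * cd) / (cb * cc)
    ror_low = ror * math.exp(-Z95 * s)
    ror_high = ror * math.exp(Z95 * s)

    prr = (ca / (ca + cb)) / (cc / (cc + cd))
    s_prr_sq = 1 / ca - 1 / (ca + cb) + 1 / cc - 1 / (cc + cd)
    s_prr = math.sqrt(max(s_prr_sq, 0.0))
    prr_low = prr * math.exp(-Z95 * s_prr)
    prr_high = prr * math.exp(Z95 * s_prr)

    if min(a + b, c + d, a + c, b + d) == 0:
        chi2 = nan  # a zero margin leaves the Pearson statistic undefined
    else:
        chi2 = float(stats.chi2_contingency(table.as_array(),
                                            correction=chi2_correction)[0])

    rrr = a * n / ((a + b) * (a + c))
    ebgm = rrr
    ebgm05 = ebgm * math.exp(-Z95 * s)
    ic = math.log2(rrr) if rrr > 0 else -math.inf

    if ic025_method == "normal":
        ic025 = ic - Z95 * s / LN2
    elif ic025_method == "bate":
        ic025 = _ic025_bate(a, a + b, a + c, n)
    elif ic025_method == "mc":
        if rng is None:
            rng = np.random.default_rng(0)
        ic025 = _ic025_mc(a, b, c, d, mc_draws, rng)
    else:
        raise ValueError(f"unknown ic025_method {ic025_method!r}")

    return DisproportionalityResult(
        drug, a, ror, ror_low, ror_high, prr, prr_low, prr_high,
        chi2, ic, ic025, ebgm, ebgm05)


def evaluate_signal(result: DisproportionalityResult,
                    criterion: SignalCriterion = SignalCriterion(),
                    ) -> tuple[bool, dict[str, bool]]:
    """Apply the conjunctive criterion; returns the flag and the
    per-condition breakdown."""
    def ok(x: float) -> bool:
        return np.isfinite(x)

    breakdown = {
        "min_reports": result.a >= criterion.min_a,
        "ror_low": ok(result.ror_low) and result.ror_low > criterion.ror_low_gt,
        "prr": ok(result.prr) and result.prr >= criterion.prr_ge,
        "chi2": ok(result.chi2) and result.chi2 >= criterion.chi2_ge,
        "ic025": ok(result.ic025) and result.ic025 > criterion.ic025_gt,
        "ebgm05": ok(result.ebgm05) and result.ebgm05 > criterion.ebgm05_gt,
    }
    positive = all(breakdown.values())
    result.positive = positive
    return positive, breakdown


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

SIGNAL_COLUMNS = ["drug", "n", "ror", "ror_low", "ror_high", "prr", "prr_low",
                  "prr_high", "chi2", "ic", "ic025", "ebgm", "ebgm05",
                  "positive"]


def screen(units: pd.DataFrame,
           criterion: SignalCriterion = SignalCriterion(),
           *,
           drug_col: str = "drug",
           event_col: str = "event",
           min_reports: int = 1,
           chi2_correction: bool = True,
           zero_cell_correction: bool = True,
           ic025_method: str = "normal",
           rng: np.random.Generator | None = None,
           ) -> pd.DataFrame:
    """Screen every drug in a stratum of counting units.

    Returns one row per drug with a >= ``min_reports`` target-event
    units, all statistics, and the positive flag; sorted by ROR
    descending with lexicographic drug-name tie-break.
    """
    if units.empty:
        return pd.DataFrame(columns=SIGNAL_COLUMNS)
    ev = units[event_col].astype(bool)
    grp = units.groupby(drug_col, sort=True)
    tab = grp[event_col].agg(a="sum", ab="count")
    tab["a"] = tab["a"].astype(int)
    n_event = int(ev.sum())
    n_total = int(len(units))
    rows = []
    for drug, r in tab.iterrows():
        a = int(r["a"])
        if a < min_reports:
            continue
        b = int(r["ab"]) - a
        c = n_event - a
        d = n_total - a - b - c
        res = compute_stats(
            ContingencyTable(a, b, c, d), str(drug),
            chi2_correction=chi2_correction,
            zero_cell_correction=zero_cell_correction,
            ic025_method=ic025_method, rng=rng)
        evaluate_signal(res, criterion)
        rows.append(res.as_dict())
    if not rows:
        return pd.DataFrame(columns=SIGNAL_COLUMNS)
    out = pd.DataFrame(rows)[SIGNAL_COLUMNS]
    out = out.sort_values(["ror", "drug"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    n_pos = int(out["positive"].sum())
    logger.info("screened %d drugs (%d units, %d with event): %d positive",
                len(out), n_total, n_event, n_pos)
    return out


# ---------------------------------------------------------------------------
# table reconstruction from printed statistics
# ---------------------------------------------------------------------------

def reconstruct_table(a: int, ror: float, ror_low: float,
                      prr: float) -> ContingencyTable:
    """Recover the (real-valued) 2x2 cells from the published summary
    statistics of a row: a, the ROR point and its 95% lower bound, and
    the PRR point.

    Solves ROR = ad/(bc), PRR = a(c+d)/(c(a+b)) and
    ln(ROR/ROR_low) = 1.96*sqrt(1/a+1/b+1/c+1/d) for (b, c, d) by
    numerical root finding.  Useful for auditing printed screening
    tables whose raw counts were not released; cells are rounded to the
    nearest integer counts.
    """
    s_target = math.log(ror / ror_low) / Z95
    # algebraic reduction used for the starting point:
    # substituting d = ror*b*c/a into PRR gives PRR = (a + ror*b)/(a + b)
    b0 = a * (prr - 1.0) / (ror - prr)
    k = s_target ** 2 - 1.0 / a - 1.0 / b0
    c0 = (1.0 + a / (ror * b0)) / k
    d0 = ror * b0 * c0 / a

    def system(x):
        b, c, d = np.exp(x)  # positivity via log parameterisation
        return [
            a * d / (b * c) - ror,
            (a / (a + b)) / (c / (c + d)) - prr,
            math.log(ror / ror_low) - Z95 * math.sqrt(1/a + 1/b + 1/c + 1/d),
        ]

    sol, info, ier, msg = optimize.fsolve(
        system, np.log([b0, c0, d0]), full_output=True)
    if ier != 1:
        raise RuntimeError(f"table reconstruction did not converge: {msg}")
    b, c, d = (int(round(v)) for v in np.exp(sol))
    return ContingencyTable(a, b, c, d)
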