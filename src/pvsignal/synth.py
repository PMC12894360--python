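"""Synthetic spontaneous-report generator with known ground truth.

Emulates the two database dialects the pipeline ingests — FAERS-style
quarterly ASCII packages (with duplicate report versions and deletion
lists) and a consolidated EudraVigilance-style master-case listing — so
every downstream stage can be tested against a truth manifest.

Generative model
----------------
Each case draws one suspect drug and one reaction Preferred Term from a
joint distribution q(i,j) proportional to lambda_ij * p_i * p_j, where
p are the configured marginal reporting probabilities and lambda_ij = 1
except on planted drug-event cells.  For a planted cell the raw
multiplier lambda is solved numerically so that the *attained* relative
reporting ratio q(i,j) / (q_i. * q_.j) equals the requested target RRR
(a raw multiplier overshoots the marginals it inflates, so plugging the
target in directly would bias the recovered signal low).  Demographics,
reporter occupation, seriousness, dechallenge/rechallenge codes, dates
(with FAERS-style partial-date masking), duplicate versions and
deletion lists are layered on top, independently of the drug-event
draw.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from . import faers_io

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedSignal",
    "SyntheticConfig",
    "TruthManifest",
    "simulate_cases",
    "generate_faers_package",
    "generate_ev_listing",
]

# the screening-list PT codes; manifest tabulations use target-event
# membership defined by this set
DEFAULT_TARGET_PTS = [
    "10050208", "10030300", "10067162", "10041493", "10021929", "10079294",
    "10080320", "10074268", "10074729", "10003495", "10003883", "10049572",
    "10043298",
]

_TARGET_PT_NAMES = {
    "10050208": "Teratospermia", "10030300": "Oligospermia",
    "10067162": "Asthenospermia", "10041493": "Spermatogenesis abnormal",
    "10021929": "Infertility male", "10079294": "Oligoasthenoteratozoospermia",
    "10080320": "Oligoasthenozoospermia", "10074268": "Reproductive toxicity",
    "10074729": "Necrospermia", "10003495": "Aspermia",
    "10003883": "Azoospermia", "10049572": "Testicular necrosis",
    "10043298": "Testicular atrophy",
}

_SIGNAL_DRUGS = [
    "BLEOMYCIN", "CARBAMAZEPINE", "CHORIONIC GONADOTROPHIN", "CITALOPRAM",
    "DOXORUBICIN", "DUTASTERIDE", "ETOPOSIDE", "FINASTERIDE",
    "HYDROXYCARBAMIDE", "LEUPRORELIN", "MEDROXYPROGESTERONE", "MINOXIDIL",
    "PAROXETINE", "SULFASALAZINE", "TAMSULOSIN", "TESTOSTERONE",
    "TRIPTORELIN", "VALPROIC ACID", "VINBLASTINE",
]
_DECOY_DRUGS = [
    "IBUPROFEN", "METFORMIN", "AMOXICILLIN", "ATORVASTATIN", "OMEPRAZOLE",
    "SALBUTAMOL", "LORATADINE", "SERTRALINE", "LISINOPRIL", "WARFARIN",
    "PREDNISONE", "LEVOTHYROXINE", "FUROSEMIDE", "GABAPENTIN", "TRAMADOL",
    "CETIRIZINE", "DOXYCYCLINE", "INSULIN GLARGINE", "TIMOLOL", "ACICLOVIR",
]

_BACKGROUND_EVENTS = [
    ("20000001", "Headache"), ("20000002", "Nausea"), ("20000003", "Diarrhoea"),
    ("20000004", "Rash"), ("20000005", "Fatigue"), ("20000006", "Dizziness"),
    ("20000007", "Vomiting"), ("20000008", "Pruritus"), ("20000009", "Pyrexia"),
    ("20000010", "Insomnia"), ("20000011", "Anxiety"), ("20000012", "Dyspnoea"),
    ("20000013", "Arthralgia"), ("20000014", "Myalgia"), ("20000015", "Cough"),
    ("20000016", "Hypertension"), ("20000017", "Alopecia"),
    ("20000018", "Constipation"), ("20000019", "Abdominal pain"),
    ("20000020", "Oedema peripheral"), ("20000021", "Somnolence"),
    ("20000022", "Tremor"), ("20000023", "Palpitations"),
    ("20000024", "Weight decreased"),
]


def _default_drug_vocabulary() -> list:
    vocab = [[d, 0.01] for d in _SIGNAL_DRUGS]
    vocab += [[d, 0.0405] for d in _DECOY_DRUGS]
    return vocab


def _default_event_vocabulary() -> list:
    vocab = [[code, name, 0.0004] for code, name in _TARGET_PT_NAMES.items()]
    vocab += [[code, name, 0.04] for code, name in _BACKGROUND_EVENTS]
    return vocab


@dataclass
class PlantedSignal:
    """A drug-event association of known strength.

    ``rrr`` is the target relative reporting ratio: the factor by which
    the cell's reporting probability exceeds the product of the
    generated marginals (the quantity the unshrunk EBGM estimates).
    Optional stratum restrictions confine the excess to cases with a
    given occupation code and/or seriousness flag.
    """
    drug: str
    pt_code: str
    rrr: float
    occupation: str | None = None
    serious: bool | None = None

    def __post_init__(self):
        if not self.rrr > 0:
            raise ValueError(f"planted rrr must be > 0, got {self.rrr}")


@dataclass
class SyntheticConfig:
    """Study conditions of one synthetic database draw.

    Defaults emulate the reporting structure of the male-infertility
    screening problem: a 39-drug vocabulary (the 19 screened drugs plus
    20 decoys), the 13 target reproductive-toxicity PTs at low marginal
    probability against 24 common background reactions, reporter and
    age mixes matching the published FAERS cohort, and partial dates at
    a rate that leaves roughly 20% of cases with computable
    time-to-onset — the documented completeness of real spontaneous
    reports.
    """
    seed: int = 0
    n_cases: int = 20000
    drug_vocabulary: list = field(default_factory=_default_drug_vocabulary)
    event_vocabulary: list = field(default_factory=_default_event_vocabulary)
    planted_associations: list = field(default_factory=list)
    duplicate_rate: float = 0.10
    deletion_rate: float = 0.02
    male_fraction: float = 0.5
    # mixture of truncated normals on [0, 95] years; "missing" mass first
    age_distribution: dict = field(default_factory=lambda: {
        "missing": 0.44,
        "components": [[0.8, 35.0, 10.0], [0.2, 60.0, 12.0]],
    })
    occupation_distribution: dict = field(default_factory=lambda: {
        "MD": 0.29, "PH": 0.07, "OT": 0.13, "CN": 0.43, "LW": 0.02,
        "missing": 0.06,
    })
    serious_rate: float = 0.4
    # per-drug time-to-onset model: family + params (days); "default"
    # applies to drugs without their own entry. log-normal median
    # exp(4.883) ~ 132 days.
    tto_model: dict = field(default_factory=lambda: {
        "default": ["lognormal", 4.883, 2.0],
    })
    date_completeness: float = 0.45
    dechal_rechal_model: dict = field(default_factory=lambda: {
        "planted": {"Y": 0.35, "N": 0.05, "U": 0.25, "D": 0.10,
                    "missing": 0.25},
        "background": {"Y": 0.05, "N": 0.10, "U": 0.30, "D": 0.15,
                       "missing": 0.40},
    })
    polytherapy_rate: float = 0.0   # probability of a second suspect drug
    concomitant_rate: float = 0.3   # probability of a non-suspect (role C) drug
    quarters: list = field(default_factory=lambda: [
        "2023Q1", "2023Q2", "2023Q3", "2023Q4",
        "2024Q1", "2024Q2", "2024Q3", "2024Q4"])
    target_pt_codes: list = field(default_factory=lambda: list(DEFAULT_TARGET_PTS))

    def __post_init__(self):
        self.planted_associations = [
            p if isinstance(p, PlantedSignal) else PlantedSignal(**p)
            for p in self.planted_associations]
        self.validate()

    def validate(self) -> None:
        if not self.drug_vocabulary or not self.event_vocabulary:
            raise ValueError("drug and event vocabularies must be non-empty")
        for name, rate in [("duplicate_rate", self.duplicate_rate),
                           ("deletion_rate", self.deletion_rate),
                           ("male_fraction", self.male_fraction),
                           ("serious_rate", self.serious_rate),
                           ("date_completeness", self.date_completeness),
                           ("polytherapy_rate", self.polytherapy_rate),
                           ("concomitant_rate", self.concomitant_rate)]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        for _, p in self.drug_vocabulary:
            if not 0.0 <= p <= 1.0:
                raise ValueError("drug marginal probability outside [0, 1]")
        for _, _, p in self.event_vocabulary:
            if not 0.0 <= p <= 1.0:
                raise ValueError("event marginal probability outside [0, 1]")
        if sum(p for _, p in self.drug_vocabulary) > 1.0 + 1e-9:
            raise ValueError("drug marginal probabilities sum above 1")
        if sum(p for *_, p in self.event_vocabulary) > 1.0 + 1e-9:
            raise ValueError("event marginal probabilities sum above 1")
        drugs = {d for d, _ in self.drug_vocabulary}
        events = {c for c, *_ in self.event_vocabulary}
        for plant in self.planted_associations:
            if plant.drug not in drugs:
                raise ValueError(f"planted drug {plant.drug!r} not in vocabulary")
            if plant.pt_code not in events:
                raise ValueError(f"planted PT {plant.pt_code!r} not in vocabulary")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class TruthManifest:
    """Ground truth recorded alongside a generated database."""
    seed: int
    n_cases: int
    planted: list                 # [{drug, pt_code, target_rrr, raw_multiplier}]
    surviving_caseids: list       # caseids not on any deletion list
    n_versions_emitted: int
    # tabulation of male case-drug units vs target-event membership,
    # among surviving cases: {drug: [event_units, total_units]}
    unit_tabulation: dict
    n_units_total: int
    n_event_units_total: int

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def contingency_cells(self, drug: str) -> tuple[int, int, int, int]:
        """Expected 2x2 cells (a, b, c, d) for one drug."""
        ev, tot = self.unit_tabulation.get(drug, (0, 0))
        a, b = ev, tot - ev
        c = self.n_event_units_total - a
        d = self.n_units_total - a - b - c
        return a, b, c, d


# ---------------------------------------------------------------------------
# planted-cell calibration
# ---------------------------------------------------------------------------

def _solve_multipliers(plants: list[PlantedSignal],
                       p_drug: dict[str, float],
                       p_event: dict[str, float],
                       target_set: set[str]) -> dict[tuple, float]:
    """Solve the raw cell multipliers so each planted association
    attains its target RRR *as the screening measures it* — the drug
    tabulated against the whole target event set.

    For one planted cell (d, e) with raw multiplier L, base event-set
    mass P_E and marginals p_d, p_e, the attained set-level relative
    reporting ratio is

        RRR(L) = Z * (P_E + (L-1) p_e)
                 / ((1 + (L-1) p_e) * (P_E + (L-1) p_d p_e)),

    with Z the joint normaliser.  A raw multiplier both dilutes into
    the unboosted set members and inflates the drug and event-set
    marginals, so RRR(L) is unimodal with a finite ceiling; the solve
    is a 1-D root find on the rising branch.  When the planted PT lies
    outside the screening set the set collapses to {e} and the same
    formula calibrates the single-cell ratio.  Plants on distinct
    drugs interact only through Z and the event-set mass; a short
    fixed-point iteration over the joint solve suffices.
    """
    lambdas = {(p.drug, p.pt_code): p.rrr for p in plants}
    targets = {(p.drug, p.pt_code): p.rrr for p in plants}
    p_set_base = sum(p_event[e] for e in p_event if e in target_set)
    for _ in range(12):
        z = 1.0 + sum((lam - 1.0) * p_drug[d] * p_event[e]
                      for (d, e), lam in lambdas.items())
        new = {}
        for (d, e), target in targets.items():
            pd_, pe_ = p_drug[d], p_event[e]
            if e in target_set:
                # event-set mass excluding this plant's own cell,
                # including the excess mass other plants add to the set
                pE = p_set_base + sum(
                    (lam - 1.0) * p_drug[d2] * p_event[e2]
                    for (d2, e2), lam in lambdas.items()
                    if (d2, e2) != (d, e) and e2 in target_set)
            else:
                pE = pe_

            def attained(lam, pd_=pd_, pe_=pe_, pE=pE, z=z):
                num = pE + (lam - 1) * pe_
                den = (1 + (lam - 1) * pe_) * (pE + (lam - 1) * pd_ * pe_)
                return z * num / den

            f = lambda lam: attained(lam) - target  # noqa: E731
            if target == 1.0:
                new[(d, e)] = 1.0
                continue
            if target < 1.0:
                new[(d, e)] = optimize.brentq(f, 1e-9, 1.0,
                                              xtol=1e-12, rtol=1e-13)
                continue
            # locate the unimodal peak, then solve on the rising branch
            grid = np.logspace(0.0, 9.0, 400)
            vals = np.array([attained(g) for g in grid])
            peak = int(np.argmax(vals))
            if vals[peak] < target:
                raise ValueError(
                    f"target RRR {target} unattainable for ({d}, {e}): "
                    f"set-level ceiling is {vals[peak]:.3g} at these "
                    "marginals")
            new[(d, e)] = optimize.brentq(f, 1.0, grid[peak],
                                          xtol=1e-12, rtol=1e-13)
        if all(abs(new[k] - lambdas[k]) < 1e-9 * max(1.0, lambdas[k])
               for k in new):
            lambdas = new
            break
        lambdas = new
    for (d, e), lam in lambdas.items():
        if lam * p_drug[d] * p_event[e] > 1.0:
            raise ValueError(
                f"planted multiplier for ({d}, {e}) drives cell probability "
                "above 1")
    return lambdas


# ---------------------------------------------------------------------------
# core case simulator
# ---------------------------------------------------------------------------

def _sample_categorical(rng, labels, probs, n):
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(labels), size=n, p=probs)
    return np.asarray(labels, dtype=object)[idx]


def _sample_ages(rng, spec, n):
    miss = spec.get("missing", 0.0)
    comps = spec["components"]
    weights = np.array([c[0] for c in comps], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(comps), size=n, p=weights)
    means = np.array([c[1] for c in comps])[which]
    sds = np.array([c[2] for c in comps])[which]
    ages = np.clip(rng.normal(means, sds), 0.0, 95.0)
    ages = np.round(ages).astype(float)
    ages[rng.random(n) < miss] = np.nan
    return ages


def _sample_tto(rng, model, drugs):
    days = np.empty(len(drugs), dtype=float)
    drugs = np.asarray(drugs, dtype=object)
    for drug in np.unique(drugs):
        spec = model.get(str(drug), model["default"])
        mask = drugs == drug
        family = spec[0]
        if family == "lognormal":
            mu, sigma = float(spec[1]), float(spec[2])
            days[mask] = rng.lognormal(mu, sigma, mask.sum())
        elif family == "weibull":
            shape, scale = float(spec[1]), float(spec[2])
            days[mask] = scale * rng.weibull(shape, mask.sum())
        elif family == "exponential":
            days[mask] = rng.exponential(float(spec[1]), mask.sum())
        else:
            raise ValueError(f"unknown tto family {family!r}")
    # heavy-tailed families can draw implausible multi-century onsets;
    # therapy never predates the report window by more than ~20 years
    return np.minimum(np.floor(days), 7300.0).astype(int)


def _mask_dates(rng, dates: pd.Series, completeness: float) -> np.ndarray:
    """Full YYYYMMDD with probability ``completeness``; otherwise the
    partial forms real reports carry (YYYYMM or YYYY, split evenly)."""
    full = dates.dt.strftime("%Y%m%d").to_numpy(dtype=object)
    r = rng.random(len(full))
    out = full.copy()
    part6 = (r >= completeness) & (r < completeness + (1 - completeness) / 2)
    part4 = r >= completeness + (1 - completeness) / 2
    out[part6] = dates.dt.strftime("%Y%m").to_numpy(dtype=object)[part6]
    out[part4] = dates.dt.strftime("%Y").to_numpy(dtype=object)[part4]
    return out


def _quarter_bounds(quarter: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    year, q = int(quarter[:4]), int(quarter[-1])
    start = pd.Timestamp(year=year, month=3 * (q - 1) + 1, day=1)
    end = start + pd.offsets.QuarterEnd(0)
    return start, end


def quarter_of(dates: pd.Series) -> pd.Series:
    return dates.dt.year.astype(str) + "Q" + dates.dt.quarter.astype(str)


def simulate_cases(config: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the latent case table both dialect writers serialise.

    One row per master case; duplicate versions, file layout and
    deletion lists are applied by the writers.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cases

    drug_names = [d for d, _ in config.drug_vocabulary]
    p_drug_raw = np.array([p for _, p in config.drug_vocabulary], dtype=float)
    p_drug_raw /= p_drug_raw.sum()
    p_drug = dict(zip(drug_names, p_drug_raw))
    event_codes = [c for c, _, _ in config.event_vocabulary]
    event_names = {c: nm for c, nm, _ in config.event_vocabulary}
    p_event_raw = np.array([p for *_, p in config.event_vocabulary], dtype=float)
    p_event_raw /= p_event_raw.sum()
    p_event = dict(zip(event_codes, p_event_raw))

    lambdas = _solve_multipliers(config.planted_associations, p_drug,
                             p_event, set(config.target_pt_codes))

    # demographics first (planted strata may condition on them)
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    ages = _sample_ages(rng, config.age_distribution, n)
    occ_labels = list(config.occupation_distribution)
    occ = _sample_categorical(
        rng, occ_labels, list(config.occupation_distribution.values()), n)
    occ = np.where(occ == "missing", "", occ)
    serious = rng.random(n) < config.serious_rate

    # drug-event draw, per stratum pattern of active plants
    restricted = [p for p in config.planted_associations
                  if p.occupation is not None or p.serious is not None]
    active = np.ones((n, len(config.planted_associations)), dtype=bool)
    for j, plant in enumerate(config.planted_associations):
        if plant.occupation is not None:
            active[:, j] &= occ == plant.occupation
        if plant.serious is not None:
            active[:, j] &= serious == plant.serious
    drug = np.empty(n, dtype=object)
    event = np.empty(n, dtype=object)
    patterns = (np.unique(active, axis=0) if restricted
                else np.ones((1, len(config.planted_associations)), dtype=bool))
    for pattern in patterns:
        rows = np.nonzero((active == pattern).all(axis=1))[0]
        if len(rows) == 0:
            continue
        lam = {k: (v if on else 1.0)
               for (k, v), on in zip(lambdas.items(), pattern)}
        # drug marginal under the active multipliers
        q_drug = p_drug_raw.copy()
        for (d, e), lv in lam.items():
            q_drug[drug_names.index(d)] *= 1 + (lv - 1) * p_event[e]
        q_drug /= q_drug.sum()
        di = rng.choice(len(drug_names), size=len(rows), p=q_drug)
        drug[rows] = np.asarray(drug_names, dtype=object)[di]
        # conditional event draw per drug
        planted_drugs = {d for (d, _e) in lam}
        for k, dname in enumerate(drug_names):
            sel = rows[di == k]
            if len(sel) == 0:
                continue
            q_ev = p_event_raw.copy()
            if dname in planted_drugs:
                for (d, e), lv in lam.items():
                    if d == dname:
                        q_ev[event_codes.index(e)] *= lv
                q_ev /= q_ev.sum()
            event[sel] = _sample_categorical(rng, event_codes, q_ev, len(sel))

    # extra suspect drugs (polytherapy) and a non-suspect concomitant
    extra = np.full(n, "", dtype=object)
    poly = rng.random(n) < config.polytherapy_rate
    if poly.any():
        cand = _sample_categorical(rng, drug_names, p_drug_raw, int(poly.sum()))
        same = cand == drug[poly]
        cand[same] = ""   # drop collisions with the primary suspect
        extra[poly] = cand
    concom = np.full(n, "", dtype=object)
    cmask = rng.random(n) < config.concomitant_rate
    if cmask.any():
        cc = _sample_categorical(rng, drug_names, p_drug_raw, int(cmask.sum()))
        cc[cc == drug[cmask]] = ""
        concom[cmask] = cc

    # dechallenge / rechallenge conditional on planted-cell membership
    planted_cells = set(lambdas)
    member = np.fromiter(((d, e) in planted_cells for d, e in zip(drug, event)),
                         dtype=bool, count=n)
    dr_model = config.dechal_rechal_model
    codes = ["Y", "N", "U", "D", "missing"]

    def draw_dr(mask_planted):
        out = np.empty(n, dtype=object)
        for key, mask in [("planted", mask_planted), ("background", ~mask_planted)]:
            m = int(mask.sum())
            if m == 0:
                continue
            probs = [dr_model[key].get(c, 0.0) for c in codes]
            out[mask] = _sample_categorical(rng, codes, probs, m)
        return np.where(out == "missing", "", out)

    dechal = draw_dr(member)
    rechal = draw_dr(member)

    # dates: receipt date uniform over the configured quarter span;
    # event precedes receipt by a reporting lag; therapy start precedes
    # the event by the drug's time-to-onset
    span_start, _ = _quarter_bounds(config.quarters[0])
    _, span_end = _quarter_bounds(config.quarters[-1])
    span_days = (span_end - span_start).days + 1
    fda_date = span_start + pd.to_timedelta(
        rng.integers(0, span_days, n), unit="D")
    lag = rng.integers(0, 366, n)
    event_date = fda_date - pd.to_timedelta(lag, unit="D")
    tto = _sample_tto(rng, config.tto_model, drug)
    start_date = event_date - pd.to_timedelta(tto, unit="D")

    event_dt = _mask_dates(rng, pd.Series(event_date), config.date_completeness)
    start_dt = _mask_dates(rng, pd.Series(start_date), config.date_completeness)

    dup = rng.random(n) < config.duplicate_rate
    dup_shift = rng.integers(1, 91, n)
    deleted = rng.random(n) < config.deletion_rate

    caseid = np.array([f"{10000001 + i}" for i in range(n)], dtype=object)
    df = pd.DataFrame({
        "caseid": caseid,
        "sex": sex,
        "age": ages,
        "occp_cod": occ,
        "serious": serious,
        "drug": drug,
        "extra_drug": extra,
        "concom_drug": concom,
        "event_code": event,
        "event_name": [event_names[e] for e in event],
        "tto_days": tto,
        "fda_date": fda_date,
        "event_dt": event_dt,
        "start_dt": start_dt,
        "dechal": dechal,
        "rechal": rechal,
        "duplicated": dup,
        "dup_shift": dup_shift,
        "deleted": deleted,
        "planted_cell": member,
    })
    df.attrs["lambdas"] = {f"{d}|{e}": lam for (d, e), lam in lambdas.items()}
    return df


def _build_manifest(config: SyntheticConfig, df: pd.DataFrame,
                    n_versions: int,
                    lambdas: dict | None = None) -> TruthManifest:
    surviving = df.loc[~df["deleted"], "caseid"].tolist()
    alive = df[~df["deleted"]]
    male = alive[alive["sex"] == "M"]
    # counting units: unique (case, suspect drug); the generator never
    # repeats a drug within a case, so rows are already units
    units = pd.concat([
        male[["caseid", "drug", "event_code"]],
        male.loc[male["extra_drug"] != "",
                 ["caseid", "extra_drug", "event_code"]].rename(
                     columns={"extra_drug": "drug"}),
    ], ignore_index=True)
    target = set(config.target_pt_codes)
    units["event"] = units["event_code"].isin(target)
    tab = units.groupby("drug")["event"].agg(["sum", "count"])
    if lambdas is None:
        lambdas = df.attrs.get("lambdas", {})
    planted = []
    for p in config.planted_associations:
        planted.append({
            "drug": p.drug, "pt_code": p.pt_code, "target_rrr": p.rrr,
            "raw_multiplier": lambdas.get(f"{p.drug}|{p.pt_code}"),
            "occupation": p.occupation, "serious": p.serious,
        })
    return TruthManifest(
        seed=config.seed,
        n_cases=config.n_cases,
        planted=planted,
        surviving_caseids=surviving,
        n_versions_emitted=n_versions,
        unit_tabulation={d: [int(r["sum"]), int(r["count"])]
                         for d, r in tab.iterrows()},
        n_units_total=int(len(units)),
        n_event_units_total=int(units["event"].sum()),
    )


# ---------------------------------------------------------------------------
# FAERS-dialect writer
# ---------------------------------------------------------------------------

def generate_faers_package(config: SyntheticConfig,
                           outdir: str | Path) -> TruthManifest:
    """Write quarterly DEMO/DRUG/REAC/THER/OUTC tables, deletion lists
    and a ``manifest.json`` under ``outdir``; returns the manifest.

    Duplicated cases appear as two versions with the same CASEID,
    distinct PRIMARYIDs, non-decreasing FDA_DT, and a perturbed age (the
    only non-key field touched, so deduplication is checkable
    field-by-field).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    df = simulate_cases(config, rng)
    span_start, _ = _quarter_bounds(config.quarters[0])
    _, span_end = _quarter_bounds(config.quarters[-1])

    versions = []
    base = df.assign(version=1, primaryid=df["caseid"] + "1",
                     fda=df["fda_date"], age_v=df["age"])
    versions.append(base)
    dups = df[df["duplicated"]]
    if len(dups):
        fda2 = dups["fda_date"] + pd.to_timedelta(dups["dup_shift"], unit="D")
        fda2 = fda2.clip(upper=span_end)
        v2 = dups.assign(version=2, primaryid=dups["caseid"] + "2",
                         fda=fda2, age_v=dups["age"] + 1.0)
        versions.append(v2)
    vv = pd.concat(versions, ignore_index=True)
    vv["fda_dt"] = vv["fda"].dt.strftime("%Y%m%d")
    vv["quarter"] = quarter_of(vv["fda"])
    vv["age_str"] = vv["age_v"].map(
        lambda a: "" if pd.isna(a) else str(int(a)))
    vv = vv.sort_values(["caseid", "version"], kind="mergesort")

    outc_codes = _sample_categorical(
        rng, ["HO", "OT", "DS", "LT", "DE"], [0.4, 0.3, 0.15, 0.1, 0.05],
        len(vv))
    vv["outc_cod"] = outc_codes

    for q, g in vv.groupby("quarter", sort=True):
        demo = pd.DataFrame({
            "primaryid": g["primaryid"], "caseid": g["caseid"],
            "fda_dt": g["fda_dt"], "event_dt": g["event_dt"],
            "age": g["age_str"], "age_cod": np.where(g["age_str"] == "", "", "YR"),
            "sex": g["sex"], "occp_cod": g["occp_cod"]})
        faers_io.write_table(
            outdir / faers_io.table_filename("DEMO", q), "DEMO", demo)

        drug_rows = [pd.DataFrame({
            "primaryid": g["primaryid"], "caseid": g["caseid"],
            "drug_seq": "1", "role_cod": "PS", "drugname": g["drug"],
            "dechal": g["dechal"], "rechal": g["rechal"]})]
        ge = g[g["extra_drug"] != ""]
        if len(ge):
            drug_rows.append(pd.DataFrame({
                "primaryid": ge["primaryid"], "caseid": ge["caseid"],
                "drug_seq": "2", "role_cod": "PS", "drugname": ge["extra_drug"],
                "dechal": "", "rechal": ""}))
        gc = g[g["concom_drug"] != ""]
        if len(gc):
            drug_rows.append(pd.DataFrame({
                "primaryid": gc["primaryid"], "caseid": gc["caseid"],
                "drug_seq": "3", "role_cod": "C", "drugname": gc["concom_drug"],
                "dechal": "", "rechal": ""}))
        drug = pd.concat(drug_rows, ignore_index=True).sort_values(
            ["primaryid", "drug_seq"], kind="mergesort")
        faers_io.write_table(
            outdir / faers_io.table_filename("DRUG", q), "DRUG", drug)

        reac = pd.DataFrame({
            "primaryid": g["primaryid"], "caseid": g["caseid"],
            "pt": g["event_name"]})
        faers_io.write_table(
            outdir / faers_io.table_filename("REAC", q), "REAC", reac)

        ther = pd.DataFrame({
            "primaryid": g["primaryid"], "caseid": g["caseid"],
            "dsg_drug_seq": "1", "start_dt": g["start_dt"]})
        faers_io.write_table(
            outdir / faers_io.table_filename("THER", q), "THER", ther)

        gs = g[g["serious"]]
        outc = pd.DataFrame({
            "primaryid": gs["primaryid"], "caseid": gs["caseid"],
            "outc_cod": gs["outc_cod"]})
        faers_io.write_table(
            outdir / faers_io.table_filename("OUTC", q), "OUTC", outc)

        del_ids = vv[(vv["quarter"] == q) & vv["deleted"] & (vv["version"] == 1)]
        faers_io.write_deletion_list(
            outdir / faers_io.deletion_filename(q),
            sorted(del_ids["caseid"].unique()))

    manifest = _build_manifest(config, df, n_versions=len(vv))
    manifest.save(outdir / "manifest.json")
    logger.info("wrote synthetic FAERS package: %d cases, %d versions, "
                "%d quarters -> %s", len(df), len(vv),
                vv["quarter"].nunique(), outdir)
    return manifest


# ---------------------------------------------------------------------------
# EV-style consolidated listing
# ---------------------------------------------------------------------------

_AGE_GROUP_BOUNDS = [(0, 18, "<18"), (18, 45, "18-44"), (45, 65, "45-64"),
                     (65, math.inf, ">=65")]


def _age_group(age: float) -> str:
    if pd.isna(age):
        return "Not Specified"
    for lo, hi, label in _AGE_GROUP_BOUNDS:
        if lo <= age < hi:
            return label
    return "Not Specified"


def generate_ev_listing(config: SyntheticConfig,
                        path: str | Path | None = None,
                        ) -> tuple[pd.DataFrame, TruthManifest]:
    """One consolidated row per master case (no duplicate versions and
    no deletion lists — consolidation is assumed already done, as in the
    source system)."""
    rng = np.random.default_rng(config.seed)
    df = simulate_cases(config, rng)
    lambdas = dict(df.attrs.get("lambdas", {}))
    df = df.assign(deleted=False, duplicated=False)
    df.attrs["lambdas"] = lambdas

    qual = np.select(
        [np.isin(df["occp_cod"], ["MD", "PH", "OT", "HP"]),
         np.isin(df["occp_cod"], ["CN", "LW"])],
        ["Healthcare Professional", "Non Healthcare Professional"],
        default="")
    suspected = np.where(df["extra_drug"] != "",
                         df["drug"] + ";" + df["extra_drug"], df["drug"])
    region = np.where(rng.random(len(df)) < 0.55, "EEA", "Non-EEA")
    listing = pd.DataFrame({
        "case_id": "EV-" + df["caseid"],
        "qualification": qual,
        "sex": np.where(df["sex"] == "M", "Male", "Female"),
        "age_group": df["age"].map(_age_group),
        "suspected_drugs": suspected,
        "reaction_pts": df["event_code"],
        "serious": np.where(df["serious"], "Y", "N"),
        "region": region,
        "receive_year": df["fda_date"].dt.year.astype(int),
    })
    manifest = _build_manifest(config, df, n_versions=len(df))
    manifest.surviving_caseids = listing["case_id"].tolist()
    if path is not None:
        listing.to_csv(path, index=False, lineterminator="\n")
        logger.info("wrote synthetic EV listing: %d master cases -> %s",
                    len(listing), path)
    return listing, manifest
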