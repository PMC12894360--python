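"""Shared fixtures: small hand-built report fixtures and the
session-scoped Monte-Carlo runs reused by calibration tests."""

from __future__ import annotations

import math

import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.synth import PlantedSignal, SyntheticConfig

PLANTED_DRUG = "FINASTERIDE"
PLANTED_PT = "10003883"
PLANTED_RRR = 20.0
N_SEEDS = 20
RECOVERY_N_CASES = 50_000
NULL_N_CASES = 20_000


@pytest.fixture(scope="session")
def terms():
    return pv.load_default_terms()


def _screen_listing(cfg: SyntheticConfig) -> pd.DataFrame:
    listing, _ = pv.generate_ev_listing(cfg)
    units = pv.screening_units(pv.from_ev(listing))
    return pv.screen(units)


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty independent databases with one planted RRR=20 signal:
    the screening table of each."""
    runs = []
    for seed in range(N_SEEDS):
        cfg = SyntheticConfig(
            seed=seed, n_cases=RECOVERY_N_CASES,
            planted_associations=[
                PlantedSignal(PLANTED_DRUG, PLANTED_PT, PLANTED_RRR)])
        runs.append(_screen_listing(cfg))
    return runs


@pytest.fixture(scope="session")
def null_runs():
    """Twenty planted-null databases at the default vocabulary size."""
    runs = []
    for seed in range(N_SEEDS):
        cfg = SyntheticConfig(seed=seed, n_cases=NULL_N_CASES)
        runs.append(_screen_listing(cfg))
    return runs


def ebgm_interval(row) -> tuple[float, float]:
    """Symmetric log-normal 95% interval implied by (EBGM, EBGM05)."""
    s = math.log(row["ebgm"] / row["ebgm05"]) / 1.96
    return (row["ebgm"] * math.exp(-1.96 * s),
            row["ebgm"] * math.exp(1.96 * s))


# ---------------------------------------------------------------------------
# a tiny hand-built CaseData fixture
# ---------------------------------------------------------------------------

@pytest.fixture()
def five_case_data() -> pv.CaseData:
    """Five cases exercising the selection rules: male/female, PS vs
    concomitant roles, matched and unmatched PTs, multi-drug and
    multi-PT cases."""
    cases = pd.DataFrame({
        "caseid": ["c1", "c2", "c3", "c4", "c5"],
        "source": "FAERS",
        "sex": ["male", "female", "male", "male", "male"],
        "age_years": [35.0, 35.0, 50.0, None, 28.0],
        "age_group": ["18-44", "18-44", "45-64", "Not specified", "18-44"],
        "reporter": ["consumer", "consumer", "healthcare_professional",
                     "unspecified", "consumer"],
        "serious": [True, False, False, True, False],
        "event_date": ["20230513", "20230601", "202306", "20230710", ""],
        "year": [2023] * 5,
    })
    drugs = pd.DataFrame({
        "caseid": ["c1", "c2", "c3", "c3", "c4", "c5", "c5"],
        "drug": ["FINASTERIDE", "FINASTERIDE", "TESTOSTERONE", "DUTASTERIDE",
                 "IBUPROFEN", "VINBLASTINE", "IBUPROFEN"],
        "role": ["PS", "PS", "PS", "PS", "C", "PS", "C"],
        "dechal": ["Y", "Y", "U", "", "", "N", ""],
        "rechal": ["Y", "", "", "", "", "", ""],
        "start_full": pd.array([20230101, 20230101, None, None, None,
                                20230301, None], dtype="Float64"),
        "has_start": [True, True, False, False, False, True, False],
    })
    reactions = pd.DataFrame({
        "caseid": ["c1", "c2", "c3", "c4", "c5", "c5"],
        "pt_code": ["10003883", "10003883", "", "10021929", "", ""],
        "pt_name": ["", "", "  oligospermia ", "", "Azoospermia",
                    "Infertility male"],
    })
    return pv.CaseData(cases, drugs, reactions, source="FAERS")
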