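"""Unit and property tests for the disproportionality statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.dispro import (ContingencyTable, DegenerateTableError,
                             DisproportionalityResult, SignalCriterion)

Z = 1.959963984540054


# ---------------------------------------------------------------------------
# independent arithmetic reference (kept deliberately naive)
# ---------------------------------------------------------------------------

def reference_stats(a, b, c, d, yates=True):
    n = a + b + c + d
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = (a * d) / (b * c)
    prr = (a / (a + b)) / (c / (c + d))
    s_prr = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    exp = [(a + b) * (a + c) / n, (a + b) * (b + d) / n,
           (c + d) * (a + c) / n, (c + d) * (b + d) / n]
    obs = [a, b, c, d]
    if yates:
        # correction magnitude never exceeds the deviation itself
        chi2 = sum((max(abs(o - e) - 0.5, 0.0)) ** 2 / e
                   for o, e in zip(obs, exp))
    else:
        chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    rrr = a * n / ((a + b) * (a + c))
    return {
        "ror": ror, "ror_low": ror * math.exp(-Z * s),
        "ror_high": ror * math.exp(Z * s),
        "prr": prr, "prr_low": prr * math.exp(-Z * s_prr),
        "prr_high": prr * math.exp(Z * s_prr),
        "chi2": chi2, "ebgm": rrr, "ebgm05": rrr * math.exp(-Z * s),
        "ic": math.log2(rrr), "ic025": math.log2(rrr) - Z * s / math.log(2),
    }


def test_worked_example_frozen_values():
    """Values computed with the standalone arithmetic reference before
    the implementation was written."""
    r = pv.compute_stats(ContingencyTable(10, 90, 100, 9800), "X",
                         chi2_correction=False)
    assert r.ror == pytest.approx(10.889, abs=5e-4)
    assert r.ror_low == pytest.approx(5.503, abs=5e-4)
    assert r.ror_high == pytest.approx(21.544, abs=2e-3)
    assert r.prr == pytest.approx(9.900, abs=5e-4)
    assert r.chi2 == pytest.approx(73.55, abs=0.01)
    assert r.ebgm == pytest.approx(9.0909, abs=5e-5)
    assert r.ic == pytest.approx(3.1844, abs=5e-5)
    assert r.ebgm05 == pytest.approx(4.595, abs=5e-4)
    r_yates = pv.compute_stats(ContingencyTable(10, 90, 100, 9800), "X",
                               chi2_correction=True)
    assert r_yates.chi2 == pytest.approx(65.51, abs=0.01)


def test_no_association_identity():
    r = pv.compute_stats(ContingencyTable(25, 25, 25, 25), "X")
    assert r.ror == r.prr == r.ebgm == 1.0
    assert r.ic == 0.0
    assert r.chi2 == 0.0


@pytest.mark.parametrize("yates", [True, False])
def test_oracle_equivalence_random_tables(yates):
    """Every statistic matches the direct-arithmetic reference to 1e-10
    relative on 1,000 random tables."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        a, b, c, d = rng.integers(1, 500, size=4)
        got = pv.compute_stats(ContingencyTable(int(a), int(b), int(c), int(d)),
                               chi2_correction=yates)
        want = reference_stats(int(a), int(b), int(c), int(d), yates=yates)
        for key, expected in want.items():
            assert getattr(got, key) == pytest.approx(expected, rel=1e-10), key


@given(st.integers(1, 200), st.integers(1, 500), st.integers(1, 500),
       st.integers(1, 5000))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_interval_and_identity_invariants(a, b, c, d):
    r = pv.compute_stats(ContingencyTable(a, b, c, d))
    assert r.ror_low <= r.ror <= r.ror_high
    assert r.prr_low <= r.prr <= r.prr_high
    assert r.ebgm05 <= r.ebgm
    assert r.ic == pytest.approx(math.log2(r.ebgm))
    # EBGM05/EBGM mirrors ror_low/ROR (shared log-SE)
    assert r.ebgm05 / r.ebgm == pytest.approx(r.ror_low / r.ror, rel=1e-9)


@given(st.integers(2, 50), st.integers(1, 300), st.integers(1, 300),
       st.integers(1, 3000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_monotonicity_in_a(a, b, c, d):
    lo = pv.compute_stats(ContingencyTable(a - 1, b, c, d))
    hi = pv.compute_stats(ContingencyTable(a, b, c, d))
    # ROR and PRR are strictly increasing in a unconditionally
    assert hi.ror > lo.ror
    assert hi.prr > lo.prr
    # the unshrunk EBGM (= relative reporting ratio) is strictly
    # increasing only while the background dominates the drug's own
    # margin (as a grows without bound RRR falls back towards 1), so
    # the property is asserted in that screening regime
    if c >= a * a and b >= a:
        assert hi.ebgm > lo.ebgm
        assert hi.ic > lo.ic


@given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 200),
       st.integers(1, 200))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_drug_swap_symmetry(a, b, c, d):
    r1 = pv.compute_stats(ContingencyTable(a, b, c, d))
    r2 = pv.compute_stats(ContingencyTable(c, d, a, b))
    assert r2.ror == pytest.approx(1.0 / r1.ror, rel=1e-12)


def test_zero_cell_handling():
    with pytest.raises(DegenerateTableError):
        pv.compute_stats(ContingencyTable(5, 0, 3, 100),
                         zero_cell_correction=False)
    r = pv.compute_stats(ContingencyTable(5, 0, 3, 100))
    assert np.isfinite(r.ror) and np.isfinite(r.ror_high)
    # zero marginal: statistics undefined
    r2 = pv.compute_stats(ContingencyTable(0, 0, 3, 100))
    assert math.isnan(r2.ror) and math.isnan(r2.ebgm)


def test_ic025_variants_ordering():
    t = ContingencyTable(20, 200, 100, 10000)
    base = pv.compute_stats(t, ic025_method="normal")
    bate = pv.compute_stats(t, ic025_method="bate")
    mc = pv.compute_stats(t, ic025_method="mc",
                          rng=np.random.default_rng(0))
    for r in (base, bate, mc):
        assert r.ic025 < r.ic
    assert bate.ic025 == pytest.approx(base.ic025, abs=0.6)
    assert mc.ic025 == pytest.approx(base.ic025, abs=0.6)


# ---------------------------------------------------------------------------
# criterion
# ---------------------------------------------------------------------------

def _result(**kw):
    base = dict(drug="X", a=10, ror=5, ror_low=2, ror_high=10, prr=5,
                prr_low=2, prr_high=10, chi2=50, ic=2, ic025=1, ebgm=5,
                ebgm05=3)
    base.update(kw)
    return DisproportionalityResult(**base)


def test_criterion_conjunction_and_boundaries():
    pos, breakdown = pv.evaluate_signal(_result())
    assert pos and all(breakdown.values())
    # fewer than 3 reports never positive, however extreme the rest
    pos, breakdown = pv.evaluate_signal(
        _result(a=2, ror=1000, ror_low=500, prr=1000, chi2=1e5, ic025=10,
                ebgm05=100))
    assert not pos and not breakdown["min_reports"]
    # strict inequalities at the IC025 and EBGM05 boundaries
    assert not pv.evaluate_signal(_result(ic025=0.0))[0]
    assert not pv.evaluate_signal(_result(ebgm05=2.0))[0]
    # PRR and chi2 thresholds are >=
    assert pv.evaluate_signal(_result(prr=2.0, chi2=4.0))[0]


def test_published_screening_row_is_positive():
    """A row with the strength reported for bleomycin (n=14,
    ror_low=33.82, PRR=56.93, chi2=764.44, IC025=2.84, EBGM05=33.39)
    satisfies every condition."""
    r = _result(a=14, ror=57.29, ror_low=33.82, ror_high=97.06, prr=56.93,
                chi2=764.44, ic=5.82, ic025=2.84, ebgm=56.57, ebgm05=33.39)
    pos, breakdown = pv.evaluate_signal(r)
    assert pos and all(breakdown.values())


def test_criterion_thresholds_configurable():
    crit = SignalCriterion(min_a=1, ebgm05_gt=0.5)
    assert pv.evaluate_signal(_result(a=1, ebgm05=1.0), crit)[0]


# ---------------------------------------------------------------------------
# table construction & screening
# ---------------------------------------------------------------------------

def _units(rows):
    return pd.DataFrame(rows, columns=["drug", "event"])


def test_build_contingency_small_stratum():
    units = _units([("D1", True), ("D1", False), ("D2", True), ("D2", False)])
    t = pv.build_contingency(units, "D1")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    with pytest.raises(DegenerateTableError):
        pv.build_contingency(units, "D3")


def test_build_contingency_conservation():
    units = _units([("D1", True), ("D1", False), ("D2", True), ("D2", False),
                    ("D3", False)])
    full = pv.build_contingency(units, "D1")
    smaller = pv.build_contingency(units.iloc[:-1], "D1")
    assert (full.a, full.b, full.c) == (smaller.a, smaller.b, smaller.c)
    assert full.d == smaller.d + 1


def test_screen_ranking_and_tie_break():
    rng = np.random.default_rng(3)
    drugs = rng.choice(["AAA", "BBB", "CCC"], 300).tolist() + ["ZZZ"] * 10
    events = rng.random(310) < 0.2
    units = pd.DataFrame({"drug": drugs, "event": events})
    out = pv.screen(units)
    assert list(out["ror"]) == sorted(out["ror"], reverse=True)
    # stable deterministic output
    out2 = pv.screen(units.sample(frac=1.0, random_state=1))
    pd.testing.assert_frame_equal(out, out2)


def test_screen_single_drug_stratum_degenerate():
    units = _units([("ONLY", True), ("ONLY", False), ("ONLY", False)])
    out = pv.screen(units)
    assert len(out) == 1
    assert not out["positive"].any()


def test_screen_empty():
    out = pv.screen(pd.DataFrame(columns=["drug", "event"]))
    assert out.empty


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def test_reconstruct_table_round_trip():
    t = ContingencyTable(37, 1500, 4200, 250000)
    r = pv.compute_stats(t)
    t2 = pv.reconstruct_table(37, r.ror, r.ror_low, r.prr)
    assert (t2.a, t2.b, t2.c, t2.d) == (t.a, t.b, t.c, t.d)
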