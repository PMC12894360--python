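"""Case definition, name standardization and cohort description."""

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.cohort import AGE_UNIT_YEARS, _age_group, _age_to_years


def test_default_terms_content(terms):
    assert len(terms.entries) == 13
    assert ("10003883", "Azoospermia") in terms.entries
    assert ("10021929", "Infertility male") in terms.entries


@pytest.mark.parametrize("reactions,expected", [
    ([("10003883", "")], {"10003883"}),                     # code match
    ([("", "Azoospermia")], {"10003883"}),                  # name match
    ([("", "  oligospermia ")], {"10030300"}),              # trim + case
    ([("", "Erectile dysfunction")], set()),                # not listed
    ([("99999999", "Azoospermia")], set()),                 # code present, wrong
    ([("", "Azoosperm")], set()),                           # no substring match
    ([("10003883", ""), ("", "Infertility male")],
     {"10003883", "10021929"}),
])
def test_match_event_terms(terms, reactions, expected):
    assert pv.match_event_terms(reactions, terms) == expected


def test_select_cases_five_case_fixture(five_case_data, terms):
    """Hand-enumerated: c1 male+PS+matched -> in; c2 female -> out;
    c3 two PS drugs, one matched PT -> 2 records, 1 case; c4 only
    concomitant role -> out; c5 PS drug, two matched PTs -> 2 records."""
    cases, records = pv.select_cases(five_case_data, terms)
    assert set(cases["caseid"]) == {"c1", "c3", "c5"}
    per_case = records.groupby("caseid").size()
    assert per_case["c1"] == 1
    assert per_case["c3"] == 2          # two suspect drugs, one PT
    assert per_case["c5"] == 2          # one drug, two matched PTs
    assert set(records.columns) == {"caseid", "drug", "pt_code", "role",
                                    "dechal", "rechal"}
    # no orphans: every record's case is in the case table
    assert set(records["caseid"]) <= set(cases["caseid"])
    assert len(cases) <= len(records)


def test_selection_fixed_point(five_case_data, terms):
    cases, records = pv.select_cases(five_case_data, terms)
    keep = set(cases["caseid"])
    sub = pv.CaseData(
        five_case_data.cases[five_case_data.cases.caseid.isin(keep)],
        five_case_data.drugs[five_case_data.drugs.caseid.isin(keep)],
        five_case_data.reactions[five_case_data.reactions.caseid.isin(keep)])
    cases2, records2 = pv.select_cases(sub, terms)
    assert set(cases2["caseid"]) == keep
    assert len(records2) == len(records)


def test_screening_units_counting_modes(five_case_data, terms):
    units = pv.screening_units(five_case_data, terms)
    # male cases only; unique (case, drug); c4's concomitant drug excluded
    assert set(zip(units["caseid"], units["drug"])) == {
        ("c1", "FINASTERIDE"), ("c3", "TESTOSTERONE"), ("c3", "DUTASTERIDE"),
        ("c5", "VINBLASTINE")}
    assert units["event"].all()
    rec = pv.screening_units(five_case_data, terms, events_as_records=True)
    # c5 expands to its two matched PTs
    assert len(rec[rec["caseid"] == "c5"]) == 2
    assert len(rec) == 5


def test_standardize_drug_names_lookup_and_passthrough(caplog):
    df = pd.DataFrame({"drug": ["PROPECIA", "propecia ", "DRUGX 10MG",
                                "PROSCAR"]})
    syn = pd.DataFrame({"verbatim": ["PROPECIA", "PROSCAR"],
                        "preferred": ["FINASTERIDE", "FINASTERIDE"]})
    out = pv.standardize_drug_names(df, syn)
    assert list(out["drug"]) == ["FINASTERIDE", "FINASTERIDE", "DRUGX 10MG",
                                 "FINASTERIDE"]


def test_standardize_chain_and_cycle():
    out = pv.standardize_drug_names(
        pd.DataFrame({"drug": ["A"]}), {"A": "B", "B": "C"})
    assert list(out["drug"]) == ["C"]
    with pytest.raises(ValueError, match="cyclic"):
        pv.standardize_drug_names(pd.DataFrame({"drug": ["A"]}),
                                  {"A": "B", "B": "A"})


def test_age_conversion_units_and_groups():
    age = pd.Series(["4", "35", "300", "104.36", "7305", "17532", "nope"])
    cod = pd.Series(["DEC", "YR", "MON", "WK", "DY", "HR", "YR"])
    years = _age_to_years(age, cod)
    assert years[0] == pytest.approx(40)
    assert years[1] == pytest.approx(35)
    assert years[2] == pytest.approx(25)
    assert years[3] == pytest.approx(2.0, abs=0.01)
    assert years[4] == pytest.approx(20.0, abs=0.01)
    assert years[5] == pytest.approx(2.0, abs=0.01)
    assert np.isnan(years[6])
    groups = _age_group(pd.Series([17.9, 18.0, 44.9, 45.0, 64.9, 65.0,
                                   np.nan]))
    assert list(groups) == ["<18", "18-44", "18-44", "45-64", "45-64",
                            ">=65", "Not specified"]
    assert set(AGE_UNIT_YEARS) == {"DEC", "YR", "MON", "WK", "DY", "HR"}


def test_faers_reporter_and_serious_mapping(tmp_path):
    cfg = pv.SyntheticConfig(seed=13, n_cases=600)
    pv.generate_faers_package(cfg, tmp_path / "pkg")
    pkg = pv.apply_deletion_lists(
        pv.deduplicate(pv.read_faers_package(tmp_path / "pkg")),
        pv.read_faers_package(tmp_path / "pkg").deleted_ids)
    cd = pv.from_faers(pkg)
    demo = pkg.demo.set_index("caseid")
    merged = cd.cases.set_index("caseid").join(demo["occp_cod"])
    assert (merged.loc[merged["occp_cod"].isin(["CN", "LW"]),
                       "reporter"] == "consumer").all()
    assert (merged.loc[merged["occp_cod"].isin(["MD", "PH", "OT"]),
                       "reporter"] == "healthcare_professional").all()
    assert (merged.loc[merged["occp_cod"] == "", "reporter"]
            == "unspecified").all()
    # serious flag mirrors presence of an outcome row
    assert set(cd.cases.loc[cd.cases["serious"], "caseid"]) == \
        set(pkg.outc["caseid"])


def test_ev_round_trip_consistency():
    cfg = pv.SyntheticConfig(seed=17, n_cases=400)
    listing, _ = pv.generate_ev_listing(cfg)
    cd = pv.from_ev(listing)
    assert len(cd.cases) == 400
    assert cd.cases["sex"].isin(["male", "female"]).all()
    assert (cd.drugs["role"] == "SUSPECT").all()
    dup = listing.copy()
    dup.loc[1, "case_id"] = dup.loc[0, "case_id"]
    with pytest.raises(ValueError, match="duplicate"):
        pv.from_ev(dup)


def _cohort_like_published_counts() -> pd.DataFrame:
    """A case table reproducing the published FAERS cohort margins:
    1,955 male cases; ages 52/722/209/118/854; occupations 833 consumer,
    35 lawyer, 575 physician, 142 pharmacist, 253 other
    health-professional, 117 not specified."""
    ages = (["<18"] * 52 + ["18-44"] * 722 + ["45-64"] * 209 +
            [">=65"] * 118 + ["Not specified"] * 854)
    occupations = (["Consumer"] * 833 + ["Lawyer"] * 35 +
                   ["Physician"] * 575 + ["Pharmacist"] * 142 +
                   ["Other health-professional"] * 253 +
                   ["Not specified"] * 117)
    reporters = (["consumer"] * (833 + 35) +
                 ["healthcare_professional"] * (575 + 142 + 253) +
                 ["unspecified"] * 117)
    return pd.DataFrame({"caseid": [str(i) for i in range(1955)],
                         "sex": "male", "age_group": ages,
                         "occupation": occupations, "reporter": reporters})


def test_describe_cohort_percentages():
    summary = pv.describe_cohort(_cohort_like_published_counts())
    s = summary.set_index(["characteristic", "level"])
    assert s.loc[("sex", "male"), "count"] == 1955
    assert s.loc[("sex", "male"), "pct"] == 100.0
    assert s.loc[("age_group", "18-44"), "pct"] == 36.93
    assert s.loc[("occupation", "Consumer"), "pct"] == 42.61
    assert s.loc[("occupation", "Lawyer"), "pct"] == 1.79
    assert s.loc[("reporter", "unspecified"), "pct"] == 5.98


def test_describe_cohort_empty():
    out = pv.describe_cohort(pd.DataFrame(
        columns=["caseid", "sex", "age_group", "reporter"]))
    assert out.empty
    assert out.attrs["total"] == 0
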