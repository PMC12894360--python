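"""Dialect round-trip, deduplication and deletion-list tests."""

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal import faers_io
from pvsignal.synth import SyntheticConfig


def _write_fixture_package(tmp_path):
    """Three hand-built cases in one quarter, one drug name containing
    the field delimiter."""
    q = "2023Q1"
    demo = pd.DataFrame({
        "primaryid": ["1011", "1021", "1031"],
        "caseid": ["101", "102", "103"],
        "fda_dt": ["20230110", "20230215", "20230320"],
        "event_dt": ["20221201", "202211", "2022"],
        "age": ["35", "", "61"],
        "age_cod": ["YR", "", "YR"],
        "sex": ["M", "F", "M"],
        "occp_cod": ["MD", "CN", ""],
    })
    drug = pd.DataFrame({
        "primaryid": ["1011", "1021", "1031"],
        "caseid": ["101", "102", "103"],
        "drug_seq": ["1", "1", "1"],
        "role_cod": ["PS", "PS", "C"],
        "drugname": ["FINASTERIDE", "VITAMIN C $ ZINC", "IBUPROFEN"],
        "dechal": ["Y", "", "U"],
        "rechal": ["N", "", ""],
    })
    reac = pd.DataFrame({
        "primaryid": ["1011", "1021", "1031"],
        "caseid": ["101", "102", "103"],
        "pt": ["Azoospermia", "10030300", "Headache"],
    })
    ther = pd.DataFrame({
        "primaryid": ["1011"], "caseid": ["101"],
        "dsg_drug_seq": ["1"], "start_dt": ["20220901"],
    })
    outc = pd.DataFrame({
        "primaryid": ["1011"], "caseid": ["101"], "outc_cod": ["HO"],
    })
    for name, df in [("DEMO", demo), ("DRUG", drug), ("REAC", reac),
                     ("THER", ther), ("OUTC", outc)]:
        faers_io.write_table(tmp_path / faers_io.table_filename(name, q),
                             name, df)
    return demo, drug


def test_round_trip_preserves_fields(tmp_path):
    demo, drug = _write_fixture_package(tmp_path)
    pkg = pv.read_faers_package(tmp_path)
    assert len(pkg.demo) == 3
    pd.testing.assert_frame_equal(pkg.demo, demo)
    # embedded delimiter quoted and recovered intact
    assert "VITAMIN C $ ZINC" in set(pkg.drug["drugname"])
    versions = pkg.versions()
    assert len(versions) == 3
    v101 = next(v for v in versions if v.key.caseid == "101")
    assert v101.key.fda_dt == 20230110
    assert v101.drugs[0]["dechal"] == "Y"
    assert v101.outcomes == ["HO"]


def test_missing_table_raises(tmp_path):
    _write_fixture_package(tmp_path)
    (tmp_path / "REAC23Q1.txt").unlink()
    with pytest.raises(FileNotFoundError):
        pv.read_faers_package(tmp_path)


def test_malformed_lines_counted_and_tolerance(tmp_path):
    _write_fixture_package(tmp_path)
    with open(tmp_path / "REAC23Q1.txt", "a") as fh:
        fh.write("9991$999\n")  # one field short
    pkg = pv.read_faers_package(tmp_path, malformed_tolerance=0.5)
    assert pkg.report.n_malformed["REAC23Q1.txt"] == 1
    assert len(pkg.reac) == 3
    with pytest.raises(ValueError, match="tolerance"):
        pv.read_faers_package(tmp_path, malformed_tolerance=0.0)


def test_demo_rows_without_key_are_quarantined(tmp_path):
    _write_fixture_package(tmp_path)
    with open(tmp_path / "DEMO23Q1.txt", "a") as fh:
        fh.write("1041$104$$$30$YR$M$MD\n")   # missing fda_dt
    pkg = pv.read_faers_package(tmp_path)
    assert len(pkg.demo) == 3
    assert len(pkg.rejects) == 1
    assert pkg.rejects.iloc[0]["caseid"] == "104"


def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])


def test_dedup_keeps_latest_fda_dt():
    demo = _demo([("1111", "111", "20240101"), ("1112", "111", "20240301")])
    out = pv.deduplicate(demo)
    assert list(out["primaryid"]) == ["1112"]


def test_dedup_tie_broken_by_max_primaryid():
    demo = _demo([("1112", "111", "20240301"), ("1113", "111", "20240301")])
    out = pv.deduplicate(demo)
    assert list(out["primaryid"]) == ["1113"]
    # numeric, not lexicographic, comparison when both ids parse
    demo = _demo([("999", "111", "20240301"), ("1000", "111", "20240301")])
    assert list(pv.deduplicate(demo)["primaryid"]) == ["1000"]


def test_dedup_single_version_and_empty():
    demo = _demo([("1111", "111", "20240101")])
    assert list(pv.deduplicate(demo)["primaryid"]) == ["1111"]
    assert pv.deduplicate(_demo([])).empty


def test_dedup_idempotent_and_order_invariant():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(200):
        case = f"c{rng.integers(0, 60)}"
        rows.append((str(rng.integers(1, 10**6)), case,
                     f"2023{rng.integers(1, 13):02d}{rng.integers(1, 29):02d}"))
    demo = _demo(rows)
    once = pv.deduplicate(demo)
    twice = pv.deduplicate(once)
    pd.testing.assert_frame_equal(once, twice)
    for seed in range(3):
        shuffled = demo.sample(frac=1.0, random_state=seed)
        pd.testing.assert_frame_equal(pv.deduplicate(shuffled), once)


def test_conservation_accounting():
    demo = _demo([("1", "a", "20230101"), ("2", "a", "20230102"),
                  ("3", "b", "20230101"), ("4", "c", "20230101"),
                  ("5", "c", "20230301")])
    out = pv.deduplicate(demo)
    assert len(demo) == len(out) + (len(demo) - len(out))
    assert len(out) == demo["caseid"].nunique()


def test_apply_deletion_lists():
    demo = _demo([(str(i), f"c{i}", "20230101") for i in range(10)])
    out = pv.apply_deletion_lists(demo, {"c3", "c7"})
    assert len(out) == 8
    assert not set(out["caseid"]) & {"c3", "c7"}
    # absent id: no-op
    out2 = pv.apply_deletion_lists(demo, {"zzz"})
    assert len(out2) == 10


def test_synthetic_package_matches_manifest(tmp_path):
    """Version counts, dedup survivors and deletion exclusions all
    reconcile with the generator's truth manifest."""
    cfg = SyntheticConfig(seed=7, n_cases=2000, duplicate_rate=0.2,
                          deletion_rate=0.1)
    manifest = pv.generate_faers_package(cfg, tmp_path / "pkg")
    pkg = pv.read_faers_package(tmp_path / "pkg")
    assert len(pkg.demo) == manifest.n_versions_emitted
    deduped = pv.deduplicate(pkg)
    assert len(deduped.demo) == cfg.n_cases
    survivors = pv.apply_deletion_lists(deduped, deduped.deleted_ids)
    assert set(survivors.demo["caseid"]) == set(manifest.surviving_caseids)
    # duplicate versions differ only in the perturbed non-key field
    dup_case = pkg.demo[pkg.demo.duplicated("caseid", keep=False)].iloc[0]
    pair = pkg.demo[pkg.demo["caseid"] == dup_case["caseid"]]
    assert pair["sex"].nunique() == 1 and pair["occp_cod"].nunique() == 1


def test_versions_list_dedup_dispatch(tmp_path):
    _write_fixture_package(tmp_path)
    pkg = pv.read_faers_package(tmp_path)
    versions = pkg.versions()
    out = pv.deduplicate(versions)
    assert [v.key.caseid for v in out] == ["101", "102", "103"]
    kept = pv.apply_deletion_lists(out, {"102"})
    assert [v.key.caseid for v in kept] == ["101", "103"]
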