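"""Ingest and cohort-selection rules: PT gathering, the four retention rules,
and the summary table's partition/rounding contracts."""

import csv

import pandas as pd
import pytest

from aefi_signal.records import AgeGroup, VaccineClass, AGE_MIN_YEARS
from aefi_signal.synth import (
    HEXA_VAX_NAME,
    PENTA_VAX_NAME,
    SimConfig,
    generate_reports,
    write_vaers_dialect,
)
from aefi_signal.vaers_io import (
    CohortConfig,
    read_vaers_dir,
    read_vaers_extract,
    round_pct,
    select_cohort,
    summarize_cohort,
)
from tests.conftest import make_report


def _write_raw(tmp_path, data_rows, vax_rows, sym_rows):
    data_cols = [
        "VAERS_ID",
        "RECVDATE",
        "STATE",
        "AGE_YRS",
        "SEX",
        "DIED",
        "L_THREAT",
        "HOSPITAL",
        "X_STAY",
        "DISABLE",
        "RECOVD",
        "NUMDAYS",
    ]
    with open(tmp_path / "VAERSDATA.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(data_cols)
        w.writerows(data_rows)
    with open(tmp_path / "VAERSVAX.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "VAX_TYPE", "VAX_NAME"])
        w.writerows(vax_rows)
    with open(tmp_path / "VAERSSYMPTOMS.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "SYMPTOM1", "SYMPTOM2", "SYMPTOM3", "SYMPTOM4", "SYMPTOM5"])
        w.writerows(sym_rows)
    return (
        tmp_path / "VAERSDATA.csv",
        tmp_path / "VAERSVAX.csv",
        tmp_path / "VAERSSYMPTOMS.csv",
    )


def _data_row(vid, age="0.25", sex="M", died="", recvdate="07/01/2020"):
    return [vid, recvdate, "TX", age, sex, died, "", "", "", "", "U", "1"]


def test_symptom_columns_gather_into_pt_set(tmp_path):
    pts7 = ["Pyrexia", "Seizure", "Apnoea", "Vomiting", "Rash", "Crying", "Lethargy"]
    triple = _write_raw(
        tmp_path,
        [_data_row("1")],
        [["1", "DTAPIPVHIB", PENTA_VAX_NAME]],
        [["1"] + pts7[:5], ["1"] + pts7[5:] + ["", "", "Pyrexia"]],  # repeated PT string
    )
    raw = read_vaers_extract(triple)
    assert raw.loc[0, "PTS"] == frozenset(pts7)


def test_blank_age_retained_then_filtered(tmp_path):
    triple = _write_raw(
        tmp_path,
        [_data_row("1", age=""), _data_row("2")],
        [["1", "", PENTA_VAX_NAME], ["2", "", PENTA_VAX_NAME]],
        [["1", "Pyrexia", "", "", "", ""], ["2", "Pyrexia", "", "", "", ""]],
    )
    raw = read_vaers_extract(triple)
    assert len(raw) == 2  # missingness is not a read error
    cohort = select_cohort(raw)
    assert [r.report_id for r in cohort] == ["2"]


def test_missing_mandatory_column_is_hard_error(tmp_path):
    triple = _write_raw(tmp_path, [_data_row("1")], [["1", "", PENTA_VAX_NAME]], [])
    df = pd.read_csv(triple[0])
    df.drop(columns=["DIED"]).to_csv(triple[0], index=False)
    with pytest.raises(ValueError, match="DIED"):
        read_vaers_extract(triple)


def test_selection_rules_on_toy_raw(tmp_path):
    """Six reports: one duplicate id, one error-only PT set, one over-age —
    three survive."""
    rows = [
        _data_row("1"),
        _data_row("1"),  # duplicate id
        _data_row("2"),
        _data_row("3", age="3.0"),  # outside age window
        _data_row("4"),  # error-only PTs
        _data_row("5"),
    ]
    vax = [[vid, "", PENTA_VAX_NAME] for vid in "112345"]
    sym = [
        ["1", "Pyrexia", "", "", "", ""],
        ["2", "Seizure", "", "", "", ""],
        ["3", "Pyrexia", "", "", "", ""],
        ["4", "Incorrect dose administered", "", "", "", ""],
        ["5", "Rash", "Incorrect dose administered", "", "", ""],
    ]
    cohort = select_cohort(read_vaers_extract(_write_raw(tmp_path, rows, vax, sym)))
    assert sorted(r.report_id for r in cohort) == ["1", "2", "5"]
    # error PTs are kept on retained reports, they just cannot be the only PT
    assert {"Rash", "Incorrect dose administered"} == set(
        next(r for r in cohort if r.report_id == "5").pts
    )


def test_coadministration_and_both_pattern_resolution(tmp_path):
    rows = [_data_row("1"), _data_row("2")]
    vax = [
        ["1", "", HEXA_VAX_NAME],
        ["1", "FLU4", "INFLUENZA (SEASONAL) (FLUZONE)"],
        ["2", "", PENTA_VAX_NAME],
        ["2", "", HEXA_VAX_NAME],
    ]
    sym = [["1", "Pyrexia", "", "", "", ""], ["2", "Pyrexia", "", "", "", ""]]
    cohort = select_cohort(read_vaers_extract(_write_raw(tmp_path, rows, vax, sym)))
    r1 = next(r for r in cohort if r.report_id == "1")
    assert r1.vaccine_class is VaccineClass.HEXA and not r1.vaccine_alone
    r2 = next(r for r in cohort if r.report_id == "2")
    assert r2.vaccine_class is VaccineClass.HEXA and r2.vaccine_alone


def test_age_boundary_42_days_in_group_g1(tmp_path):
    age = f"{AGE_MIN_YEARS:.6f}"
    triple = _write_raw(
        tmp_path,
        [_data_row("1", age=age)],
        [["1", "", PENTA_VAX_NAME]],
        [["1", "Pyrexia", "", "", "", ""]],
    )
    cohort = select_cohort(read_vaers_extract(triple))
    assert cohort[0].age_group is AgeGroup.G1


def test_selection_is_idempotent_and_deduplicated(tmp_path):
    records, _ = generate_reports(SimConfig(n_penta=150, n_hexa=150, seed=21))
    write_vaers_dialect(records, tmp_path)
    once = select_cohort(read_vaers_dir(tmp_path))
    ids = [r.report_id for r in once]
    assert len(ids) == len(set(ids))
    # re-serialize the selected cohort and select again: nothing changes
    twice_dir = tmp_path / "again"
    write_vaers_dialect(once, twice_dir)
    twice = select_cohort(read_vaers_dir(twice_dir))
    assert sorted(r.report_id for r in twice) == sorted(ids)


def test_round_pct_half_up():
    assert round_pct(1, 16) == 6.3  # 6.25 rounds half-up
    assert round_pct(0, 0) == 0.0


def test_summary_blocks_partition_class_n(small_cohort):
    records, _ = small_cohort
    summary = summarize_cohort(records)
    for cls in ("penta", "hexa"):
        block = summary[cls]
        n = block["n"]
        for key in ("sex", "serious", "vaccine_alone", "recovered"):
            assert sum(cell["n"] for cell in block[key].values()) == n
        assert sum(block["onset"].values()) == n
        assert sum(block["by_year"].values()) == n
        assert sum(block["by_region"].values()) == n


def test_single_report_summary_degenerates():
    summary = summarize_cohort([make_report("1")])
    block = summary["penta"]
    for cell in block["sex"].values():
        assert cell["pct"] in (0.0, 100.0)
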