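"""Generator contracts: determinism, planted effects, dialect round trip,
and the deterministic published-table fixture."""

import csv

import numpy as np
import pytest

from aefi_signal.records import VaccineClass
from aefi_signal.synth import (
    SimConfig,
    generate_reports,
    table1_fixture,
    write_vaers_dialect,
)
from aefi_signal.vaers_io import read_vaers_dir, select_cohort
from tests.conftest import make_report


def _record_key(r):
    return (
        r.report_id,
        r.vaccine_class,
        round(r.age_years, 2),
        r.sex,
        r.died,
        r.life_threatening,
        r.hospitalized,
        r.prolonged_hosp,
        r.disabled,
        r.recovered,
        r.vaccine_alone,
        r.onset_days,
        r.report_year,
        r.region,
        r.pts,
    )


def test_seeded_determinism():
    cfg = SimConfig(n_penta=200, n_hexa=150, seed=42)
    r1, t1 = generate_reports(cfg)
    r2, t2 = generate_reports(cfg)
    assert [_record_key(r) for r in r1] == [_record_key(r) for r in r2]
    assert t1.expected_pt_counts == t2.expected_pt_counts
    r3, _ = generate_reports(SimConfig(n_penta=200, n_hexa=150, seed=43))
    assert [_record_key(r) for r in r1] != [_record_key(r) for r in r3]


def test_zero_class_count_degenerates():
    records, _ = generate_reports(SimConfig(n_penta=0, n_hexa=50, seed=1))
    assert len(records) == 50
    assert all(r.vaccine_class is VaccineClass.HEXA for r in records)


def test_invalid_config_names_field():
    cfg = SimConfig(p_female=1.5)
    with pytest.raises(ValueError, match="p_female"):
        cfg.validate()
    cfg = SimConfig(age_dist={"penta": (0.5, 0.5, 0.5), "hexa": (0.6, 0.25, 0.15)})
    with pytest.raises(ValueError, match="age_dist"):
        cfg.validate()


def test_null_cohort_matches_baselines():
    """With all planted rates at 1, empirical per-PT proportions sit within
    3 binomial standard errors of their baselines for ≥95% of PTs."""
    cfg = SimConfig(n_penta=10_000, n_hexa=10_000, seed=5)
    records, _ = generate_reports(cfg)
    for cls in VaccineClass:
        sub = [r for r in records if r.vaccine_class is cls]
        n = len(sub)
        ok = 0
        checked = 0
        for pt, _, p in cfg.pt_vocab:
            if pt == "Pyrexia":
                continue  # fallback PT absorbs otherwise-empty reports
            checked += 1
            obs = sum(pt in r.pts for r in sub) / n
            se = np.sqrt(p * (1 - p) / n)
            if abs(obs - p) <= 3 * se:
                ok += 1
        assert ok / checked >= 0.95


def test_planted_effect_monotonicity():
    base = SimConfig(seed=1, planted_rr={("Apnoea", "hexa"): 2.0})
    doubled = SimConfig(seed=1, planted_rr={("Apnoea", "hexa"): 4.0})
    _, t1 = generate_reports(SimConfig(n_penta=0, n_hexa=100, seed=1, planted_rr=base.planted_rr))
    _, t2 = generate_reports(SimConfig(n_penta=0, n_hexa=100, seed=1, planted_rr=doubled.planted_rr))
    assert t2.expected_pt_counts["hexa"]["Apnoea"] > t1.expected_pt_counts["hexa"]["Apnoea"]


def test_rate_above_one_clamps_with_warning(caplog):
    cfg = SimConfig(n_penta=0, n_hexa=100, seed=2, planted_rr={("Pyrexia", "hexa"): 100.0})
    with caplog.at_level("WARNING"):
        records, truth = generate_reports(cfg)
    assert "clamped" in caplog.text
    assert truth.expected_pt_counts["hexa"]["Pyrexia"] == 100.0
    assert all("Pyrexia" in r.pts for r in records)


def test_symptom_overflow_rows(tmp_path):
    pts = {
        "Pyrexia",
        "Seizure",
        "Apnoea",
        "Vomiting",
        "Rash",
        "Crying",
        "Lethargy",
    }
    rec = make_report("X1", pts=pts)
    _, _, sym_path = write_vaers_dialect([rec], tmp_path)
    with open(sym_path, newline="") as fh:
        rows = [row for row in csv.reader(fh)][1:]
    assert len(rows) == 2
    gathered = {v for row in rows for v in row[1:] if v}
    assert gathered == pts


def test_coadmin_writes_extra_vax_row(tmp_path):
    rec = make_report("X2", vaccine_alone=False)
    _, vax_path, _ = write_vaers_dialect([rec], tmp_path)
    with open(vax_path, newline="") as fh:
        rows = [row for row in csv.reader(fh)][1:]
    assert len(rows) == 2
    assert all(row[0] == "X2" for row in rows)


def test_dialect_round_trip_is_identity(tmp_path):
    cfg = SimConfig(n_penta=250, n_hexa=250, seed=9)
    records, _ = generate_reports(cfg)
    write_vaers_dialect(records, tmp_path)
    back = select_cohort(read_vaers_dir(tmp_path))
    assert sorted(map(_record_key, back)) == sorted(map(_record_key, records))


def test_fixture_margins_match_published_table():
    records = table1_fixture()
    penta = [r for r in records if r.vaccine_class is VaccineClass.PENTA]
    hexa = [r for r in records if r.vaccine_class is VaccineClass.HEXA]
    assert (len(penta), len(hexa)) == (3259, 1720)
    assert sum(r.died for r in penta) == 70
    assert sum(r.died for r in hexa) == 39
    assert sum(r.hospitalized for r in hexa) == 585
    assert sum(r.serious for r in penta) == 440
    assert sum(r.serious for r in hexa) == 658
    assert sum(r.vaccine_alone for r in penta) == 1044
    assert sum(r.vaccine_alone for r in hexa) == 206
    # fixture is deterministic
    again = table1_fixture()
    assert [_record_key(r) for r in again] == [_record_key(r) for r in records]
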