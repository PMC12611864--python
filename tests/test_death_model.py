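"""Death-classification logistic model: coding, identities, recovery."""

import numpy as np
import pandas as pd
import pytest

from aefi_signal.death_model import DesignSpec, build_design, fit_logistic
from aefi_signal.records import Sex, VaccineClass
from aefi_signal.synth import SimConfig, generate_reports
from tests.conftest import make_report


def _cohort_2x2(n11, n10, n01, n00):
    """Binary coadmin covariate with given (died, coadmin) cell counts."""
    recs = []
    i = 0
    for coad, dead, n in [(True, True, n11), (True, False, n10), (False, True, n01), (False, False, n00)]:
        for _ in range(n):
            i += 1
            recs.append(
                make_report(str(i), died=dead, vaccine_alone=not coad, sex=Sex.MALE, age_years=0.2)
            )
    return recs


def test_design_codes_observed_levels_only():
    recs = [make_report("1", age_years=0.2), make_report("2", age_years=0.5, died=True)]
    design = build_design(recs, VaccineClass.PENTA)
    assert "age_G2" in design.X.columns and "age_G3" not in design.X.columns


def test_unknown_sex_excluded_and_counted():
    recs = [
        make_report("1", sex=Sex.UNKNOWN),
        make_report("2", sex=Sex.MALE, died=True),
        make_report("3", sex=Sex.FEMALE),
    ]
    with pytest.warns(UserWarning):
        design = build_design(recs, VaccineClass.PENTA)
    assert design.n_excluded_unknown_sex == 1
    assert len(design.y) == 2


def test_constant_term_dropped_with_warning():
    recs = [make_report(str(i), sex=Sex.MALE, died=(i == 0)) for i in range(10)]
    with pytest.warns(UserWarning, match="sex_female"):
        design = build_design(recs, VaccineClass.PENTA)
    assert "sex_female" not in design.X.columns
    assert "sex_female" in design.dropped_terms


def test_zero_deaths_is_hard_error():
    recs = [make_report(str(i)) for i in range(5)]
    with pytest.raises(ValueError, match="zero deaths"):
        build_design(recs, VaccineClass.PENTA)


def test_separation_warning_names_level():
    recs = [make_report(str(i), died=False, vaccine_alone=True) for i in range(20)]
    recs += [make_report(str(100 + i), died=True, vaccine_alone=False) for i in range(5)]
    recs += [make_report("200", died=False, vaccine_alone=False)]
    with pytest.warns(UserWarning, match="coadmin"):
        build_design(recs, VaccineClass.PENTA)


def test_saturated_fit_equals_crude_odds_ratio():
    recs = _cohort_2x2(10, 90, 5, 95)
    fit = fit_logistic(build_design(recs, VaccineClass.PENTA))
    crude = (10 * 95) / (90 * 5)
    assert fit.term("coadmin").odds_ratio == pytest.approx(crude, rel=1e-10)
    assert fit.n_used == 200 and fit.converged


def test_reference_relabel_inverts_odds_ratio():
    recs = _cohort_2x2(10, 90, 5, 95)
    fit = fit_logistic(build_design(recs, VaccineClass.PENTA))
    flipped = [
        make_report(r.report_id, died=r.died, vaccine_alone=not r.vaccine_alone, sex=Sex.MALE, age_years=0.2)
        for r in recs
    ]
    fit2 = fit_logistic(build_design(flipped, VaccineClass.PENTA))
    assert fit2.term("coadmin").odds_ratio == pytest.approx(
        1.0 / fit.term("coadmin").odds_ratio, rel=1e-8
    )


def test_generator_covariates_match_design_sums(small_cohort):
    records, truth = small_cohort
    for cls in VaccineClass:
        design = build_design(records, cls)
        cc = truth.covariate_counts[cls.value]
        assert design.n_excluded_unknown_sex == cc["unknown_sex"]
        assert design.X["sex_female"].sum() == cc["female"]
        assert design.y.sum() == sum(
            r.died and r.sex is not Sex.UNKNOWN
            for r in records
            if r.vaccine_class is cls
        )


def test_planted_coefficients_recovered_at_large_n():
    """One large synthetic cohort: estimated ORs near the planted ones."""
    cfg = SimConfig(n_penta=60_000, n_hexa=0, seed=31)
    records, truth = generate_reports(cfg)
    fit = fit_logistic(build_design(records, VaccineClass.PENTA))
    planted_female_or = float(np.exp(truth.death_coefs.female))
    est = fit.term("sex_female").odds_ratio
    assert est == pytest.approx(planted_female_or, rel=0.35)
    assert fit.term("sex_female").ci_low < fit.term("sex_female").ci_high
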