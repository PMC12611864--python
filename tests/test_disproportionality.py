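"""Statistic formulations, zero-cell handling, MGPS posterior identities,
flags and the consensus rule."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import digamma
from scipy.stats import gamma as gamma_dist

from aefi_signal.contingency import ContingencyTable
from aefi_signal.disproportionality import (
    DEFAULT_PRIOR,
    MgpsPrior,
    SignalResult,
    bcpnn_ic,
    fit_mgps_prior,
    fit_prior_from_counts,
    flag_signals,
    mgps_scores,
    prr,
    ror,
    score_tables,
)
from aefi_signal.records import VaccineClass


def table(a, b, c, d, label="x"):
    return ContingencyTable(a, b, c, d, label, "PT", VaccineClass.HEXA)


@pytest.mark.parametrize(
    "cells,expected_ror,expected_flag",
    [
        ((10, 10, 10, 10), 1.0, False),
        ((20, 80, 10, 90), 2.25, False),
        ((3, 0, 1, 10), 49.0, None),  # +0.5 on all cells: (3.5*10.5)/(0.5*1.5)
    ],
)
def test_ror_values(cells, expected_ror, expected_flag):
    est, (lo, hi), flag = ror(table(*cells))
    assert est == pytest.approx(expected_ror, rel=1e-12)
    assert lo <= est <= hi
    if expected_flag is not None:
        assert flag is expected_flag


def test_prr_values_and_count_gate():
    est, chi2, flag = prr(table(20, 80, 10, 90))
    assert est == pytest.approx(2.0, rel=1e-12)
    assert flag  # PRR >= 2 and a >= 3
    est, _, flag = prr(table(2, 8, 1, 9))
    assert not flag  # a = 2 < 3 regardless of PRR
    est, _, flag = prr(table(10, 10, 10, 10))
    assert est == 1.0 and not flag


def test_ic_point_estimate():
    # a == E gives IC = 0 exactly: a=4, b=4, c=4, d=4 -> E = 4
    t = table(4, 4, 4, 4)
    ic, ic025, flag = bcpnn_ic(t)
    assert t.expected == 4.0
    assert ic == 0.0
    assert ic025 < 0 and not flag
    # a=8, E=2: (8+12)(8+2)/100 = 2
    t = table(8, 12, 2, 78)
    ic, _, _ = bcpnn_ic(t)
    assert ic == pytest.approx(math.log2(8.5 / 2.5), rel=1e-12)


def test_ic025_matches_monte_carlo_posterior():
    t = table(8, 12, 2, 78)  # shape 8.5, rate 2.5
    _, ic025, _ = bcpnn_ic(t)
    rng = np.random.default_rng(2024)
    draws = rng.gamma(8.5, 1 / 2.5, size=200_000)
    mc = np.log2(np.quantile(draws, 0.025))
    assert abs(ic025 - mc) < 0.02


def test_mgps_degenerate_prior_closed_form():
    """Symmetric prior == single Gamma(1,1) component: posterior Gamma(4,2)
    for a=3, E=1."""
    prior = MgpsPrior(1.0, 1.0, 1.0, 1.0, 0.5)
    t = table(3, 1, 0, 8)  # E = (3+1)(3+0)/12 = 1
    assert t.expected == pytest.approx(1.0)
    ebgm, eb05, flag = mgps_scores(t, prior)
    assert ebgm == pytest.approx(math.exp(digamma(4) - math.log(2)), rel=1e-12)
    assert eb05 == pytest.approx(gamma_dist.ppf(0.05, 4, scale=0.5), abs=1e-6)


def test_mgps_zero_count_shrinks_below_one():
    prior = MgpsPrior(1.0, 2.0, 2.0, 4.0, 0.5)  # prior mean 0.5 <= 1
    ebgm, eb05, flag = mgps_scores(table(0, 10, 5, 5), prior)
    assert ebgm < 1.0 and eb05 < ebgm and not flag


def test_prior_fit_guard_and_collapse():
    with pytest.raises(ValueError, match="20"):
        fit_prior_from_counts(np.arange(5), np.ones(5))
    # single-component truth: fitted mixture collapses or components merge
    rng = np.random.default_rng(7)
    e = rng.uniform(1, 30, 3000)
    lam = rng.gamma(2.0, 1 / 2.0, 3000)
    a = rng.poisson(lam * e)
    prior = fit_prior_from_counts(a, e)
    m1, m2 = prior.alpha1 / prior.beta1, prior.alpha2 / prior.beta2
    collapsed = prior.w >= 0.95 or prior.w <= 0.05
    merged = (
        abs(prior.alpha1 - prior.alpha2) / prior.alpha2 < 0.05
        and abs(prior.beta1 - prior.beta2) / prior.beta2 < 0.05
    )
    # either the weight collapses, the shapes merge, or both component means
    # agree with the single-component truth
    means_agree = abs(m1 - 1.0) < 0.1 and abs(m2 - 1.0) < 0.1
    assert collapsed or merged or means_agree


def _result(flags):
    return SignalResult(
        event_label="x",
        level="PT",
        a=1,
        expected=1.0,
        ror=1.0,
        ror_ci=(1.0, 1.0),
        ror_flag=flags[0],
        prr=1.0,
        chi2=0.0,
        prr_flag=flags[1],
        ic=0.0,
        ic025=0.0,
        ic_flag=flags[2],
        ebgm=1.0,
        eb05=1.0,
        mgps_flag=flags[3],
    )


def test_consensus_equals_popcount_over_all_16_flag_sets():
    for flags in product([False, True], repeat=4):
        [res] = flag_signals([_result(flags)])
        assert res.consensus == (sum(flags) >= 2)


def test_score_tables_orders_consensus_first(small_cohort):
    records, _ = small_cohort
    from aefi_signal.contingency import build_all_tables

    tables = build_all_tables(records, "PT", VaccineClass.HEXA)
    results = score_tables(tables)
    assert len(results) == len(tables)
    keys = [(-int(r.consensus), -r.a, r.event_label) for r in results]
    assert keys == sorted(keys)
    for r in results:
        assert r.ror_ci[0] <= r.ror <= r.ror_ci[1]
        assert r.ic025 <= r.ic
        assert r.eb05 <= r.ebgm
        assert np.isfinite([r.ror, r.prr, r.ic, r.ic025, r.ebgm, r.eb05]).all()


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    a=st.integers(1, 40),
    b=st.integers(1, 200),
    c=st.integers(1, 50),
    d=st.integers(1, 200),
)
def test_monotonicity_in_target_count(a, b, c, d):
    """Moving one target report into the event cell (margins fixed) never
    decreases any of the four statistics."""
    t1, t2 = table(a, b + 1, c, d), table(a + 1, b, c, d)
    assert ror(t2)[0] >= ror(t1)[0]
    assert prr(t2)[0] >= prr(t1)[0]
    assert bcpnn_ic(t2)[0] >= bcpnn_ic(t1)[0]
    e1, _, _ = mgps_scores(t1, DEFAULT_PRIOR)
    e2, _, _ = mgps_scores(t2, DEFAULT_PRIOR)
    assert e2 >= e1 - 1e-12


def test_ebgm_bounded_by_posterior_component_ratios():
    """EBGM is a posterior-weighted geometric mean, so it must lie between
    the component-wise bounds ln((α+a)/(β+E)) − 1/(α+a) < E[ln λ] <
    ln((α+a)/(β+E)) implied by the digamma inequalities."""
    prior = DEFAULT_PRIOR
    for a, b, c, d in [(5, 95, 1, 99), (1, 9, 5, 85), (30, 70, 10, 90), (0, 10, 3, 7)]:
        t = table(a, b, c, d)
        e = t.expected
        ebgm, _, _ = mgps_scores(t, prior)
        ratios_hi = [
            (prior.alpha1 + a) / (prior.beta1 + e),
            (prior.alpha2 + a) / (prior.beta2 + e),
        ]
        ratios_lo = [
            r * math.exp(-1.0 / (alpha + a))
            for r, alpha in zip(ratios_hi, (prior.alpha1, prior.alpha2))
        ]
        assert min(ratios_lo) - 1e-9 <= ebgm <= max(ratios_hi) + 1e-9
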