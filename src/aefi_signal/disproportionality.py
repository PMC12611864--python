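"""The four disproportionality statistics and the consensus signal rule.

Formulations (stated here because they are what this package computes):

* **ROR** — reporting odds ratio ``(a·d)/(b·c)`` with a log-normal Wald 95% CI
  ``exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))``; the Haldane–Anscombe +0.5
  correction is applied to all four cells iff any cell is zero.
  Signal: ROR ≥ 3 and CI lower bound > 1.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` under the
  same zero-cell rule, with the Yates-corrected Pearson chi-square reported
  for reference.  Signal: PRR ≥ 2 and a ≥ 3 (the EMA reading of "N ≥ 3" as
  the target event count).
* **BCPNN IC** — information component in the shrinkage form
  ``IC = log2((a+0.5)/(E+0.5))`` with ``E = (a+b)(a+c)/N``; the posterior for
  the Poisson mean is Gamma(a+0.5, E+0.5), and IC025 is the base-2 log of its
  2.5% quantile.  Signal: IC025 > 0.
* **MGPS** — DuMouchel's two-component gamma-Poisson shrinker: counts are
  Poisson(λE) with λ drawn from a mixture of two gamma densities; the prior is
  fit by maximizing the marginal negative-binomial likelihood, and the
  posterior is again a two-component gamma mixture.  EBGM is the geometric
  mean ``2^{E[log2 λ]}`` and EB05 the posterior 5th percentile.
  Signal: EB05 > 2.

An event is a **consensus signal** when at least two of the four per-method
flags are true.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import digamma, expit, gammaln, logit, logsumexp
from scipy.stats import gamma as gamma_dist

from .contingency import ContingencyTable

log = logging.getLogger(__name__)

__all__ = [
    "MgpsPrior",
    "DEFAULT_PRIOR",
    "SignalResult",
    "ror",
    "prr",
    "bcpnn_ic",
    "fit_mgps_prior",
    "fit_prior_from_counts",
    "mgps_scores",
    "flag_signals",
    "score_tables",
    "signals_to_frame",
    "PriorFitError",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _cells(table: ContingencyTable) -> tuple[float, float, float, float]:
    """Cell counts with the Haldane–Anscombe +0.5 applied iff any cell is 0."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def ror(table: ContingencyTable) -> tuple[float, tuple[float, float], bool]:
    """Reporting odds ratio, its Wald 95% CI, and the signal flag."""
    a, b, c, d = _cells(table)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(est) - Z95 * se), math.exp(math.log(est) + Z95 * se)
    return est, (lo, hi), (est >= 3.0 and lo > 1.0)


def _yates_chi2(table: ContingencyTable) -> float:
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2 / denom


def prr(table: ContingencyTable) -> tuple[float, float, bool]:
    """Proportional reporting ratio, Yates chi-square, and the signal flag."""
    a, b, c, d = _cells(table)
    est = (a / (a + b)) / (c / (c + d))
    return est, _yates_chi2(table), (est >= 2.0 and table.a >= 3)


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float, bool]:
    """Information component (bits), its lower 2.5% credible bound, and flag."""
    e = table.expected
    shape, rate = table.a + 0.5, e + 0.5
    ic = math.log2(shape / rate)
    ic025 = math.log2(gamma_dist.ppf(0.025, shape, scale=1.0 / rate))
    return ic, ic025, (ic025 > 0.0)


# ---------------------------------------------------------------------------
# MGPS


@dataclass(frozen=True)
class FitDiagnostics:
    nll: float
    n_starts: int
    n_converged: int
    iterations: int


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate λ.

    Component j has shape ``alpha_j`` and rate ``beta_j``; ``w`` is the weight
    of the first component.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    diagnostics: Optional[FitDiagnostics] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("MgpsPrior: gamma parameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("MgpsPrior: mixture weight must lie in (0, 1)")

    @property
    def mean(self) -> float:
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2


#: DuMouchel's canonical starting prior, also the fallback for tiny table sets.
DEFAULT_PRIOR = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _log_nb(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Marginal negative-binomial log pmf of a count with expectation baseline e."""
    return (
        gammaln(alpha + a)
        - gammaln(alpha)
        - gammaln(a + 1)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def _mixture_nll(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = expit(theta[4])
    lp = np.stack(
        [np.log(w) + _log_nb(a, e, a1, b1), np.log1p(-w) + _log_nb(a, e, a2, b2)]
    )
    return -float(logsumexp(lp, axis=0).sum())


_STARTS: list[tuple[float, float, float, float, float]] = [
    (0.2, 0.1, 2.0, 4.0, 1 / 3),  # canonical
    (1.0, 1.0, 1.0, 1.0, 0.5),  # flat, symmetric
    (0.5, 0.5, 5.0, 10.0, 0.2),  # tight null + diffuse signal component
    (2.0, 4.0, 0.2, 0.1, 2 / 3),  # canonical with labels swapped
    (0.1, 0.05, 1.0, 1.0, 0.5),  # heavy-tailed first component
]


class PriorFitError(RuntimeError):
    """All optimization starts failed; carries the best incumbent prior."""

    def __init__(self, message: str, incumbent: MgpsPrior):
        super().__init__(message)
        self.incumbent = incumbent


def fit_prior_from_counts(a: np.ndarray, e: np.ndarray) -> MgpsPrior:
    """Maximum marginal likelihood fit of the five prior hyperparameters.

    Multi-start L-BFGS-B on (log α1, log β1, log α2, log β2, logit w).
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.size < 20:
        raise ValueError(f"fit_mgps_prior needs at least 20 tables, got {a.size}")
    if np.any(e <= 0):
        raise ValueError("fit_mgps_prior: expected counts must be positive")

    bounds = [(-10.0, 10.0)] * 4 + [(-7.0, 7.0)]
    best = None
    n_conv = 0
    for start in _STARTS:
        theta0 = np.array([*np.log(start[:4]), logit(start[4])])
        res = minimize(
            _mixture_nll,
            theta0,
            args=(a, e),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500},
        )
        if res.success:
            n_conv += 1
        if best is None or res.fun < best.fun:
            best = res
    a1, b1, a2, b2 = np.exp(best.x[:4])
    w = float(np.clip(expit(best.x[4]), 1e-9, 1 - 1e-9))
    diag = FitDiagnostics(
        nll=float(best.fun),
        n_starts=len(_STARTS),
        n_converged=n_conv,
        iterations=int(best.nit),
    )
    prior = MgpsPrior(float(a1), float(b1), float(a2), float(b2), w, diagnostics=diag)
    if n_conv == 0:
        raise PriorFitError(
            f"no optimization start converged (best NLL {best.fun:.4g})", prior
        )
    return prior


def fit_mgps_prior(tables: Sequence[ContingencyTable]) -> MgpsPrior:
    """Fit the gamma-mixture prior to the observed (a, E) pairs of a table set."""
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    return fit_prior_from_counts(a, e)


def _posterior_mixture(
    a: float, e: float, prior: MgpsPrior
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior component weights, shapes, and rates given a count and baseline."""
    av = np.array([a], dtype=float)
    ev = np.array([e], dtype=float)
    lp = np.array(
        [
            math.log(prior.w) + _log_nb(av, ev, prior.alpha1, prior.beta1)[0],
            math.log1p(-prior.w) + _log_nb(av, ev, prior.alpha2, prior.beta2)[0],
        ]
    )
    q = np.exp(lp - logsumexp(lp))
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    return q, shapes, rates


def mgps_scores(
    table: ContingencyTable, prior: MgpsPrior
) -> tuple[float, float, bool]:
    """EBGM, EB05 and the signal flag under a fitted gamma-mixture prior.

    EBGM uses the digamma closed form for ``E[ln λ]`` per posterior component;
    EB05 is found by bracketed root-finding on the posterior mixture CDF to
    absolute tolerance 1e-6.
    """
    q, shapes, rates = _posterior_mixture(table.a, table.expected, prior)
    mean_log = float(np.dot(q, digamma(shapes) - np.log(rates)))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return float(np.dot(q, gamma_dist.cdf(x, shapes, scale=1.0 / rates)))

    lo = float(np.min(gamma_dist.ppf(0.04, shapes, scale=1.0 / rates)))
    hi = float(np.max(gamma_dist.ppf(0.90, shapes, scale=1.0 / rates)))
    try:
        eb05 = brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-9, rtol=8.9e-16)
    except ValueError as exc:
        raise RuntimeError(
            f"EB05 root finding failed for {table.event_label!r}: "
            f"bracket [{lo:.3g}, {hi:.3g}] with CDF [{cdf(lo):.3g}, {cdf(hi):.3g}]"
        ) from exc
    return ebgm, float(eb05), (eb05 > 2.0)


# ---------------------------------------------------------------------------
# Per-event results and consensus


@dataclass
class SignalResult:
    event_label: str
    level: str
    a: int
    expected: float
    ror: float
    ror_ci: tuple[float, float]
    ror_flag: bool
    prr: float
    chi2: float
    prr_flag: bool
    ic: float
    ic025: float
    ic_flag: bool
    ebgm: float
    eb05: float
    mgps_flag: bool
    consensus: bool = False

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.ror_flag, self.prr_flag, self.ic_flag, self.mgps_flag)


def flag_signals(results: Sequence[SignalResult]) -> list[SignalResult]:
    """Set the ≥2-of-4 consensus flag and order deterministically
    (consensus first, then descending a, then label)."""
    for r in results:
        r.consensus = sum(r.flags) >= 2
    return sorted(results, key=lambda r: (-int(r.consensus), -r.a, r.event_label))


def score_tables(
    tables: Sequence[ContingencyTable],
    prior: Optional[MgpsPrior] = None,
) -> list[SignalResult]:
    """Compute all four statistics for every table and apply the consensus rule.

    When no prior is given it is fit to the supplied tables; below the
    20-table identifiability floor the canonical default prior is used
    (with a warning) instead.
    """
    if prior is None:
        if len(tables) >= 20:
            prior = fit_mgps_prior(tables)
        else:
            log.warning(
                "only %d tables: using the canonical default MGPS prior", len(tables)
            )
            prior = DEFAULT_PRIOR
    results = []
    for t in tables:
        ror_est, ror_ci, ror_flag = ror(t)
        prr_est, chi2, prr_flag = prr(t)
        ic, ic025, ic_flag = bcpnn_ic(t)
        ebgm, eb05, mgps_flag = mgps_scores(t, prior)
        results.append(
            SignalResult(
                event_label=t.event_label,
                level=t.level,
                a=t.a,
                expected=t.expected,
                ror=ror_est,
                ror_ci=ror_ci,
                ror_flag=ror_flag,
                prr=prr_est,
                chi2=chi2,
                prr_flag=prr_flag,
                ic=ic,
                ic025=ic025,
                ic_flag=ic_flag,
                ebgm=ebgm,
                eb05=eb05,
                mgps_flag=mgps_flag,
            )
        )
    return flag_signals(results)


def signals_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event": r.event_label,
                "level": r.level,
                "a": r.a,
                "E": r.expected,
                "ror": r.ror,
                "ror_lo": r.ror_ci[0],
                "ror_hi": r.ror_ci[1],
                "ror_flag": r.ror_flag,
                "prr": r.prr,
                "chi2": r.chi2,
                "prr_flag": r.prr_flag,
                "ic": r.ic,
                "ic025": r.ic025,
                "ic_flag": r.ic_flag,
                "ebgm": r.ebgm,
                "eb05": r.eb05,
                "mgps_flag": r.mgps_flag,
                "consensus": r.consensus,
            }
            for r in results
        ]
    )
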