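"""Multivariable logistic model of death classification (per vaccine class).

The outcome is whether a report was *classified* as death — a reporting
outcome, not mortality risk.  Covariates: age group (reference 6 weeks–<4
months), sex (reference male; unknown-sex reports are excluded and counted),
and co-administration (reference vaccine given alone).  Fitting is maximum
likelihood via Newton iterations with Wald intervals ``exp(β ± 1.96·SE)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .disproportionality import Z95
from .records import ReportRecord, Sex, VaccineClass

log = logging.getLogger(__name__)

__all__ = ["DesignSpec", "LogisticFit", "TermEstimate", "build_design", "fit_logistic", "fit_to_frame"]


@dataclass
class DesignSpec:
    """Design matrix plus bookkeeping from covariate coding."""

    X: pd.DataFrame  # includes the constant column
    y: np.ndarray
    reference_levels: dict[str, str]
    n_excluded_unknown_sex: int
    dropped_terms: list[str]
    separation_warnings: list[str]


@dataclass(frozen=True)
class TermEstimate:
    term: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticFit:
    terms: list[TermEstimate]
    reference_levels: dict[str, str]
    n_used: int
    n_excluded_unknown_sex: int
    converged: bool
    iterations: int
    final_gradient_norm: float

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def build_design(
    reports: Sequence[ReportRecord], vaccine_class: VaccineClass
) -> DesignSpec:
    """Dummy-coded design for one vaccine class.

    Only covariate levels actually observed get a dummy; degenerate (constant)
    terms are dropped with a warning, as are unknown-sex reports.  Covariate
    levels with all-death or no-death outcomes are reported as separation
    warnings.
    """
    sub = [r for r in reports if r.vaccine_class is vaccine_class]
    n_unknown = sum(r.sex is Sex.UNKNOWN for r in sub)
    sub = [r for r in sub if r.sex is not Sex.UNKNOWN]
    if not sub:
        raise ValueError(f"no usable {vaccine_class.value} reports")
    y = np.array([1.0 if r.died else 0.0 for r in sub])
    if y.sum() == 0:
        raise ValueError(f"{vaccine_class.value}: zero deaths; model not estimable")
    if y.sum() == len(y):
        raise ValueError(f"{vaccine_class.value}: all reports are deaths; model not estimable")

    cols: dict[str, np.ndarray] = {}
    groups = [r.age_group.value if r.age_group else "missing" for r in sub]
    for level in ("G2", "G3"):
        if level in set(groups):
            cols[f"age_{level}"] = np.array([1.0 if g == level else 0.0 for g in groups])
    cols["sex_female"] = np.array([1.0 if r.sex is Sex.FEMALE else 0.0 for r in sub])
    cols["coadmin"] = np.array([0.0 if r.vaccine_alone else 1.0 for r in sub])

    dropped = [name for name, v in cols.items() if len(np.unique(v)) < 2]
    for name in dropped:
        warnings.warn(f"{vaccine_class.value}: term {name!r} is constant; dropped")
        del cols[name]

    separation = []
    for name, v in cols.items():
        for val in (0.0, 1.0):
            mask = v == val
            if mask.any() and (y[mask].mean() in (0.0, 1.0)):
                msg = f"{vaccine_class.value}: level {name}={int(val)} has outcome separation"
                separation.append(msg)
                warnings.warn(msg)

    X = pd.DataFrame({"const": np.ones(len(sub)), **cols})
    return DesignSpec(
        X=X,
        y=y,
        reference_levels={"age_group": "G1", "sex": "male", "vaccine_alone": "yes"},
        n_excluded_unknown_sex=n_unknown,
        dropped_terms=dropped,
        separation_warnings=separation,
    )


def fit_logistic(design: DesignSpec) -> LogisticFit:
    """Newton maximum-likelihood fit with Wald CIs and two-sided p-values."""
    model = sm.Logit(design.y, design.X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels re-warns on separation
        res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=False)
    grad_norm = float(np.abs(model.score(res.params)).max())
    if not res.mle_retvals.get("converged", False):
        hint = (
            "; perfect separation suspected — a penalized fit would be needed"
            if design.separation_warnings
            else ""
        )
        raise RuntimeError(
            f"logistic fit did not converge in {res.mle_retvals.get('iterations')} "
            f"iterations (max |score| = {grad_norm:.3g}){hint}"
        )
    terms = []
    with np.errstate(over="ignore"):
        for name in design.X.columns:
            beta = float(res.params[name])
            se = float(res.bse[name])
            terms.append(
                TermEstimate(
                    term=name,
                    coef=beta,
                    se=se,
                    odds_ratio=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - Z95 * se)),
                    ci_high=float(np.exp(beta + Z95 * se)),
                    p_value=float(res.pvalues[name]),
                )
            )
    return LogisticFit(
        terms=terms,
        reference_levels=design.reference_levels,
        n_used=len(design.y),
        n_excluded_unknown_sex=design.n_excluded_unknown_sex,
        converged=True,
        iterations=int(res.mle_retvals.get("iterations", -1)),
        final_gradient_norm=grad_norm,
    )


def fit_to_frame(fit: LogisticFit) -> pd.DataFrame:
    """Summary-table layout: term, OR, CI bounds, p-value, significance mark."""
    rows = []
    for t in fit.terms:
        rows.append(
            {
                "term": t.term,
                "coef": t.coef,
                "odds_ratio": t.odds_ratio,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p_value": t.p_value,
                "significant": t.p_value < 0.05,
            }
        )
    return pd.DataFrame(rows)
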