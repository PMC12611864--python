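"""Stratified analyses: age group, sex, and seriousness strata.

Each stratum is analysed with the same contingency + disproportionality
machinery as the full cohort; ``top_k_pts`` produces the ranked
most-frequently-reported PT table with per-PT ROR and 95% CI computed against
the comparator *within the same stratum* (the confounding-control reading of
the stratified design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .contingency import build_table
from .disproportionality import ror
from .records import ReportRecord, VaccineClass

log = logging.getLogger(__name__)

__all__ = ["StratumSpec", "stratify", "top_k_pts", "top_k_to_frame"]

Factor = Literal["age_group", "sex", "serious"]


@dataclass(frozen=True)
class StratumSpec:
    factor: Factor
    level: str


_FACTOR_DOMAIN = {
    "age_group": {"G1", "G2", "G3", "missing"},
    "sex": {"male", "female", "unknown"},
    "serious": {"yes", "no"},
}


def _level_of(report: ReportRecord, factor: Factor) -> str:
    if factor == "age_group":
        g = report.age_group
        return g.value if g is not None else "missing"
    if factor == "sex":
        return report.sex.value
    if factor == "serious":
        return "yes" if report.serious else "no"
    raise ValueError(f"unknown stratification factor {factor!r}")


def stratify(
    reports: Sequence[ReportRecord], factor: Factor
) -> dict[str, list[ReportRecord]]:
    """Partition the cohort by a factor; missing levels form their own stratum."""
    if factor not in _FACTOR_DOMAIN:
        raise ValueError(f"unknown stratification factor {factor!r}")
    out: dict[str, list[ReportRecord]] = {}
    for r in reports:
        out.setdefault(_level_of(r, factor), []).append(r)
    return out


def top_k_pts(
    reports: Sequence[ReportRecord],
    k: int,
    target_class: VaccineClass,
) -> list[tuple[str, int, float, tuple[float, float]]]:
    """Top-k most frequent PTs in the target class within ``reports``.

    Ranked by descending count, ties broken alphabetically; each entry carries
    the PT's ROR and Wald 95% CI against the within-stratum comparator.
    Returns fewer than k entries when fewer distinct PTs exist.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    target = [r for r in reports if r.vaccine_class is target_class]
    if not target:
        log.warning("stratum has no %s reports; empty top-k list", target_class.value)
        return []
    counts: dict[str, int] = {}
    for r in target:
        for pt in r.pts:
            counts[pt] = counts.get(pt, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    out = []
    for pt, count in ranked:
        table = build_table(reports, pt, "PT", target_class)
        est, ci, _ = ror(table)
        out.append((pt, count, est, ci))
    return out


def top_k_to_frame(
    entries: Sequence[tuple[str, int, float, tuple[float, float]]]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pt": pt, "count": n, "ror": est, "ror_lo": ci[0], "ror_hi": ci[1]}
            for pt, n, est, ci in entries
        ]
    )
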