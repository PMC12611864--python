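"""2×2 contingency tables for disproportionality analysis.

For an event (a MedDRA PT, or an SOC aggregated report-level) and a target
vaccine class the table is::

                      event   no event
    target class        a        b
    comparator          c        d

Counting is report-level: a report mentioning an event through any number of
its PTs contributes exactly one to ``a`` (or ``c``).  The comparator defaults
to the other vaccine class's cohort; an external background (c, d) pair can be
supplied instead, as in classical all-other-reports practice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .records import ReportRecord, VaccineClass
from .vocab import soc_of

__all__ = ["ContingencyTable", "map_pt_to_soc", "build_table", "build_all_tables", "tables_to_frame"]

Level = Literal["PT", "SOC"]
ComparatorMode = Literal["other_class", "external_background"]


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    event_label: str
    level: Level
    target_class: VaccineClass

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"{self.event_label}: negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected target-event count under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def swapped(self) -> "ContingencyTable":
        """The same table from the comparator's point of view."""
        other = (
            VaccineClass.HEXA
            if self.target_class is VaccineClass.PENTA
            else VaccineClass.PENTA
        )
        return ContingencyTable(self.c, self.d, self.a, self.b, self.event_label, self.level, other)


def map_pt_to_soc(pt: str, vocab: dict[str, str]) -> str:
    """SOC for a PT under the loaded vocabulary ('Unmapped' fallback)."""
    return soc_of(pt, vocab)


def _event_sets(report: ReportRecord, level: Level, vocab: Optional[dict[str, str]]) -> frozenset[str]:
    if level == "PT":
        return report.pts
    if report.socs:
        return report.socs
    if vocab is None:
        raise ValueError("SOC-level counting needs a vocabulary when records carry no SOCs")
    return frozenset(map_pt_to_soc(pt, vocab) for pt in report.pts)


def _split(
    reports: Iterable[ReportRecord], target_class: VaccineClass
) -> tuple[list[ReportRecord], list[ReportRecord]]:
    target, comparator = [], []
    for r in reports:
        (target if r.vaccine_class is target_class else comparator).append(r)
    return target, comparator


def build_table(
    reports: Sequence[ReportRecord],
    event: str,
    level: Level,
    target_class: VaccineClass,
    comparator_mode: ComparatorMode = "other_class",
    background: Optional[tuple[int, int]] = None,
    vocab: Optional[dict[str, str]] = None,
) -> ContingencyTable:
    """One 2×2 table for ``event`` at ``level`` against the comparator.

    ``background`` supplies (c, d) directly when ``comparator_mode`` is
    ``external_background``.
    """
    target, comparator = _split(reports, target_class)
    a = sum(event in _event_sets(r, level, vocab) for r in target)
    b = len(target) - a
    if comparator_mode == "external_background":
        if background is None:
            raise ValueError("external_background mode requires a (c, d) background pair")
        c, d = background
    else:
        if not comparator:
            raise ValueError(f"comparator cohort is empty for target {target_class.value}")
        c = sum(event in _event_sets(r, level, vocab) for r in comparator)
        d = len(comparator) - c
    return ContingencyTable(a, b, c, d, event, level, target_class)


def build_all_tables(
    reports: Sequence[ReportRecord],
    level: Level,
    target_class: VaccineClass,
    comparator_mode: ComparatorMode = "other_class",
    background_counts: Optional[dict[str, tuple[int, int]]] = None,
    vocab: Optional[dict[str, str]] = None,
) -> list[ContingencyTable]:
    """One table per event observed in the target class (a ≥ 1), ordered by
    descending a then label.  Events absent from the target class cannot
    signal under any of the thresholds and are not scored."""
    target, comparator = _split(reports, target_class)
    target_counts: Counter[str] = Counter()
    for r in target:
        target_counts.update(_event_sets(r, level, vocab))
    comp_counts: Counter[str] = Counter()
    if comparator_mode == "other_class":
        if not comparator:
            raise ValueError(f"comparator cohort is empty for target {target_class.value}")
        for r in comparator:
            comp_counts.update(_event_sets(r, level, vocab))
        n_comp = len(comparator)

    tables = []
    for event, a in target_counts.items():
        if comparator_mode == "external_background":
            if background_counts is None or event not in background_counts:
                raise ValueError(f"no external background counts for event {event!r}")
            c, d = background_counts[event]
        else:
            c = comp_counts.get(event, 0)
            d = n_comp - c
        tables.append(
            ContingencyTable(a, len(target) - a, c, d, event, level, target_class)
        )
    tables.sort(key=lambda t: (-t.a, t.event_label))
    return tables


def tables_to_frame(tables: Sequence[ContingencyTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event": t.event_label,
                "level": t.level,
                "target_class": t.target_class.value,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
            }
            for t in tables
        ]
    )
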