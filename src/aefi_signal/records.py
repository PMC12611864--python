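"""Core record types for AEFI (adverse event following immunization) reports.

A :class:`ReportRecord` is one de-duplicated spontaneous report: demographics,
the combination-vaccine class it concerns, seriousness flags, and the set of
MedDRA preferred terms (PTs) coded on it.  Everything downstream — contingency
tables, disproportionality statistics, subgroup analyses and the death model —
consumes collections of these records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "VaccineClass",
    "Sex",
    "Recovered",
    "AgeGroup",
    "ReportRecord",
    "age_group_of",
    "AGE_MIN_YEARS",
    "AGE_MAX_YEARS",
    "AGE_G1_G2_YEARS",
    "AGE_G2_G3_YEARS",
]

# Age window and group boundaries, in decimal years.  "6 weeks" = 42 days,
# months use the mean Gregorian month of 30.44 days, "2 years" = 730 days.
# Groups are half-open on the right except the last: [42 d, 4 mo), [4 mo, 8 mo),
# [8 mo, 730 d].
_DAYS_PER_YEAR = 365.25
AGE_MIN_YEARS = 42.0 / _DAYS_PER_YEAR
AGE_G1_G2_YEARS = 4 * 30.44 / _DAYS_PER_YEAR
AGE_G2_G3_YEARS = 8 * 30.44 / _DAYS_PER_YEAR
AGE_MAX_YEARS = 730.0 / _DAYS_PER_YEAR


class VaccineClass(str, enum.Enum):
    """The two combination-vaccine classes under comparison."""

    PENTA = "penta"  # DTaP-IPV-Hib
    HEXA = "hexa"  # DTaP-IPV-Hib-HepB


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Recovered(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"
    MISSING = "missing"


class AgeGroup(str, enum.Enum):
    """Age strata: G1 = 6 weeks–<4 months, G2 = 4–<8 months, G3 = 8 months–2 years."""

    G1 = "G1"
    G2 = "G2"
    G3 = "G3"


def age_group_of(age_years: float) -> Optional[AgeGroup]:
    """Map an age in decimal years to its stratum, or None outside the window."""
    if age_years < AGE_MIN_YEARS or age_years > AGE_MAX_YEARS:
        return None
    if age_years < AGE_G1_G2_YEARS:
        return AgeGroup.G1
    if age_years < AGE_G2_G3_YEARS:
        return AgeGroup.G2
    return AgeGroup.G3


@dataclass(frozen=True)
class ReportRecord:
    """One analysis-ready AEFI report.

    ``serious`` is the regulatory composite: death, life-threatening event,
    hospitalization, prolonged hospitalization, or disability.  ``pts`` is the
    (non-empty) set of MedDRA preferred terms; ``socs`` the derived system
    organ classes under the loaded vocabulary.
    """

    report_id: str
    vaccine_class: VaccineClass
    age_years: float
    sex: Sex
    died: bool = False
    life_threatening: bool = False
    hospitalized: bool = False
    prolonged_hosp: bool = False
    disabled: bool = False
    recovered: Recovered = Recovered.MISSING
    vaccine_alone: bool = True
    onset_days: Optional[int] = None
    report_year: int = 2018
    region: Optional[str] = None
    pts: frozenset[str] = field(default_factory=frozenset)
    socs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.pts:
            raise ValueError(f"report {self.report_id}: PT set must be non-empty")
        if self.age_years < 0:
            raise ValueError(f"report {self.report_id}: negative age")

    @property
    def serious(self) -> bool:
        return (
            self.died
            or self.life_threatening
            or self.hospitalized
            or self.prolonged_hosp
            or self.disabled
        )

    @property
    def age_group(self) -> Optional[AgeGroup]:
        return age_group_of(self.age_years)

    def with_socs(self, socs: frozenset[str]) -> "ReportRecord":
        return replace(self, socs=socs)
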