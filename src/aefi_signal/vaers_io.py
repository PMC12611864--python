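"""Ingest VAERS-dialect extracts and apply the cohort-selection rules.

The public VAERS extract ships three CSV tables per year: DATA (one row per
report: demographics, seriousness flags, dates), VAX (one row per vaccine per
report) and SYMPTOMS (up to five MedDRA PT columns per row, with overflow rows
for reports carrying more than five PTs).  ``read_vaers_extract`` joins them
into one logical row per (report, vaccine) with the PT columns gathered into a
set; ``select_cohort`` applies the study's selection rules: vaccine-name
classification into pentavalent/hexavalent, the infant age window
(42 days – 2 years), de-duplication by report id, and exclusion of reports
whose only PTs describe vaccination errors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    AGE_MAX_YEARS,
    AGE_MIN_YEARS,
    Recovered,
    ReportRecord,
    Sex,
    VaccineClass,
)
from .vocab import DEFAULT_ERROR_PTS, soc_of, toy_vocab

log = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "read_vaers_extract",
    "select_cohort",
    "summarize_cohort",
    "round_pct",
]

_MANDATORY_DATA_COLS = ["VAERS_ID", "AGE_YRS", "SEX", "DIED", "L_THREAT", "HOSPITAL", "X_STAY", "DISABLE", "RECOVD"]
_MANDATORY_VAX_COLS = ["VAERS_ID", "VAX_NAME"]

ONSET_BINS = ["0", "1", "2-7", "8-30", ">30", "missing"]


@dataclass
class CohortConfig:
    """Selection rules for cohort construction.

    The pentavalent pattern matches vaccine names carrying DTaP+IPV+Hib; the
    hexavalent pattern additionally requires the HepB component.  A name that
    matches both resolves to hexavalent (the stricter superset pattern).
    """

    start_year: int = 2018
    end_year: int = 2024
    min_age_years: float = AGE_MIN_YEARS
    max_age_years: float = AGE_MAX_YEARS
    penta_pattern: str = r"DTAP\s*\+\s*IPV\s*\+\s*HIB"
    hexa_pattern: str = r"DTAP\s*\+\s*IPV\s*\+\s*HEPB\s*\+\s*HIB"
    error_pts: frozenset[str] = field(default_factory=lambda: DEFAULT_ERROR_PTS)
    vocab: dict[str, str] = field(default_factory=toy_vocab)

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("CohortConfig: start_year > end_year")
        if self.min_age_years >= self.max_age_years:
            raise ValueError("CohortConfig: min age must be below max age")


def _read_one_year(
    data_path: str | Path, vax_path: str | Path, symptoms_path: str | Path
) -> pd.DataFrame:
    data = pd.read_csv(data_path, dtype=str, keep_default_na=False, encoding="latin-1")
    vax = pd.read_csv(vax_path, dtype=str, keep_default_na=False, encoding="latin-1")
    sym = pd.read_csv(symptoms_path, dtype=str, keep_default_na=False, encoding="latin-1")

    for col in _MANDATORY_DATA_COLS:
        if col not in data.columns:
            raise ValueError(f"{data_path}: missing mandatory column {col}")
    for col in _MANDATORY_VAX_COLS:
        if col not in vax.columns:
            raise ValueError(f"{vax_path}: missing mandatory column {col}")
    if "VAERS_ID" not in sym.columns:
        raise ValueError(f"{symptoms_path}: missing mandatory column VAERS_ID")

    sym_cols = [c for c in sym.columns if re.fullmatch(r"SYMPTOM\d+", c)]
    pt_sets: dict[str, set[str]] = {}
    for vid, group in sym.groupby("VAERS_ID", sort=False):
        pts: set[str] = set()
        for c in sym_cols:
            pts.update(v.strip() for v in group[c] if v and v.strip())
        pt_sets[vid] = pts

    data = data.copy()
    data["PTS"] = data["VAERS_ID"].map(lambda v: frozenset(pt_sets.get(v, set())))
    merged = vax.merge(data, on="VAERS_ID", how="left", indicator=True)
    orphans = (merged["_merge"] != "both").sum()
    if orphans:
        log.warning("%d VAX rows had no matching DATA row; dropped", orphans)
        merged = merged[merged["_merge"] == "both"]
    return merged.drop(columns=["_merge"])


def read_vaers_extract(
    paths: Sequence[tuple[str | Path, str | Path, str | Path]] | tuple[str | Path, str | Path, str | Path],
) -> pd.DataFrame:
    """Read one or more (DATA, VAX, SYMPTOMS) file triples.

    Returns one logical row per (report, vaccine) with a ``PTS`` frozenset
    column.  Duplicate VAERS_IDs across years are retained for the dedup
    stage.  Unparseable rows are counted and logged, never silently dropped.
    """
    if isinstance(paths, tuple) and len(paths) == 3 and not isinstance(paths[0], tuple):
        paths = [paths]  # type: ignore[list-item]
    frames = [_read_one_year(*triple) for triple in paths]
    return pd.concat(frames, ignore_index=True)


def read_vaers_dir(directory: str | Path) -> pd.DataFrame:
    """Read every ``*VAERSDATA.csv`` triple found in a directory."""
    directory = Path(directory)
    triples = []
    for data_path in sorted(directory.glob("*VAERSDATA.csv")):
        stem = data_path.name[: -len("VAERSDATA.csv")]
        vax = directory / f"{stem}VAERSVAX.csv"
        sym = directory / f"{stem}VAERSSYMPTOMS.csv"
        if vax.exists() and sym.exists():
            triples.append((data_path, vax, sym))
    if not triples:
        raise FileNotFoundError(f"no VAERSDATA/VAERSVAX/VAERSSYMPTOMS triples under {directory}")
    return read_vaers_extract(triples)


def _classify_vax_name(name: str, config: CohortConfig) -> Optional[VaccineClass]:
    if re.search(config.hexa_pattern, name, flags=re.IGNORECASE):
        return VaccineClass.HEXA
    if re.search(config.penta_pattern, name, flags=re.IGNORECASE):
        return VaccineClass.PENTA
    return None


def _parse_flag(v: str) -> bool:
    return v.strip().upper() == "Y"


_RECOVD_IN = {"Y": Recovered.YES, "N": Recovered.NO, "U": Recovered.UNKNOWN, "": Recovered.MISSING}
_SEX_IN = {"M": Sex.MALE, "F": Sex.FEMALE, "U": Sex.UNKNOWN, "": Sex.UNKNOWN}


def select_cohort(raw: pd.DataFrame, config: CohortConfig | None = None) -> list[ReportRecord]:
    """Apply the four selection rules and build analysis-ready records.

    A report is retained iff it (i) has at least one vaccine row matching a
    combination-vaccine pattern (both patterns → hexavalent), (ii) has age
    within the configured window, (iii) is the first occurrence of its report
    id, and (iv) carries at least one PT outside the vaccination-error list.
    ``vaccine_alone`` is False iff any vaccine row names another product.
    """
    config = config or CohortConfig()
    records: list[ReportRecord] = []
    seen: set[str] = set()
    n_dup = n_age = n_error_only = n_unclassified = 0
    near_dup_keys: set[tuple] = set()

    for vid, group in raw.groupby("VAERS_ID", sort=False):
        if vid in seen:
            continue
        seen.add(vid)
        first = group.iloc[0]

        classes = {c for name in group["VAX_NAME"] if (c := _classify_vax_name(name, config))}
        if not classes:
            n_unclassified += 1
            continue
        if classes == {VaccineClass.PENTA, VaccineClass.HEXA}:
            log.info("report %s matches both name patterns; resolved to hexa", vid)
        cls = VaccineClass.HEXA if VaccineClass.HEXA in classes else VaccineClass.PENTA

        # duplicate VAERS_IDs within the frame: groupby collapses them, keep
        # first file-order rows only
        if len(group["VAERS_ID"].unique()) != 1:  # pragma: no cover - defensive
            n_dup += 1

        age_str = str(first.get("AGE_YRS", "")).strip()
        if not age_str:
            # AGE_YRS missing: fall back to CAGE_YR when present
            age_str = str(first.get("CAGE_YR", "")).strip()
        try:
            age = float(age_str)
        except ValueError:
            age = float("nan")
        if not (config.min_age_years - 1e-9 <= age <= config.max_age_years + 1e-9):
            n_age += 1
            continue

        pts = first["PTS"]
        if not isinstance(pts, frozenset):
            pts = frozenset()
        if not pts or not (pts - config.error_pts):
            n_error_only += 1
            continue

        alone = all(
            _classify_vax_name(name, config) is not None for name in group["VAX_NAME"]
        )

        recv = str(first.get("RECVDATE", "")).strip()
        year_match = re.search(r"(\d{4})", recv)
        year = int(year_match.group(1)) if year_match else config.start_year

        onset_str = str(first.get("NUMDAYS", "")).strip()
        try:
            onset: Optional[int] = int(float(onset_str)) if onset_str else None
        except ValueError:
            onset = None

        sex = _SEX_IN.get(str(first.get("SEX", "")).strip().upper(), Sex.UNKNOWN)
        rec = _RECOVD_IN.get(str(first.get("RECOVD", "")).strip().upper(), Recovered.MISSING)
        region = str(first.get("STATE", "")).strip() or None

        key = (str(first.get("RECVDATE", "")), round(age, 2), sex, pts)
        if key in near_dup_keys:
            log.info("report %s is a same-day/same-age/same-sex/same-PT near-duplicate", vid)
        near_dup_keys.add(key)

        records.append(
            ReportRecord(
                report_id=str(vid),
                vaccine_class=cls,
                age_years=age,
                sex=sex,
                died=_parse_flag(str(first["DIED"])),
                life_threatening=_parse_flag(str(first["L_THREAT"])),
                hospitalized=_parse_flag(str(first["HOSPITAL"])),
                prolonged_hosp=_parse_flag(str(first["X_STAY"])),
                disabled=_parse_flag(str(first["DISABLE"])),
                recovered=rec,
                vaccine_alone=alone,
                onset_days=onset,
                report_year=year,
                region=region,
                pts=pts,
                socs=frozenset(soc_of(pt, config.vocab) for pt in pts),
            )
        )

    log.info(
        "cohort selection: %d retained, %d unclassified vaccine, %d outside age window, %d error-only",
        len(records),
        n_unclassified,
        n_age,
        n_error_only,
    )
    if not records:
        raise ValueError("cohort selection retained zero reports")
    return records


def round_pct(count: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal (summary-table convention)."""
    if denom == 0:
        return 0.0
    pct = Decimal(count) / Decimal(denom) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _count_pct_block(pairs: dict[str, int], denom: int) -> dict[str, dict[str, float | int]]:
    return {k: {"n": v, "pct": round_pct(v, denom)} for k, v in pairs.items()}


def _onset_bin(onset: Optional[int]) -> str:
    if onset is None:
        return "missing"
    if onset <= 1:
        return str(onset)
    if onset <= 7:
        return "2-7"
    if onset <= 30:
        return "8-30"
    return ">30"


def summarize_cohort(reports: Iterable[ReportRecord]) -> dict:
    """Per-class summary of counts and percentages in the published table's
    layout, plus per-year, onset-bin and per-region count tables."""
    reports = list(reports)
    if not reports:
        raise ValueError("summarize_cohort: empty cohort")
    out: dict = {}
    for cls in VaccineClass:
        sub = [r for r in reports if r.vaccine_class is cls]
        n = len(sub)
        if n == 0:
            out[cls.value] = {"n": 0}
            continue
        block: dict = {"n": n}
        block["sex"] = _count_pct_block(
            {s.value: sum(r.sex is s for r in sub) for s in Sex}, n
        )
        block["serious"] = _count_pct_block(
            {"yes": sum(r.serious for r in sub), "no": sum(not r.serious for r in sub)}, n
        )
        block["vaccine_alone"] = _count_pct_block(
            {
                "yes": sum(r.vaccine_alone for r in sub),
                "no": sum(not r.vaccine_alone for r in sub),
            },
            n,
        )
        for flag in ("died", "life_threatening", "hospitalized", "prolonged_hosp", "disabled"):
            yes = sum(getattr(r, flag) for r in sub)
            block[flag] = _count_pct_block({"yes": yes, "not_available": n - yes}, n)
        block["recovered"] = _count_pct_block(
            {v.value: sum(r.recovered is v for r in sub) for v in Recovered}, n
        )
        block["by_year"] = {
            y: sum(r.report_year == y for r in sub)
            for y in sorted({r.report_year for r in sub})
        }
        block["onset"] = {
            b: sum(_onset_bin(r.onset_days) == b for r in sub) for b in ONSET_BINS
        }
        regions = sorted({r.region or "missing" for r in sub})
        block["by_region"] = {
            reg: sum((r.region or "missing") == reg for r in sub) for reg in regions
        }
        out[cls.value] = block
    return out


def summary_to_frame(summary: dict) -> pd.DataFrame:
    """Flatten a cohort summary into a tidy (class, block, level, n, pct) frame."""
    rows = []
    for cls, block in summary.items():
        for key, val in block.items():
            if key == "n":
                rows.append({"class": cls, "block": "N", "level": "", "n": val, "pct": None})
            elif isinstance(val, dict):
                for level, cell in val.items():
                    if isinstance(cell, dict):
                        rows.append(
                            {"class": cls, "block": key, "level": level, "n": cell["n"], "pct": cell["pct"]}
                        )
                    else:
                        rows.append({"class": cls, "block": key, "level": str(level), "n": cell, "pct": None})
    return pd.DataFrame(rows)
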