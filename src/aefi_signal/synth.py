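"""Synthetic spontaneous-reporting cohorts with known ground truth.

The generator emulates a two-vaccine infant cohort in the style of a passive
surveillance system: each simulated report draws a vaccine class
(pentavalent or hexavalent), demographics, co-administration status, a set of
MedDRA-style preferred terms (per-PT Bernoulli with a multiplicative
vaccine-specific relative reporting rate), seriousness flags, and a death
classification from a logistic model on age group, sex and co-administration.
The planted relative rates and death-model coefficients are returned as a
:class:`SyntheticTruth` so recovery tests can compare estimates to truth.

``table1_fixture`` is a separate, fully deterministic cohort whose marginal
counts reproduce the published summary table of the real pentavalent /
hexavalent comparison (3,259 + 1,720 reports) exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .records import AgeGroup, Recovered, ReportRecord, Sex, VaccineClass, age_group_of
from .vocab import DEFAULT_ERROR_PTS, FALLBACK_PT, TOY_VOCABULARY, soc_of

log = logging.getLogger(__name__)

__all__ = [
    "DeathCoefs",
    "SimConfig",
    "SyntheticTruth",
    "default_config",
    "generate_reports",
    "write_vaers_dialect",
    "table1_fixture",
    "PENTA_VAX_NAME",
    "HEXA_VAX_NAME",
    "COADMIN_VAX_NAME",
]

PENTA_VAX_NAME = "DTAP + IPV + HIB (PENTACEL)"
HEXA_VAX_NAME = "DTAP + IPV + HEPB + HIB (VAXELIS)"
COADMIN_VAX_NAME = "INFLUENZA (SEASONAL) (FLUZONE QUADRIVALENT)"
_VAX_TYPE = {VaccineClass.PENTA: "DTAPIPVHIB", VaccineClass.HEXA: "DTAPIPVHIBHEPB"}

# 0.01-year age grid bounds per group (inclusive), chosen so that every grid
# value lies strictly inside its group after the 2-decimal VAERS rounding.
_AGE_GRID = {AgeGroup.G1: (12, 33), AgeGroup.G2: (34, 66), AgeGroup.G3: (67, 199)}

_REGIONS = ["FR", "TX", "CA", "MI", "NY", "MA", "WA", "PA", "FL", "OH"]
_REGION_P = [0.30, 0.12, 0.10, 0.08, 0.08, 0.08, 0.07, 0.06, 0.06, 0.05]

# Recovery-status distribution given survival (died reports are coded "no").
_RECOVD_P = {"yes": 0.45, "no": 0.17, "unknown": 0.30, "missing": 0.08}


@dataclass(frozen=True)
class DeathCoefs:
    """Log-odds coefficients of the death-classification model.

    Reference cell: age 6 weeks–<4 months, male, vaccine given alone.
    """

    intercept: float
    age_g2: float
    age_g3: float
    female: float
    coadmin: float

    def linear_predictor(
        self,
        g2: np.ndarray,
        g3: np.ndarray,
        female: np.ndarray,
        coadmin: np.ndarray,
    ) -> np.ndarray:
        return (
            self.intercept
            + self.age_g2 * g2
            + self.age_g3 * g3
            + self.female * female
            + self.coadmin * coadmin
        )


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    ``planted_rr`` maps (PT, vaccine-class value) to a multiplicative relative
    reporting rate applied to the PT's baseline probability for that class;
    unlisted pairs default to 1.  ``age_dist`` gives per-class probabilities
    over the three age groups (G1, G2, G3).
    """

    n_penta: int = 3259
    n_hexa: int = 1720
    pt_vocab: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(TOY_VOCABULARY)
    )
    planted_rr: dict[tuple[str, str], float] = field(default_factory=dict)
    age_dist: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"penta": (0.55, 0.25, 0.20), "hexa": (0.60, 0.25, 0.15)}
    )
    p_female: float = 0.455
    p_unknown_sex: float = 0.06
    p_coadmin: dict[str, float] = field(
        default_factory=lambda: {"penta": 0.68, "hexa": 0.88}
    )
    death_coefs: DeathCoefs = field(
        default_factory=lambda: DeathCoefs(
            intercept=-5.0,
            age_g2=float(np.log(0.212)),
            age_g3=float(np.log(0.170)),
            female=float(np.log(0.440)),
            coadmin=float(np.log(6.694)),
        )
    )
    seriousness_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "penta": {
                "hospitalized": 0.101,
                "life_threatening": 0.015,
                "prolonged_hosp": 0.003,
                "disabled": 0.019,
            },
            "hexa": {
                "hospitalized": 0.340,
                "life_threatening": 0.051,
                "prolonged_hosp": 0.007,
                "disabled": 0.019,
            },
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_penta < 0 or self.n_hexa < 0:
            raise ValueError("n_penta/n_hexa: counts must be non-negative")
        pts = [pt for pt, _, _ in self.pt_vocab]
        if len(set(pts)) != len(pts):
            raise ValueError("pt_vocab: each PT must map to exactly one SOC")
        for pt, _, p in self.pt_vocab:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pt_vocab: baseline for {pt!r} outside [0, 1]")
        for (pt, cls), rr in self.planted_rr.items():
            if rr < 0:
                raise ValueError(f"planted_rr: negative multiplier for ({pt!r}, {cls!r})")
            if cls not in ("penta", "hexa"):
                raise ValueError(f"planted_rr: unknown vaccine class {cls!r}")
            if pt not in set(pts):
                raise ValueError(f"planted_rr: PT {pt!r} not in pt_vocab")
        for cls, dist in self.age_dist.items():
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"age_dist[{cls!r}]: probabilities must sum to 1")
            if any(p < 0 for p in dist):
                raise ValueError(f"age_dist[{cls!r}]: negative probability")
        for name, p in (("p_female", self.p_female), ("p_unknown_sex", self.p_unknown_sex)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: probability outside [0, 1]")
        if self.p_female + self.p_unknown_sex > 1.0:
            raise ValueError("p_female + p_unknown_sex exceeds 1")
        for cls, p in self.p_coadmin.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_coadmin[{cls!r}]: probability outside [0, 1]")
        for cls, probs in self.seriousness_probs.items():
            for k, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"seriousness_probs[{cls!r}][{k!r}] outside [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "pt_vocab" in d:
            d["pt_vocab"] = [tuple(row) for row in d["pt_vocab"]]
        if "planted_rr" in d and isinstance(d["planted_rr"], dict):
            d["planted_rr"] = {
                (k.split("|", 1)[0], k.split("|", 1)[1]) if isinstance(k, str) else tuple(k): v
                for k, v in d["planted_rr"].items()
            }
        if "age_dist" in d:
            d["age_dist"] = {k: tuple(v) for k, v in d["age_dist"].items()}
        if "death_coefs" in d and isinstance(d["death_coefs"], dict):
            d["death_coefs"] = DeathCoefs(**d["death_coefs"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def default_config(seed: int = 0) -> SimConfig:
    cfg = SimConfig(seed=seed)
    cfg.validate()
    return cfg


def paperlike_config(seed: int = 0) -> SimConfig:
    """Study conditions with planted signals emulating the reported pattern:
    elevated hexavalent reporting in nervous-system, respiratory, cardiac and
    vascular events (strongest in young infants' events such as apnoea and
    cyanosis), and mild pentavalent elevation in investigations/error terms."""
    cfg = SimConfig(
        seed=seed,
        planted_rr={
            ("Apnoea", "hexa"): 2.5,
            ("Cyanosis", "hexa"): 2.5,
            ("Seizure", "hexa"): 1.8,
            ("Febrile convulsion", "hexa"): 2.0,
            ("Hypotonic-hyporesponsive episode", "hexa"): 2.0,
            ("Bradycardia", "hexa"): 2.0,
            ("Hypotension", "hexa"): 2.5,
            ("Loss of consciousness", "hexa"): 2.0,
            ("Platelet count increased", "penta"): 1.8,
            ("Body temperature increased", "penta"): 1.3,
            ("Incorrect dose administered", "penta"): 1.5,
        },
    )
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Planted parameters plus bookkeeping for recovery tests."""

    planted_rr: dict[tuple[str, str], float]
    death_coefs: DeathCoefs
    expected_pt_counts: dict[str, dict[str, float]]  # class -> PT -> E[count]
    age_group_counts: dict[str, dict[str, int]]  # class -> group -> realized n
    covariate_counts: dict[str, dict[str, int]]  # class -> {female, unknown_sex, coadmin, died}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_rr": {f"{pt}|{cls}": rr for (pt, cls), rr in self.planted_rr.items()},
            "death_coefs": asdict(self.death_coefs),
            "expected_pt_counts": self.expected_pt_counts,
            "age_group_counts": self.age_group_counts,
            "covariate_counts": self.covariate_counts,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _clipped_pt_probs(
    config: SimConfig, cls: VaccineClass
) -> tuple[list[str], np.ndarray]:
    pts = [pt for pt, _, _ in config.pt_vocab]
    base = np.array([p for _, _, p in config.pt_vocab])
    rr = np.array(
        [config.planted_rr.get((pt, cls.value), 1.0) for pt in pts]
    )
    raw = base * rr
    over = raw > 1.0
    if over.any():
        for pt in np.array(pts)[over]:
            log.warning(
                "planted rate for (%s, %s) exceeds 1 after multiplication; clamped",
                pt,
                cls.value,
            )
    return pts, np.minimum(raw, 1.0)


def generate_reports(config: SimConfig) -> tuple[list[ReportRecord], SyntheticTruth]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    PT occurrences are conditionally independent given vaccine class (per-PT
    Bernoulli at ``min(1, baseline × rr)``); a report that would carry no PT
    is assigned the benign fallback PT so report counts stay exact.  The death
    indicator follows the configured logistic model; other seriousness flags
    are drawn independently given death status, with death forcing the serious
    composite.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab_map = {pt: soc for pt, soc, _ in config.pt_vocab}
    records: list[ReportRecord] = []
    expected: dict[str, dict[str, float]] = {}
    group_counts: dict[str, dict[str, int]] = {}
    cov_counts: dict[str, dict[str, int]] = {}

    for cls, n in ((VaccineClass.PENTA, config.n_penta), (VaccineClass.HEXA, config.n_hexa)):
        pts, probs = _clipped_pt_probs(config, cls)
        expected[cls.value] = {pt: float(n * p) for pt, p in zip(pts, probs)}
        if n == 0:
            group_counts[cls.value] = {g.value: 0 for g in AgeGroup}
            cov_counts[cls.value] = {"female": 0, "unknown_sex": 0, "coadmin": 0, "died": 0}
            continue

        grp_idx = rng.choice(3, size=n, p=config.age_dist[cls.value])
        lo = np.array([_AGE_GRID[g][0] for g in (AgeGroup.G1, AgeGroup.G2, AgeGroup.G3)])
        hi = np.array([_AGE_GRID[g][1] for g in (AgeGroup.G1, AgeGroup.G2, AgeGroup.G3)])
        age_cents = lo[grp_idx] + rng.integers(
            0, hi[grp_idx] - lo[grp_idx] + 1, size=n
        )
        ages = age_cents / 100.0

        u = rng.random(n)
        sex = np.where(
            u < config.p_unknown_sex,
            "unknown",
            np.where(u < config.p_unknown_sex + config.p_female, "female", "male"),
        )
        coadmin = rng.random(n) < config.p_coadmin[cls.value]

        pt_matrix = rng.random((n, len(pts))) < probs[None, :]
        # fallback: a report with no clinical PT (empty, or error-PTs only)
        # gets the benign fallback PT, so no report is event-free and every
        # generated report survives the error-only cohort exclusion
        clinical_cols = [i for i, pt in enumerate(pts) if pt not in DEFAULT_ERROR_PTS]
        empty = ~pt_matrix[:, clinical_cols].any(axis=1)
        if empty.any():
            fallback_col = pts.index(FALLBACK_PT) if FALLBACK_PT in pts else 0
            pt_matrix[empty, fallback_col] = True

        g2 = (grp_idx == 1).astype(float)
        g3 = (grp_idx == 2).astype(float)
        female = (sex == "female").astype(float)
        eta = config.death_coefs.linear_predictor(g2, g3, female, coadmin.astype(float))
        died = rng.random(n) < expit(eta)

        sprobs = config.seriousness_probs[cls.value]
        hosp = rng.random(n) < sprobs["hospitalized"]
        lthreat = rng.random(n) < sprobs["life_threatening"]
        prolonged = rng.random(n) < sprobs["prolonged_hosp"]
        disabled = rng.random(n) < sprobs["disabled"]

        rec_u = rng.random(n)
        cuts = np.cumsum([_RECOVD_P["yes"], _RECOVD_P["no"], _RECOVD_P["unknown"]])
        recovered = np.select(
            [rec_u < cuts[0], rec_u < cuts[1], rec_u < cuts[2]],
            ["yes", "no", "unknown"],
            default="missing",
        )
        onset = np.minimum(rng.geometric(0.30, size=n) - 1, 90)
        onset_missing = rng.random(n) < 0.08
        years = rng.integers(2018, 2025, size=n)
        regions = rng.choice(_REGIONS, size=n, p=_REGION_P)

        prefix = "P" if cls is VaccineClass.PENTA else "H"
        for i in range(n):
            pt_set = frozenset(np.array(pts)[pt_matrix[i]])
            records.append(
                ReportRecord(
                    report_id=f"{prefix}{i + 1:07d}",
                    vaccine_class=cls,
                    age_years=float(ages[i]),
                    sex=Sex(str(sex[i])),
                    died=bool(died[i]),
                    life_threatening=bool(lthreat[i]),
                    hospitalized=bool(hosp[i]),
                    prolonged_hosp=bool(prolonged[i]),
                    disabled=bool(disabled[i]),
                    recovered=Recovered.NO if died[i] else Recovered(str(recovered[i])),
                    vaccine_alone=not bool(coadmin[i]),
                    onset_days=None if onset_missing[i] else int(onset[i]),
                    report_year=int(years[i]),
                    region=str(regions[i]),
                    pts=pt_set,
                    socs=frozenset(soc_of(pt, vocab_map) for pt in pt_set),
                )
            )

        realized_groups = np.array([age_group_of(a).value for a in ages])
        group_counts[cls.value] = {
            g.value: int((realized_groups == g.value).sum()) for g in AgeGroup
        }
        cov_counts[cls.value] = {
            "female": int((sex == "female").sum()),
            "unknown_sex": int((sex == "unknown").sum()),
            "coadmin": int(coadmin.sum()),
            "died": int(died.sum()),
        }

    truth = SyntheticTruth(
        planted_rr=dict(config.planted_rr),
        death_coefs=config.death_coefs,
        expected_pt_counts=expected,
        age_group_counts=group_counts,
        covariate_counts=cov_counts,
    )
    return records, truth


# ---------------------------------------------------------------------------
# VAERS-dialect writer


def _flag(b: bool) -> str:
    return "Y" if b else ""


_RECOVD_OUT = {
    Recovered.YES: "Y",
    Recovered.NO: "N",
    Recovered.UNKNOWN: "U",
    Recovered.MISSING: "",
}


def write_vaers_dialect(
    records: Sequence[ReportRecord], out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write DATA / VAX / SYMPTOMS CSVs in the VAERS public-extract layout.

    SYMPTOMS rows carry at most five PT columns; reports with more PTs spill
    into additional rows.  Reading the files back through the ingest module
    reproduces the records exactly.
    """
    if not records:
        raise ValueError("write_vaers_dialect: empty record collection")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    data_path = out_dir / "VAERSDATA.csv"
    vax_path = out_dir / "VAERSVAX.csv"
    sym_path = out_dir / "VAERSSYMPTOMS.csv"

    with open(data_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
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
        )
        for r in records:
            w.writerow(
                [
                    r.report_id,
                    f"07/01/{r.report_year}",
                    r.region or "",
                    f"{r.age_years:.2f}",
                    {"male": "M", "female": "F", "unknown": "U"}[r.sex.value],
                    _flag(r.died),
                    _flag(r.life_threatening),
                    _flag(r.hospitalized),
                    _flag(r.prolonged_hosp),
                    _flag(r.disabled),
                    _RECOVD_OUT[r.recovered],
                    "" if r.onset_days is None else r.onset_days,
                ]
            )

    with open(vax_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "VAX_TYPE", "VAX_NAME"])
        for r in records:
            name = PENTA_VAX_NAME if r.vaccine_class is VaccineClass.PENTA else HEXA_VAX_NAME
            w.writerow([r.report_id, _VAX_TYPE[r.vaccine_class], name])
            if not r.vaccine_alone:
                w.writerow([r.report_id, "FLU4", COADMIN_VAX_NAME])

    with open(sym_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "SYMPTOM1", "SYMPTOM2", "SYMPTOM3", "SYMPTOM4", "SYMPTOM5"])
        for r in records:
            pts = sorted(r.pts)
            for i in range(0, len(pts), 5):
                chunk = pts[i : i + 5]
                w.writerow([r.report_id] + chunk + [""] * (5 - len(chunk)))

    return data_path, vax_path, sym_path


# ---------------------------------------------------------------------------
# Deterministic fixture matching the published summary table


def _interval_flags(n: int, spans: dict[str, tuple[int, int]]) -> dict[str, np.ndarray]:
    """Boolean flag vectors where each flag is True on [start, stop)."""
    out = {}
    for name, (start, stop) in spans.items():
        v = np.zeros(n, dtype=bool)
        v[start:stop] = True
        out[name] = v
    return out


def table1_fixture() -> list[ReportRecord]:
    """Deterministic cohort reproducing the published Table-1 margins exactly.

    The published table prints only per-class margins, so the joint structure
    here is arbitrary: flags occupy contiguous index ranges laid out so the
    serious composite (union of the five flags) hits its printed count, with
    death forcing serious.
    """
    vocab_map = {pt: soc for pt, soc, _ in TOY_VOCABULARY}
    clinical_pts = [pt for pt, soc, _ in TOY_VOCABULARY if soc != "Injury, poisoning and procedural complications"]

    spec = {
        VaccineClass.PENTA: dict(
            n=3259,
            sex=(1588, 1483, 188),  # male, female, unknown
            died=(0, 70),
            disabled=(70, 131),
            life_threatening=(131, 179),
            hospitalized=(110, 440),
            prolonged_hosp=(110, 119),
            vaccine_alone=1044,
            recovered=(1203, 444, 1328),  # yes, no, unknown; rest missing
            regions=["FR", "TX", "MI", "CA", "NY"],
            prefix="FP",
        ),
        VaccineClass.HEXA: dict(
            n=1720,
            sex=(848, 753, 119),
            died=(0, 39),
            disabled=(39, 71),
            life_threatening=(71, 159),
            hospitalized=(73, 658),
            prolonged_hosp=(73, 85),
            vaccine_alone=206,
            recovered=(904, 362, 389),
            regions=["FR", "TX", "MA", "CA", "WA"],
            prefix="FH",
        ),
    }

    ages = [0.20, 0.50, 1.00]  # one representative age per group
    onsets = [0, 1, 5, 20, 45, None]
    years = [2018, 2019, 2020, 2021, 2022, 2023, 2024]
    records: list[ReportRecord] = []

    for cls, s in spec.items():
        n = s["n"]
        flags = _interval_flags(
            n,
            {
                k: s[k]
                for k in ("died", "disabled", "life_threatening", "hospitalized", "prolonged_hosp")
            },
        )
        n_m, n_f, _ = s["sex"]
        n_ry, n_rn, n_ru = s["recovered"]
        for i in range(n):
            if i < n_m:
                sex = Sex.MALE
            elif i < n_m + n_f:
                sex = Sex.FEMALE
            else:
                sex = Sex.UNKNOWN
            if i < n_ry:
                rec = Recovered.YES
            elif i < n_ry + n_rn:
                rec = Recovered.NO
            elif i < n_ry + n_rn + n_ru:
                rec = Recovered.UNKNOWN
            else:
                rec = Recovered.MISSING
            pt = clinical_pts[i % len(clinical_pts)]
            records.append(
                ReportRecord(
                    report_id=f"{s['prefix']}{i + 1:06d}",
                    vaccine_class=cls,
                    age_years=ages[i % 3],
                    sex=sex,
                    died=bool(flags["died"][i]),
                    life_threatening=bool(flags["life_threatening"][i]),
                    hospitalized=bool(flags["hospitalized"][i]),
                    prolonged_hosp=bool(flags["prolonged_hosp"][i]),
                    disabled=bool(flags["disabled"][i]),
                    recovered=rec,
                    vaccine_alone=i < s["vaccine_alone"],
                    onset_days=onsets[i % len(onsets)],
                    report_year=years[i % len(years)],
                    region=s["regions"][i % len(s["regions"])],
                    pts=frozenset({pt}),
                    socs=frozenset({soc_of(pt, vocab_map)}),
                )
            )
    return records
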