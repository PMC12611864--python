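"""Toy MedDRA-style vocabulary: preferred term (PT) -> system organ class (SOC).

Real MedDRA is licensed and must be supplied by the user as a two-column CSV
(PT, SOC).  The bundled toy vocabulary covers ~50 PTs across 13 SOCs chosen to
resemble an infant combination-vaccine safety profile (injection-site
reactions, fever, seizures, apnoea, ...), plus a block of vaccination-error
PTs used by the cohort filter.  Each PT carries a baseline per-report
reporting probability used by the synthetic generator.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

log = logging.getLogger(__name__)

UNMAPPED_SOC = "Unmapped"

SOC_GENERAL = "General disorders and administration site conditions"
SOC_NERVOUS = "Nervous system disorders"
SOC_RESP = "Respiratory, thoracic and mediastinal disorders"
SOC_GI = "Gastrointestinal disorders"
SOC_SKIN = "Skin and subcutaneous tissue disorders"
SOC_CARDIAC = "Cardiac disorders"
SOC_VASC = "Vascular disorders"
SOC_IMMUNE = "Immune system disorders"
SOC_METAB = "Metabolism and nutrition disorders"
SOC_INVEST = "Investigations"
SOC_PSYCH = "Psychiatric disorders"
SOC_MSK = "Musculoskeletal and connective tissue disorders"
SOC_INJURY = "Injury, poisoning and procedural complications"

# (PT, SOC, baseline reporting probability per report)
TOY_VOCABULARY: list[tuple[str, str, float]] = [
    ("Pyrexia", SOC_GENERAL, 0.25),
    ("Injection site erythema", SOC_GENERAL, 0.10),
    ("Injection site swelling", SOC_GENERAL, 0.08),
    ("Injection site induration", SOC_GENERAL, 0.05),
    ("Crying", SOC_GENERAL, 0.08),
    ("Irritability", SOC_GENERAL, 0.09),
    ("Fatigue", SOC_GENERAL, 0.04),
    ("Malaise", SOC_GENERAL, 0.03),
    ("Seizure", SOC_NERVOUS, 0.030),
    ("Febrile convulsion", SOC_NERVOUS, 0.025),
    ("Somnolence", SOC_NERVOUS, 0.050),
    ("Hypotonia", SOC_NERVOUS, 0.020),
    ("Hypotonic-hyporesponsive episode", SOC_NERVOUS, 0.012),
    ("Lethargy", SOC_NERVOUS, 0.030),
    ("Loss of consciousness", SOC_NERVOUS, 0.010),
    ("Infantile spasms", SOC_NERVOUS, 0.004),
    ("Tremor", SOC_NERVOUS, 0.008),
    ("Apnoea", SOC_RESP, 0.010),
    ("Cyanosis", SOC_RESP, 0.015),
    ("Cough", SOC_RESP, 0.020),
    ("Tachypnoea", SOC_RESP, 0.008),
    ("Respiratory arrest", SOC_RESP, 0.003),
    ("Vomiting", SOC_GI, 0.070),
    ("Diarrhoea", SOC_GI, 0.050),
    ("Haematochezia", SOC_GI, 0.006),
    ("Abdominal pain", SOC_GI, 0.015),
    ("Nausea", SOC_GI, 0.010),
    ("Rash", SOC_SKIN, 0.060),
    ("Urticaria", SOC_SKIN, 0.025),
    ("Erythema", SOC_SKIN, 0.030),
    ("Pallor", SOC_SKIN, 0.015),
    ("Bradycardia", SOC_CARDIAC, 0.005),
    ("Tachycardia", SOC_CARDIAC, 0.008),
    ("Cardiac arrest", SOC_CARDIAC, 0.002),
    ("Flushing", SOC_VASC, 0.010),
    ("Hypotension", SOC_VASC, 0.004),
    ("Anaphylactic reaction", SOC_IMMUNE, 0.004),
    ("Hypersensitivity", SOC_IMMUNE, 0.010),
    ("Decreased appetite", SOC_METAB, 0.040),
    ("Dehydration", SOC_METAB, 0.008),
    ("Hyperkalaemia", SOC_METAB, 0.002),
    ("Body temperature increased", SOC_INVEST, 0.060),
    ("C-reactive protein increased", SOC_INVEST, 0.008),
    ("Platelet count increased", SOC_INVEST, 0.003),
    ("White blood cell count increased", SOC_INVEST, 0.005),
    ("Screaming", SOC_PSYCH, 0.020),
    ("Restlessness", SOC_PSYCH, 0.015),
    ("Musculoskeletal stiffness", SOC_MSK, 0.006),
    ("Muscle twitching", SOC_MSK, 0.005),
    ("Incorrect dose administered", SOC_INJURY, 0.008),
    ("Inappropriate schedule of product administration", SOC_INJURY, 0.010),
    ("Product administration error", SOC_INJURY, 0.005),
    ("Expired product administered", SOC_INJURY, 0.002),
]

# PTs that, on their own, describe a vaccination error rather than a clinical
# AEFI; reports carrying only these are excluded by the cohort filter.
DEFAULT_ERROR_PTS: frozenset[str] = frozenset(
    pt for pt, soc, _ in TOY_VOCABULARY if soc == SOC_INJURY
)

# Benign PT assigned to a simulated report that would otherwise be event-free.
FALLBACK_PT = "Pyrexia"


def toy_vocab() -> dict[str, str]:
    """The bundled PT -> SOC mapping."""
    return {pt: soc for pt, soc, _ in TOY_VOCABULARY}


def toy_baselines() -> dict[str, float]:
    """Default per-report reporting probability for each toy PT."""
    return {pt: p for pt, _, p in TOY_VOCABULARY}


def load_vocab(path: str | Path) -> dict[str, str]:
    """Read a two-column (PT, SOC) CSV; a header row is detected and skipped."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or not row[0].strip():
                continue
            if i == 0 and row[0].strip().upper() in {"PT", "PREFERRED_TERM"}:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {i + 1} has no SOC column")
            mapping[row[0].strip()] = row[1].strip()
    return mapping


def write_vocab(mapping: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["PT", "SOC"])
        for pt in sorted(mapping):
            writer.writerow([pt, mapping[pt]])
    return path


def soc_of(pt: str, vocab: dict[str, str]) -> str:
    """SOC for a PT; unknown PTs map to a designated 'Unmapped' SOC."""
    soc = vocab.get(pt)
    if soc is None:
        log.warning("PT %r not in vocabulary; mapped to %r", pt, UNMAPPED_SOC)
        return UNMAPPED_SOC
    return soc
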