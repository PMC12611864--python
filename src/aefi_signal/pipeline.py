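"""End-to-end orchestration: ingest → cohort → tables → signals → subgroups →
death model → manifest.

Every stage is a pure function of (input files, configuration, seed); running
the same configuration twice produces byte-identical manifest-tracked outputs.
A single global seed governs the only stochastic stage (synthetic cohort
generation); derived seeds are produced with numpy's ``SeedSequence`` spawning
rule so adding stages never perturbs earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from . import __version__
from .contingency import build_all_tables, tables_to_frame
from .death_model import build_design, fit_logistic, fit_to_frame
from .disproportionality import score_tables, signals_to_frame
from .records import ReportRecord, VaccineClass
from .subgroup import stratify, top_k_pts, top_k_to_frame
from .synth import SimConfig, generate_reports, table1_fixture, write_vaers_dialect
from .vaers_io import CohortConfig, read_vaers_dir, select_cohort, summarize_cohort, summary_to_frame

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    input_mode: Literal["vaers_dir", "synthetic", "fixture"] = "synthetic"
    vaers_dir: Optional[str] = None
    sim_config: Optional[SimConfig] = None
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    comparator_mode: Literal["other_class", "external_background"] = "other_class"
    levels: tuple[str, ...] = ("PT", "SOC")
    strata_factors: tuple[str, ...] = ("age_group", "sex", "serious")
    top_k: int = 20
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "WARNING"

    def validate(self) -> None:
        if self.input_mode == "vaers_dir" and not self.vaers_dir:
            raise ValueError("RunConfig: vaers_dir mode needs a directory")
        if self.top_k < 1:
            raise ValueError("RunConfig: top_k must be at least 1")

    def hash(self) -> str:
        payload = {
            "input_mode": self.input_mode,
            "vaers_dir": self.vaers_dir,
            "sim_config": None if self.sim_config is None else repr(self.sim_config),
            "comparator_mode": self.comparator_mode,
            "levels": list(self.levels),
            "strata_factors": list(self.strata_factors),
            "top_k": self.top_k,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _load_reports(config: RunConfig) -> list[ReportRecord]:
    if config.input_mode == "fixture":
        return table1_fixture()
    if config.input_mode == "synthetic":
        sim = config.sim_config or SimConfig()
        # derive the generator seed from the run seed (kept below 2**31)
        child = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
        sim.seed = child
        records, _ = generate_reports(sim)
        return records
    raw = read_vaers_dir(config.vaers_dir)
    return select_cohort(raw, config.cohort_config)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the JSON-serializable manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "files": {},
    }

    def write_frame(df, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["files"][name] = {"rows": int(len(df))}
        log.info("stage output %s: %d rows", name, len(df))

    stage = "ingest"
    try:
        reports = _load_reports(config)
        manifest["n_reports"] = len(reports)
        manifest["n_by_class"] = {
            cls.value: sum(r.vaccine_class is cls for r in reports) for cls in VaccineClass
        }

        stage = "cohort_summary"
        summary = summarize_cohort(reports)
        (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["files"]["cohort_summary.json"] = {"rows": len(summary)}
        write_frame(summary_to_frame(summary), "cohort_summary.csv")

        stage = "contingency"
        vocab = config.cohort_config.vocab
        all_tables = {}
        for level in config.levels:
            for cls in VaccineClass:
                tables = build_all_tables(
                    reports, level, cls, config.comparator_mode, vocab=vocab
                )
                all_tables[(level, cls)] = tables
                write_frame(tables_to_frame(tables), f"contingency_{level}_{cls.value}.csv")

        stage = "signals"
        for (level, cls), tables in all_tables.items():
            results = score_tables(tables)
            write_frame(signals_to_frame(results), f"signals_{level}_{cls.value}.csv")

        stage = "subgroups"
        for factor in config.strata_factors:
            strata = stratify(reports, factor)
            for level_name in sorted(strata):
                sub = strata[level_name]
                for cls in VaccineClass:
                    if not any(r.vaccine_class is cls for r in sub):
                        continue
                    if not any(r.vaccine_class is not cls for r in sub):
                        continue
                    tables = build_all_tables(sub, "PT", cls, vocab=vocab)
                    results = score_tables(tables)
                    tag = f"{factor}-{level_name}_{cls.value}"
                    write_frame(signals_to_frame(results), f"signals_stratum_{tag}.csv")
                    entries = top_k_pts(sub, config.top_k, cls)
                    write_frame(top_k_to_frame(entries), f"topk_{tag}.csv")

        stage = "death_model"
        for cls in VaccineClass:
            sub = [r for r in reports if r.vaccine_class is cls]
            try:
                fit = fit_logistic(build_design(sub, cls))
            except (ValueError, RuntimeError) as exc:
                log.warning("death model skipped for %s: %s", cls.value, exc)
                manifest.setdefault("death_model_skipped", {})[cls.value] = str(exc)
                continue
            write_frame(fit_to_frame(fit), f"death_model_{cls.value}.csv")

    except Exception as exc:
        raise PipelineError(stage, exc, manifest) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def simulate_to_dir(sim: SimConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic cohort and write it in the VAERS dialect plus a
    ground-truth JSON sidecar."""
    records, truth = generate_reports(sim)
    data, vax, sym = write_vaers_dialect(records, out_dir)
    truth_path = truth.to_json(Path(out_dir) / "truth.json")
    return {
        "n_reports": len(records),
        "files": [str(data), str(vax), str(sym), str(truth_path)],
    }
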