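#!/usr/bin/env python
"""Baseline characteristics of both cohorts.

Runs the deterministic fixture that reproduces the published summary-table
margins (3,259 pentavalent / 1,720 hexavalent reports) through the cohort
summarizer, then summarizes the synthetic cohort written by
01_simulate_cohort.py.  Finding to check in the output: the hexavalent class
shows a much larger serious fraction (38.3% vs 13.5%) driven by
hospitalization and life-threatening events, while the pentavalent class has
the larger vaccine-given-alone fraction (32.0% vs 12.0%).
"""

import json
from pathlib import Path

from aefi_signal.synth import table1_fixture
from aefi_signal.vaers_io import read_vaers_dir, select_cohort, summarize_cohort, summary_to_frame

OUT = Path("results/tables")


def show(summary: dict, label: str) -> None:
    print(f"--- {label} ---")
    for cls in ("penta", "hexa"):
        b = summary[cls]
        print(
            f"{cls}: N={b['n']}  serious {b['serious']['yes']['pct']}%  "
            f"hospitalized {b['hospitalized']['yes']['pct']}%  "
            f"died {b['died']['yes']['pct']}%  "
            f"vaccine alone {b['vaccine_alone']['yes']['pct']}%"
        )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    fixture_summary = summarize_cohort(table1_fixture())
    show(fixture_summary, "published-margin fixture")
    summary_to_frame(fixture_summary).to_csv(OUT / "fixture_summary.csv", index=False)
    (OUT / "fixture_summary.json").write_text(json.dumps(fixture_summary, indent=2, sort_keys=True))

    syn_dir = Path("scratch/synthetic")
    if syn_dir.exists():
        cohort = select_cohort(read_vaers_dir(syn_dir))
        syn_summary = summarize_cohort(cohort)
        show(syn_summary, "synthetic cohort (re-ingested from dialect files)")
        summary_to_frame(syn_summary).to_csv(OUT / "synthetic_summary.csv", index=False)
    else:
        print("synthetic cohort not found; run 01_simulate_cohort.py first")


if __name__ == "__main__":
    main()
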