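#!/usr/bin/env python
"""Subgroup analyses: age-group, sex and seriousness strata.

For each stratum the same contingency + disproportionality machinery runs
within-stratum, and the top-20 most frequently reported PTs are tabulated
with their within-stratum RORs and 95% CIs.  The youngest infants
(6 weeks–<4 months) carry the largest share of reports in both classes.
"""

from pathlib import Path

from aefi_signal.records import VaccineClass
from aefi_signal.subgroup import stratify, top_k_pts, top_k_to_frame
from aefi_signal.vaers_io import read_vaers_dir, select_cohort

OUT = Path("results/subgroups")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = select_cohort(read_vaers_dir("scratch/synthetic"))

    for factor in ("age_group", "sex", "serious"):
        strata = stratify(cohort, factor)
        sizes = {
            level: {
                cls.value: sum(r.vaccine_class is cls for r in sub)
                for cls in VaccineClass
            }
            for level, sub in sorted(strata.items())
        }
        print(f"{factor}: stratum sizes {sizes}")
        for level, sub in sorted(strata.items()):
            for cls in VaccineClass:
                entries = top_k_pts(sub, 20, cls)
                if not entries:
                    continue
                frame = top_k_to_frame(entries)
                frame.to_csv(
                    OUT / f"top20_{factor}-{level}_{cls.value}.csv",
                    index=False,
                    float_format="%.10g",
                )
        if factor == "age_group":
            for cls in VaccineClass:
                head = top_k_pts(strata.get("G1", []), 3, cls)
                pretty = ", ".join(f"{pt} (n={n}, ROR {est:.2f})" for pt, n, est, _ in head)
                print(f"   G1 top PTs, {cls.value}: {pretty}")


if __name__ == "__main__":
    main()
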