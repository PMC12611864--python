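#!/usr/bin/env python
"""Multivariable logistic regression of death classification, per vaccine
class.

Covariates: age group (reference 6 weeks–<4 months), sex (reference male,
unknown-sex reports excluded), co-administration (reference vaccine alone).
The synthetic cohort plants protective age and female effects and a harmful
co-administration effect, so the fitted odds ratios should sit below 1 for
the age and female terms and above 1 for co-administration.
"""

from pathlib import Path

from aefi_signal.death_model import build_design, fit_logistic, fit_to_frame
from aefi_signal.records import VaccineClass
from aefi_signal.vaers_io import read_vaers_dir, select_cohort

OUT = Path("results/death_model")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = select_cohort(read_vaers_dir("scratch/synthetic"))

    for cls in VaccineClass:
        try:
            design = build_design(cohort, cls)
            fit = fit_logistic(design)
        except (ValueError, RuntimeError) as exc:
            print(f"{cls.value}: model not estimable ({exc})")
            continue
        frame = fit_to_frame(fit)
        frame.to_csv(OUT / f"death_model_{cls.value}.csv", index=False, float_format="%.10g")
        print(
            f"--- {cls.value}: n={fit.n_used} "
            f"(excluded unknown sex: {fit.n_excluded_unknown_sex}) ---"
        )
        for t in fit.terms:
            if t.term == "const":
                continue
            print(
                f"   {t.term:12s} OR {t.odds_ratio:6.3f} "
                f"(95% CI {t.ci_low:6.3f}-{t.ci_high:6.3f})  p={t.p_value:.4f}"
            )


if __name__ == "__main__":
    main()
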