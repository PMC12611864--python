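#!/usr/bin/env python
"""Generate the study cohort: a synthetic two-vaccine infant cohort in the
VAERS file dialect.

The generator uses the study conditions (3,259 pentavalent + 1,720 hexavalent
reports, infant age window, paper-style demographics) with planted relative
reporting rates that emulate the reported signal pattern: elevated
hexavalent reporting of respiratory, nervous-system, cardiac and vascular
events.  Outputs: the three VAERS-dialect CSVs plus the ground-truth sidecar
under scratch/synthetic/.
"""

from aefi_signal.pipeline import simulate_to_dir
from aefi_signal.synth import paperlike_config

OUT = "scratch/synthetic"
SEED = 20180101


def main() -> None:
    cfg = paperlike_config(seed=SEED)
    info = simulate_to_dir(cfg, OUT)
    print(f"wrote {info['n_reports']} reports ({cfg.n_penta} penta + {cfg.n_hexa} hexa)")
    for f in info["files"]:
        print("  ", f)
    planted = sorted(cfg.planted_rr.items(), key=lambda kv: -kv[1])
    print("planted relative reporting rates:")
    for (pt, cls), rr in planted:
        print(f"   {pt:40s} {cls:6s} x{rr}")


if __name__ == "__main__":
    main()
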