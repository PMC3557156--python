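#!/usr/bin/env python
"""Generate the study's synthetic data: two divergently selected lines.

One ancestral population per chromosome is split into a "fat" and a
"lean" line; on chromosome 12 the lines are pushed apart at a focal
variant (s = +/-0.1 for 45 generations), all other chromosomes drift
neutrally after the split.  Twenty-four 5 Mb chip-like chromosomes, 100 phased
haplotypes per line, written as .hap/.legend/.samples panels under
results/panels/ together with the realized ground truth.
"""

import json
import os
from dataclasses import asdict, replace

from sweepscan.panel import concat_panels, write_panel
from sweepscan.simulate import (SweepSimParams, SweepSpec,
                                make_two_line_panel)
from sweepscan.studies import derive_seed

SEED = 2014
N_CHROMS = 24
SWEEP_CHROM = "12"
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "panels")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    base = SweepSimParams(sweep=SweepSpec())
    fat_chroms, lean_chroms, truth = [], [], None
    for k in range(1, N_CHROMS + 1):
        name = str(k)
        selected = name == SWEEP_CHROM
        params = replace(
            base, chrom_name=name,
            sweep=base.sweep if selected
            else SweepSpec(selection_coefficient=0.0, start_frequency=0.3),
        )
        fat, lean, t = make_two_line_panel(params, derive_seed(SEED, k))
        fat_chroms.append(fat)
        lean_chroms.append(lean)
        if selected:
            truth = t
        print(f"chrom {name}: {fat.n_markers} markers"
              + (f", focal at {t.focal_pos} "
                 f"(fat {t.line_divergence['fat']:.2f} / "
                 f"lean {t.line_divergence['lean']:.2f})" if selected else ""))
    fat_panel = concat_panels(fat_chroms)
    lean_panel = concat_panels(lean_chroms)
    write_panel(fat_panel, os.path.join(OUT, "fat"))
    write_panel(lean_panel, os.path.join(OUT, "lean"))
    with open(os.path.join(OUT, "truth.json"), "w") as fh:
        json.dump({"sweep_chrom": SWEEP_CHROM, **asdict(truth)}, fh, indent=2)
    print(f"wrote {fat_panel.n_markers}-marker panels for both lines -> {OUT}")


if __name__ == "__main__":
    main()
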