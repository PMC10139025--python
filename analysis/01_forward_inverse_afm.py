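#!/usr/bin/env python
"""Forward-inverse check of the AFM pipeline on two reference lines.

Simulates single-cell stiffness populations configured from the softest
(TYKNU, 0.28 ± 0.12 kPa) and stiffest (OVCAR4, 1.13 ± 0.50 kPa) lines of
the packaged summary table, pushes every synthetic indentation curve
through baseline correction, contact detection, Hertz fitting and
per-cell aggregation, and compares the recovered grand means with the
generator truth. Writes results/percell_stiffness.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cellmech import forcecurve as fc
from cellmech.simgen import PopulationSpec, gen_population
from cellmech.stats_assoc import load_table1

OUT = Path(__file__).resolve().parents[1] / "results"
N_CELLS = 50  # desk-scale run; the acceptance script uses 100
SEED = 0


def main() -> int:
    OUT.mkdir(exist_ok=True)
    table1 = load_table1().set_index("line_id")
    frames = []
    for line in ("TYKNU", "OVCAR4"):
        row = table1.loc[line]
        spec = PopulationSpec(
            component_means=(float(row.mean_E_kPa),),
            component_sds=(float(row.sd_E_kPa),),
            n_cells=N_CELLS,
            curves_per_cell=5,
        )
        cells = gen_population(spec, seed=SEED)
        per_cell = fc.process_cells([(c.cell_id, c.curves) for c in cells])
        per_cell.insert(0, "line_id", line)
        frames.append(per_cell)
        grand = per_cell.E_kPa_mean.mean()
        truth = np.mean([c.true_modulus for c in cells])
        print(
            f"{line}: recovered grand mean {grand:.3f} kPa "
            f"(sample truth {truth:.3f}, nominal {row.mean_E_kPa}) "
            f"from {len(per_cell)}/{N_CELLS} cells"
        )
    pd.concat(frames).to_csv(OUT / "percell_stiffness.csv", index=False)
    print(f"wrote {OUT / 'percell_stiffness.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
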