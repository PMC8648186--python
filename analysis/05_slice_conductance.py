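#!/usr/bin/env python
"""Estimate synaptic conductances from the slice I-V table.

Fits I = g (Vm - E_rev) per cell (with the shared-reversal fallback where a
cell's own I-V is degenerate), summarizes conductance per mouse
(median / IQR), computes per-mouse connection probability on a simulated
cell census, and regresses conductance on collicular layer.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from escapekit import core_io as cio
from escapekit import slice_iv as sl
from escapekit.synth import generate_slice_population

ROOT = Path(__file__).resolve().parents[1]
SESSION = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ivs = cio.read_iv_table(SESSION / "iv_cells.csv")
    fits = sl.fit_population(ivs)
    table = pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "mouse_id": iv.mouse_id,
                "layer": iv.layer,
                "g_ns": f.g_ns,
                "e_reversal_mv": f.e_reversal_mv,
                "fit_method": f.fit_method,
            }
            for f, iv in zip(fits, ivs)
        ]
    )
    table.to_csv(RESULTS / "slice_conductance_fits.csv", index=False)
    print(f"{len(table)} cells fitted "
          f"({(table.fit_method == 'shared_reversal').sum()} via shared reversal)")
    print(f"conductance: median {table.g_ns.median():.2f} nS, "
          f"reversal median {table.e_reversal_mv.median():.1f} mV")

    by_mouse = sl.conductance_by_mouse(table)
    by_mouse.to_csv(RESULTS / "slice_conductance_by_mouse.csv", index=False)

    reg = sl.layer_conductance_regression(table)
    print(f"conductance vs layer: slope {reg['slope']:+.2f} nS/layer, p {reg['p_value']:.2g}")

    # connection probability on a simulated census (8 mice x 20 tested cells)
    cells = generate_slice_population(0.6, 8, 20, np.random.default_rng(1))
    prob = sl.connection_probability(cells)
    prob.to_csv(RESULTS / "slice_connection_probability.csv", index=False)
    print(
        f"connection probability (8 simulated mice, true 0.60): "
        f"mean {prob['connection_probability'].mean():.3f} "
        f"+/- {prob['connection_probability'].std(ddof=1) / np.sqrt(len(prob)):.3f} SEM"
    )


if __name__ == "__main__":
    main()
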