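#!/usr/bin/env python
"""Direction-contrast tuning of superficial excitatory neurons.

Aligns each center-responsive excitatory cell's 9 x 9 response matrix to its
preferred direction, averages population tuning curves per surround
relationship, and fits the with-surround curves against the center-alone
curve: the slope diagnoses divisive suppression (< 1, same-direction
surround) vs multiplicative potentiation (> 1, opposite surround), and rises
monotonically with the center-surround direction difference.  Center-silent
cells' emergent responses are summarized against the same direction
difference.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, ensure_dirs, load_trials, recording_path

import pandas as pd

import scmotion as sm

SEED = 77


def main() -> None:
    ensure_dirs()
    rec = sm.load_recording(recording_path("ssgs", "direction"))
    trials = load_trials("ssgs", "direction")
    result = sm.analyze_trials(trials, rec.protocol, cell_meta=rec.cell_meta, seed=SEED)
    cells = result.cells
    cells.to_csv(RESULTS / "cells_ssgs.csv", index=False)

    exc = cells[cells.cell_class == "excitatory"]
    mats = result.matrices_for((cells.cell_class == "excitatory") & cells.responsive_center)
    print(f"excitatory: {len(exc)} cells, {len(mats)} center-responsive, "
          f"{int((exc.center_silent).sum())} center-silent")

    curves = sm.population_curves(mats)
    curve_rows = []
    for name, df in curves.items():
        for rel_dir, row in df.iterrows():
            curve_rows.append({"curve": name, "relative_direction": rel_dir,
                               "mean_pct": 100 * row["mean"], "sem_pct": 100 * row["sem"]})
    pd.DataFrame(curve_rows).to_csv(RESULTS / "population_curves_exc.csv", index=False)

    fits = sm.slopes_vs_delta_theta(mats)
    fit_rows = []
    print("population modulation fits (with-surround vs center-alone):")
    for d, fit in fits.items():
        print(f"  dtheta={d:3d}: slope={fit.slope:.2f}  intercept={100 * fit.intercept:.2f} %dF/F0  "
              f"R^2={fit.r_squared:.2f}  slope 95% CI [{fit.slope_ci_95[0]:.2f}, {fit.slope_ci_95[1]:.2f}]")
        fit_rows.append({"delta_theta": d, "slope": fit.slope,
                         "intercept_pct": 100 * fit.intercept, "r_squared": fit.r_squared,
                         "slope_ci_lo": fit.slope_ci_95[0], "slope_ci_hi": fit.slope_ci_95[1]})
    pd.DataFrame(fit_rows).to_csv(RESULTS / "population_fits_exc.csv", index=False)

    per_cell = sm.per_cell_fits(mats)
    per_cell.to_csv(RESULTS / "per_cell_fits_exc.csv", index=False)
    passing = per_cell[per_cell.passes_filter]
    frac_pass = len(passing) / len(per_cell) if len(per_cell) else float("nan")
    print(f"per-cell linear fits: {frac_pass:.0%} pass R^2 >= 0.5; "
          f"mean filtered slopes by dtheta: "
          + ", ".join(f"{d:.0f}->{s:.2f}" for d, s in sm.mean_filtered_slopes(per_cell).items()))

    silent_mask = (cells.cell_class == "excitatory") & cells.center_silent & cells.aligned
    silent_mats = [result.matrices[i] for i in cells.loc[silent_mask, "cell_id"]]
    if silent_mats:
        curve, center_ref = sm.center_silent_curve(silent_mats)
        curve.assign(mean_pct=100 * curve["mean"]).to_csv(RESULTS / "center_silent_curve_exc.csv")
        print(f"center-silent emergent response ({len(silent_mats)} cells), %dF/F0 vs dtheta: "
              + ", ".join(f"{d}->{100 * v:.1f}" for d, v in curve["mean"].items())
              + f"; center-alone reference {100 * center_ref:.2f}")


if __name__ == "__main__":
    main()
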