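#!/usr/bin/env python
"""Excitatory vs inhibitory surround modulation.

Inhibitory neurons are suppressed by any surround and most strongly by the
opposite direction, the reverse of the excitatory potentiation.  This driver
compares modulation-index distributions between classes, tabulates the
four-way bootstrap categories (non-responsive / non-modulated / potentiated /
suppressed) for the preferred-center + opposite-surround comparison, and runs
the two control analyses for surround-alone-responsive inhibitory cells:
sub-linear summation (C-S response vs sum of components) and re-analysis
restricted to cells without a surround-alone response.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, ensure_dirs, load_trials, recording_path

import pandas as pd

import scmotion as sm

SEED = 78


def main() -> None:
    ensure_dirs()
    rec = sm.load_recording(recording_path("ssgs", "direction"))
    trials = load_trials("ssgs", "direction")
    result = sm.analyze_trials(trials, rec.protocol, cell_meta=rec.cell_meta, seed=SEED)
    cells = result.cells

    comp = sm.class_comparison(cells)
    pct = comp["category_percentages"]
    pct.to_csv(RESULTS / "category_percentages.csv")
    print("four-way categories, % of cells per class (opposite-surround bootstrap):")
    print(pct.round(1).to_string())
    print("between-class KS tests on modulation indices:")
    print(comp["tests"].round(4).to_string(index=False))

    for cls in ("excitatory", "inhibitory"):
        sub = cells[(cells.cell_class == cls) & cells.responsive]
        print(f"{cls}: median MI same={sub.mi_same.median():+.2f}  opposite={sub.mi_opp.median():+.2f}  "
              f"(n={len(sub)} responsive)")

    inh_center = (cells.cell_class == "inhibitory") & cells.responsive_center
    mats = result.matrices_for(inh_center)
    summation = sm.summation_comparison(mats)
    summary = summation.groupby("delta_theta")["mean_difference"].mean() * 100
    summation.to_csv(RESULTS / "summation_comparison_inh.csv", index=False)
    print("inhibitory summation: mean [R_CS - (R_C + R_S)] %dF/F0 by dtheta: "
          + ", ".join(f"{d}->{v:+.1f}" for d, v in summary.items()))

    no_sal = inh_center & ~cells.responsive_surround_alone
    fits = sm.slopes_vs_delta_theta(result.matrices_for(no_sal))
    print(f"inhibitory cells without surround-alone response (n={int(no_sal.sum())}): "
          f"slope at dtheta=0: {fits[0].slope:.2f}, at 180: {fits[180].slope:.2f} "
          "(suppression by any surround persists)")
    pd.DataFrame(
        [{"delta_theta": d, "slope": f.slope, "intercept_pct": 100 * f.intercept,
          "r_squared": f.r_squared} for d, f in fits.items()]
    ).to_csv(RESULTS / "population_fits_inh_no_surround_alone.csv", index=False)


if __name__ == "__main__":
    main()
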