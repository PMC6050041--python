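#!/usr/bin/env python
"""Receptive-field mapping: centroids, patch coverage, and per-class scatter.

Estimates RF centers from flashing-square responses by response-weighted
center of mass, asks whether each center falls within the 10-degree grating
patch, and compares the 2D scatter of centroids (RMS distance from the mean)
between inhibitory and excitatory cells per field of view.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, ensure_dirs, load_trials, recording_path

import numpy as np
import pandas as pd

import scmotion as sm
from scmotion.errors import NoRFError
from scmotion.receptive_field import rf_map_from_trials


def main() -> None:
    ensure_dirs()
    rec = sm.load_recording(recording_path("ssgs", "flash"))
    trials = load_trials("ssgs", "flash")
    meta = rec.cell_meta.set_index("cell_id")

    rows = []
    for cell_id, sub in trials.groupby("cell_id"):
        try:
            rf = rf_map_from_trials(sub, rec.protocol)
            x, y = rf.centroid()
        except NoRFError:
            rows.append({"cell_id": cell_id, "mappable": False, "x": np.nan, "y": np.nan,
                         "n_responsive": 0, "area_deg2": 0.0, "covered": False})
            continue
        rows.append({"cell_id": cell_id, "mappable": True, "x": x, "y": y,
                     "n_responsive": rf.n_responsive, "area_deg2": rf.area_deg2,
                     "covered": sm.is_rf_covered((x, y))})
    rf_table = pd.DataFrame(rows).merge(meta, on="cell_id")
    rf_table.to_csv(RESULTS / "rf_centroids.csv", index=False)

    mapped = rf_table[rf_table.mappable]
    print(f"mappable RFs: {len(mapped)}/{len(rf_table)} cells; "
          f"covered by the 10-degree patch: {mapped.covered.mean():.0%}")
    print(f"median RF area: {mapped.area_deg2.median():.0f} deg^2 "
          "(significant-square-count convention)")

    disp_rows = []
    for (fov, cls), grp in mapped.groupby(["fov_id", "cell_class"]):
        if len(grp) >= 2:
            disp = sm.centroid_dispersion(grp[["x", "y"]].to_numpy())
            disp_rows.append({"fov_id": fov, "cell_class": cls, "n": len(grp), "dispersion_deg": disp})
    disp = pd.DataFrame(disp_rows)
    disp.to_csv(RESULTS / "rf_dispersion.csv", index=False)
    med = disp.groupby("cell_class")["dispersion_deg"].median()
    print("median per-field-of-view centroid dispersion (deg): "
          + ", ".join(f"{c}={v:.1f}" for c, v in med.items()))


if __name__ == "__main__":
    main()
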