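#!/usr/bin/env python
"""Specificity to direction contrast vs other feature contrasts.

Compares surround modulation under direction contrast with anti-phase
(same-direction, 180 degrees out of phase), temporal-frequency (1 or 4 Hz
surround vs 2 Hz center), and static-orientation (iso vs cross) contrasts.
Direction contrast is the only one that drives strong bidirectional
modulation; the other contrasts merely attenuate suppression.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, ensure_dirs, load_trials, recording_path

import pandas as pd

import scmotion as sm

SEED = 79


def main() -> None:
    ensure_dirs()
    rec = sm.load_recording(recording_path("ssgs", "direction"))
    trials = load_trials("ssgs", "direction")
    result = sm.analyze_trials(trials, rec.protocol, cell_meta=rec.cell_meta, seed=SEED)
    d = result.cells.set_index("cell_id")
    pref = d.loc[d.responsive_center, "preferred_direction"]
    ref = d.loc[d.responsive_center, "r_pref_c"]

    frames = []
    for name in ("anti_phase", "temporal_freq", "static"):
        frec = sm.load_recording(recording_path("ssgs", name))
        ftrials = load_trials("ssgs", name)
        mi = sm.feature_contrast_mi(ftrials, frec.protocol, pref_dirs=pref, r_pref_c=ref)
        frames.append(mi)
    mi = pd.concat(frames, ignore_index=True)
    mi = mi.merge(d[["cell_class"]], left_on="cell_id", right_index=True)
    # direction-contrast references for the same cells
    for tag, col in (("same_direction", "mi_same"), ("opposite_direction", "mi_opp")):
        extra = d.loc[d.responsive_center, [col, "cell_class"]].rename(columns={col: "mi"})
        extra = extra.reset_index().assign(tag=tag)
        mi = pd.concat([mi, extra[["cell_id", "tag", "mi", "cell_class"]]], ignore_index=True)
    mi.to_csv(RESULTS / "feature_contrast_mi.csv", index=False)

    medians = mi.groupby(["cell_class", "tag"])["mi"].median().unstack()
    order = ["same_direction", "anti_phase", "tf_low", "tf_high",
             "static_iso", "static_cross", "opposite_direction"]
    medians = medians[[c for c in order if c in medians.columns]]
    print("median modulation index per surround type:")
    print(medians.round(3).to_string())
    print("\nonly the opposite-direction surround potentiates excitatory cells;")
    print("phase/TF/orientation contrasts merely attenuate suppression.")


if __name__ == "__main__":
    main()
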