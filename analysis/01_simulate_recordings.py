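#!/usr/bin/env python
"""Generate the synthetic imaging cohorts.

Two cohorts mirror the two preparations: a superficial (sSGS) mixed
excitatory/inhibitory population imaged with the fast dye through the
direction-contrast, feature-contrast, and flashing-square protocols; and a
depth-spanning population (10-205 um) imaged with the slow nuclear indicator
through the direction-contrast protocol.  Raw recordings (HDF5) go to
scratch/data; ground-truth parameter tables to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, RESULTS, ensure_dirs, recording_path

import scmotion as sm
from scmotion.io import ground_truth_frame

N_CELLS = 500
SEED = 2018


def main() -> None:
    ensure_dirs()

    ssgs_cfg = sm.GeneratorConfig()
    ssgs_cells = sm.sample_population(ssgs_cfg, N_CELLS, seed=SEED)
    sm.save_config(ssgs_cfg, DATA / "ssgs_config.yaml")
    ground_truth_frame(ssgs_cells).to_csv(RESULTS / "ground_truth_ssgs.csv", index=False)

    protocols = {
        "direction": sm.build_direction_contrast_protocol(8, 4, seed=SEED),
        "anti_phase": sm.build_feature_contrast_protocol("anti_phase", 4, seed=SEED + 1),
        "temporal_freq": sm.build_feature_contrast_protocol("temporal_freq", 4, seed=SEED + 2),
        "static": sm.build_feature_contrast_protocol("static_orientation", 4, seed=SEED + 3),
        "flash": sm.build_flash_grid_protocol(4, seed=SEED + 4),
    }
    for name, protocol in protocols.items():
        rec = sm.simulate_recording(protocol, ssgs_cells, seed=SEED + 10 + hash(name) % 100)
        sm.save_recording(rec, recording_path("ssgs", name))
        print(f"ssgs/{name}: {rec.n_cells} cells x {rec.n_frames} frames "
              f"({rec.duration_s / 60:.1f} min at {rec.frame_rate_hz} Hz)")

    depth_cfg = sm.depth_survey_config()
    depth_cells = sm.sample_population(depth_cfg, N_CELLS, seed=SEED + 200)
    sm.save_config(depth_cfg, DATA / "depth_config.yaml")
    ground_truth_frame(depth_cells).to_csv(RESULTS / "ground_truth_depth.csv", index=False)
    rec = sm.simulate_recording(protocols["direction"], depth_cells, seed=SEED + 201)
    sm.save_recording(rec, recording_path("depth", "direction"))
    print(f"depth/direction: {rec.n_cells} cells x {rec.n_frames} frames (slow nuclear indicator)")


if __name__ == "__main__":
    main()
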