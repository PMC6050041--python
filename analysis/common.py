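"""Shared paths and loaders for the numbered analysis drivers.

Simulated recordings (binary HDF5) live under ``scratch/``; derived tables
and summaries land in ``results/``.  Run the scripts in order: 01 writes the
raw cohorts, 02 extracts trial tables, 03-07 analyze them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
TRIALS = ROOT / "scratch" / "trials"
RESULTS = ROOT / "results"

SSGS_COHORT = "ssgs"        # superficial, fast dye, mixed classes
DEPTH_COHORT = "depth"      # 10-205 um, slow nuclear indicator


def ensure_dirs() -> None:
    for p in (DATA, TRIALS, RESULTS):
        p.mkdir(parents=True, exist_ok=True)


def recording_path(cohort: str, protocol: str) -> Path:
    return DATA / f"{cohort}_{protocol}.h5"


def trials_path(cohort: str, protocol: str) -> Path:
    return TRIALS / f"{cohort}_{protocol}.parquet"


def load_trials(cohort: str, protocol: str) -> pd.DataFrame:
    path = trials_path(cohort, protocol)
    if not path.exists():
        raise FileNotFoundError(f"{path} missing - run analysis/01 and 02 first")
    return pd.read_parquet(path)
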