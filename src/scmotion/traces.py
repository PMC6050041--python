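"""Trial-level dF/F0 extraction and the responsiveness gate.

dF/F0 = (F - F0) / F0, where F0 is the mean fluorescence over a fixed baseline
interval before stimulus onset and F the mean over an indicator-specific
response window.  Negative values are retained through averaging (clipping
happens only inside the modulation index).  A cell is "responsive" if its mean
dF/F0 exceeds twice the baseline standard deviation (expressed in dF/F0 units,
pooled across that cell's trials) for at least one stimulus condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    IntegrityError,
    InvalidParameterError,
    WindowError,
)
from .recording import Recording

RESPONSIVENESS_SD_FACTOR = 2.0


@dataclass(frozen=True)
class WindowSpec:
    """Baseline and response windows relative to stimulus onset/offset.

    The response window is [onset + response_start_offset_s,
    offset + response_end_offset_s); the baseline window is
    [onset - baseline_pre_s, onset).  A frame belongs to a window if its
    acquisition midpoint falls in the half-open interval.
    """

    baseline_pre_s: float
    response_start_offset_s: float
    response_end_offset_s: float
    stimulus_kind: str = "grating"
    indicator: str = "fast"

    def __post_init__(self) -> None:
        if self.baseline_pre_s <= 0:
            raise InvalidParameterError("baseline_pre_s must be positive")

    def response_window(self, onset_s: float, offset_s: float) -> tuple[float, float]:
        start = onset_s + self.response_start_offset_s
        end = offset_s + self.response_end_offset_s
        if end <= start:
            raise InvalidParameterError("response window duration must be positive")
        return start, end

    def baseline_window(self, onset_s: float) -> tuple[float, float]:
        return onset_s - self.baseline_pre_s, onset_s


_DEFAULTS = {
    # (stimulus_kind, indicator): (baseline_pre, start_offset, end_offset)
    ("grating", "fast"): (1.25, 0.25, 0.75),
    ("grating", "slow_nuclear"): (1.25, 0.625, 1.125),
    ("flash_square", "fast"): (0.75, 0.25, 0.35),
}


def default_windows(stimulus_kind: str, indicator: str) -> WindowSpec:
    """Published analysis windows per stimulus kind and indicator.

    Gratings, fast dye: 1.25 s baseline; response from 250 ms after onset to
    750 ms after offset (2.5 s for a 2 s stimulus).  Slow nuclear indicator:
    the same response window shifted forward by 375 ms.  Flashing squares,
    fast dye: 0.75 s baseline; response from 250 ms after onset to 350 ms
    after offset (1.1 s for a 1 s flash).
    """
    try:
        base, start, end = _DEFAULTS[(stimulus_kind, indicator)]
    except KeyError:
        raise InvalidParameterError(
            f"no default window for stimulus_kind={stimulus_kind!r}, indicator={indicator!r}"
        ) from None
    return WindowSpec(base, start, end, stimulus_kind=stimulus_kind, indicator=indicator)


def _window_frames(frame_times: np.ndarray, start: float, end: float) -> np.ndarray:
    return np.flatnonzero((frame_times >= start) & (frame_times < end))


def compute_dff(
    trace: np.ndarray,
    onset_s: float,
    offset_s: float,
    frame_rate_hz: float,
    window: WindowSpec,
) -> tuple[float, float, float]:
    """dF/F0 for one trial of one cell.

    Returns ``(dff, F0, baseline_sd)`` where ``baseline_sd`` is the SD of the
    baseline fluorescence samples (raw units).
    """
    trace = np.asarray(trace, dtype=float)
    t = (np.arange(trace.size) + 0.5) / frame_rate_hz
    b0, b1 = window.baseline_window(onset_s)
    r0, r1 = window.response_window(onset_s, offset_s)
    if b0 < 0 or r1 > trace.size / frame_rate_hz:
        raise WindowError("analysis window exceeds trace bounds")
    b_idx = _window_frames(t, b0, b1)
    r_idx = _window_frames(t, r0, r1)
    if b_idx.size < 2:
        raise WindowError("baseline interval must contain at least 2 frames")
    if r_idx.size < 1:
        raise WindowError("response interval contains no frames")
    f0 = float(trace[b_idx].mean())
    if f0 <= 0:
        raise DegenerateBaselineError("baseline fluorescence F0 must be positive")
    f = float(trace[r_idx].mean())
    return (f - f0) / f0, f0, float(trace[b_idx].std(ddof=0))


def build_response_table(recording: Recording, window: WindowSpec | None = None) -> pd.DataFrame:
    """One row of (cell, condition, repeat, dff, F0, baseline_sd) per trial.

    Frame masks are computed once per event and applied to every ROI, so the
    table is deterministic and losslessly groupable into response matrices.
    """
    from .simulate import condition_timing  # local import to avoid cycle

    if window is None:
        stim_kind = "flash_square" if getattr(recording.protocol, "protocol_kind", "") == "rf_mapping" else "grating"
        window = default_windows(stim_kind, recording.indicator)
    events = recording.events
    if events.empty:
        return pd.DataFrame(columns=["cell_id", "condition", "repeat", "dff", "F0", "baseline_sd"])
    counts = events.groupby("condition").size()
    if (counts != recording.protocol.n_repeats).any():
        raise IntegrityError("event log does not match protocol repeat structure")

    t = recording.frame_mid_times()
    traces = np.asarray(recording.traces, dtype=float)
    cell_ids = recording.cell_meta["cell_id"].to_numpy()
    rows: list[pd.DataFrame] = []
    for onset_s, cond, repeat in events[["onset_s", "condition", "repeat"]].itertuples(index=False):
        duration = condition_timing(recording.protocol, int(cond))[0]
        offset_s = onset_s + duration
        b0, b1 = window.baseline_window(onset_s)
        r0, r1 = window.response_window(onset_s, offset_s)
        if b0 < 0 or r1 > recording.duration_s:
            raise WindowError("analysis window exceeds trace bounds")
        b_idx = _window_frames(t, b0, b1)
        r_idx = _window_frames(t, r0, r1)
        if b_idx.size < 2 or r_idx.size < 1:
            raise WindowError("frame rate too low to resolve the analysis windows")
        f0 = traces[:, b_idx].mean(axis=1)
        if np.any(f0 <= 0):
            raise DegenerateBaselineError("baseline fluorescence F0 must be positive")
        f = traces[:, r_idx].mean(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids,
                    "condition": int(cond),
                    "repeat": int(repeat),
                    "dff": (f - f0) / f0,
                    "F0": f0,
                    "baseline_sd": traces[:, b_idx].std(axis=1, ddof=0),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["cell_id", "condition", "repeat"], ignore_index=True)


def assess_responsiveness(
    cell_trials: pd.DataFrame, sd_factor: float = RESPONSIVENESS_SD_FACTOR
) -> tuple[bool, pd.Series]:
    """Responsiveness of one cell: per-condition flags plus the overall verdict.

    A condition is flagged responsive when its mean dF/F0 across repeats
    exceeds ``sd_factor`` times the pooled baseline SD in dF/F0 units
    (rms over trials of baseline_sd / F0); the cell is responsive iff any
    condition is flagged.
    """
    if cell_trials.empty:
        raise InsufficientDataError("no trials provided")
    sd_dff = cell_trials["baseline_sd"] / cell_trials["F0"]
    pooled_sd = float(np.sqrt(np.mean(sd_dff**2)))
    cond_means = cell_trials.groupby("condition")["dff"].mean()
    flags = cond_means > sd_factor * pooled_sd
    return bool(flags.any()), flags


def responsiveness_table(trials: pd.DataFrame, sd_factor: float = RESPONSIVENESS_SD_FACTOR) -> pd.DataFrame:
    """Per-cell responsiveness flags for a full trial table.

    Returns one row per (cell_id, condition) with the flag, plus a per-cell
    ``responsive`` column broadcast onto every row.
    """
    parts = []
    for cell_id, sub in trials.groupby("cell_id"):
        responsive, flags = assess_responsiveness(sub, sd_factor)
        part = flags.rename("flag").reset_index()
        part.insert(0, "cell_id", cell_id)
        part["responsive"] = responsive
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
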