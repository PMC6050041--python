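"""Synthetic recording generation: response laws, indicator kinetics, traces.

The noiseless expected dF/F0 of a trial follows the cell's ground truth:

* center alone: von Mises direction tuning scaled by the peak response
  (zero for center-silent cells);
* center + surround (direction contrast): the affine modulation law
  ``R_CS = a(dtheta) * R_C + b(dtheta)`` with the folded center-surround
  direction difference; center-silent cells use an intercept-only emergent
  response whose mean over center directions equals b(dtheta);
* feature-contrast conditions: multiplicative class-specific gain factors;
* surround alone: nonzero only for surround-alone-responsive cells;
* flashing squares: a 2D Gaussian receptive-field profile.

Traces are ``baseline_F * (1 + dff(t) + noise)`` where dff(t) superposes, per
stimulus event, a boxcar of the stimulus duration convolved with a
double-exponential indicator kernel (fast: 50 ms rise / 600 ms decay;
slow nuclear: 400 ms / 3 s).  The kernel is normalized so the mean of the
noiseless response over the indicator's standard analysis window equals the
nominal amplitude, making the generator -> pipeline round trip an identity up
to frame quadrature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .population import CellGroundTruth, DELTA_THETAS
from .protocols import (
    ANTI_PHASE,
    DIRECTIONS,
    STATIC_ORIENTATION,
    TEMPORAL_FREQ,
    FlashGridProtocol,
    StimulusProtocol,
    folded_direction_difference,
)
from .recording import Recording
from .traces import default_windows

#: (rise tau, decay tau) in seconds per indicator.
INDICATOR_KINETICS = {"fast": (0.05, 0.6), "slow_nuclear": (0.4, 3.0)}


# ---------------------------------------------------------------------------
# response laws


def tuning_factor(delta_deg: np.ndarray | float, kappa: float) -> np.ndarray | float:
    """von Mises direction tuning, normalized to 1 at the preferred direction.

    kappa = 0 gives a flat (untuned) curve.
    """
    return np.exp(kappa * (np.cos(np.deg2rad(delta_deg)) - 1.0))


def _center_response(cell: CellGroundTruth, center_dir: float) -> float:
    return cell.peak_response * float(tuning_factor(center_dir - cell.preferred_direction, cell.tuning_concentration))


def _emergent_tuned_factor(cell: CellGroundTruth, center_dir: float) -> float:
    """Direction tuning of the center-silent emergent response, normalized so
    its mean over the 8 center directions is 1 (the law's intercept is then the
    direction-averaged response)."""
    deltas = np.asarray(DIRECTIONS, dtype=float) - cell.preferred_direction
    norm = float(np.mean(tuning_factor(deltas, cell.tuning_concentration)))
    return float(tuning_factor(center_dir - cell.preferred_direction, cell.tuning_concentration)) / norm


def _orientation_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _static_center_response(cell: CellGroundTruth, center_ori: float) -> float:
    pref_ori = cell.preferred_direction % 180.0
    d = _orientation_diff(center_ori, pref_ori)
    # orientation tuning with period 180 degrees
    factor = float(np.exp(cell.tuning_concentration * (np.cos(np.deg2rad(2 * d)) - 1.0)))
    return cell.static_gain * cell.peak_response * factor


def expected_dff(cell: CellGroundTruth, protocol: StimulusProtocol | FlashGridProtocol, condition: int) -> float:
    """Noiseless expected dF/F0 (window mean) for one cell and condition."""
    if isinstance(protocol, FlashGridProtocol):
        if not cell.has_mappable_rf:
            return 0.0
        base = cell.peak_response if cell.peak_response > 0 else max(
            (b for _, b in cell.modulation_law.values()), default=0.0
        )
        amp = cell.rf_gain * base
        pos = protocol.grid_positions()[condition]
        d2 = float((pos[0] - cell.rf_centroid[0]) ** 2 + (pos[1] - cell.rf_centroid[1]) ** 2)
        return amp * float(np.exp(-d2 / (2.0 * cell.rf_sigma_deg**2)))

    cond = protocol.conditions[condition]
    c, s = cond.center_direction, cond.surround_direction
    kind = cond.surround_kind

    if kind == STATIC_ORIENTATION:
        if c is None:
            return 0.0  # static surround alone drives no response
        rc = _static_center_response(cell, c)
        if s is None:
            return rc
        dori = _orientation_diff(c, s)
        tag = {0.0: "static_iso", 45.0: "static_mid", 90.0: "static_cross"}[dori]
        return cell.feature_contrast_factors[tag] * rc

    if kind in (ANTI_PHASE, TEMPORAL_FREQ):
        rc = _center_response(cell, c)
        if kind == ANTI_PHASE:
            tag = "anti_phase"
        else:
            tag = "tf_low" if (cond.surround_param or 0) <= 2.0 else "tf_high"
        return cell.feature_contrast_factors[tag] * rc

    # drifting direction-contrast conditions
    if c is None and s is None:
        return 0.0
    if s is None:
        return _center_response(cell, c)
    if c is None:
        if not cell.surround_alone_responsive:
            return 0.0
        return cell.surround_gain * cell.peak_response * float(
            tuning_factor(s - cell.preferred_direction, cell.tuning_concentration)
        )
    dtheta = int(round(folded_direction_difference(c, s)))
    a, b = cell.modulation_law[dtheta]
    if cell.center_silent:
        return b * _emergent_tuned_factor(cell, c)
    return a * _center_response(cell, c) + b


def expected_response_matrix(cell: CellGroundTruth, protocol: StimulusProtocol) -> np.ndarray:
    """Noiseless 9 x 9 expected-response matrix (center x surround, blank last)
    for a direction-contrast protocol; used as the generative oracle."""
    if protocol.protocol_kind != "direction_contrast":
        raise InvalidParameterError("expected_response_matrix requires a direction-contrast protocol")
    n = int(round(np.sqrt(protocol.n_conditions)))
    out = np.empty((n, n))
    for i in range(protocol.n_conditions):
        out[i // n, i % n] = expected_dff(cell, protocol, i)
    return out


# ---------------------------------------------------------------------------
# trace synthesis


def condition_timing(protocol: StimulusProtocol | FlashGridProtocol, condition: int) -> tuple[float, float]:
    """(duration_s, iti_s) of one condition."""
    if isinstance(protocol, FlashGridProtocol):
        return protocol.on_s, protocol.off_s
    cond = protocol.conditions[condition]
    return cond.duration_s, cond.iti_s


def _boxcar_kernel_response(t: np.ndarray, duration: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Boxcar of ``duration`` convolved with a causal double-exponential kernel
    (exp(-t/tau_decay) - exp(-t/tau_rise)), evaluated analytically."""

    def H(u: np.ndarray) -> np.ndarray:
        u = np.maximum(u, 0.0)
        return tau_decay * (1.0 - np.exp(-u / tau_decay)) - tau_rise * (1.0 - np.exp(-u / tau_rise))

    return H(t) - H(t - duration)


def _window_gain(indicator: str, duration: float, stimulus_kind: str) -> float:
    """Mean of the raw boxcar-kernel response over the indicator's standard
    response window (continuous quadrature)."""
    tau_rise, tau_decay = INDICATOR_KINETICS[indicator]
    w = default_windows(stimulus_kind, indicator)
    t = np.arange(w.response_start_offset_s, duration + w.response_end_offset_s, 1e-4)
    return float(_boxcar_kernel_response(t, duration, tau_rise, tau_decay).mean())


def response_peak_lag_s(indicator: str, duration: float = 2.0) -> float:
    """Time from stimulus onset to the peak of the noiseless response."""
    tau_rise, tau_decay = INDICATOR_KINETICS[indicator]
    t = np.arange(0.0, duration + 6 * tau_decay, 1e-3)
    r = _boxcar_kernel_response(t, duration, tau_rise, tau_decay)
    return float(t[np.argmax(r)])


def _validate_frame_rate(frame_rate_hz: float, stimulus_kind: str, indicator: str) -> None:
    w = default_windows(stimulus_kind, indicator)
    if frame_rate_hz * w.baseline_pre_s < 2 or frame_rate_hz * (w.response_end_offset_s - w.response_start_offset_s + 1.0) < 1:
        raise InvalidParameterError("frame rate too low to resolve the analysis windows")


def simulate_recording(
    protocol: StimulusProtocol | FlashGridProtocol,
    cells: list[CellGroundTruth],
    frame_rate_hz: float = 8.079,
    seed: int = 0,
    pre_s: float = 3.0,
    post_s: float = 6.0,
) -> Recording:
    """Synthesize a Recording: full fluorescence traces plus the event log.

    Deterministic given (protocol, cells, frame_rate_hz, seed).  All cells
    share the protocol's event timing; stimulus onsets follow one another at
    duration + ITI and are not frame-aligned, so window quadrature phases vary
    across trials as in a real acquisition.
    """
    if not cells:
        raise InvalidParameterError("cells must be non-empty")
    indicators = {c.indicator for c in cells}
    if len(indicators) > 1:
        raise InvalidParameterError("all cells in one recording must share an indicator")
    indicator = indicators.pop()
    if indicator not in INDICATOR_KINETICS:
        raise InvalidParameterError(f"unknown indicator {indicator!r}")
    stimulus_kind = "flash_square" if isinstance(protocol, FlashGridProtocol) else "grating"
    _validate_frame_rate(frame_rate_hz, stimulus_kind, indicator)
    tau_rise, tau_decay = INDICATOR_KINETICS[indicator]

    order = protocol.presentation_order
    onsets = np.empty(len(order))
    t_cursor = pre_s
    durations = np.empty(len(order))
    for k, (cond, _rep) in enumerate(order):
        d, iti = condition_timing(protocol, int(cond))
        onsets[k] = t_cursor
        durations[k] = d
        t_cursor += d + iti
    n_frames = int(np.ceil((onsets[-1] + durations[-1] + post_s) * frame_rate_hz))
    t_mid = (np.arange(n_frames) + 0.5) / frame_rate_hz

    # expected window-mean amplitude per (cell, condition)
    n_cond = protocol.n_conditions
    amp = np.array([[expected_dff(c, protocol, j) for j in range(n_cond)] for c in cells])
    gains = {d: _window_gain(indicator, d, stimulus_kind) for d in np.unique(durations)}

    dff = np.zeros((len(cells), n_frames))
    tail = 8.0 * tau_decay
    for k, (cond, _rep) in enumerate(order):
        d = durations[k]
        i0 = int(np.searchsorted(t_mid, onsets[k]))
        i1 = int(np.searchsorted(t_mid, onsets[k] + d + tail))
        if i0 == i1:
            continue
        shape = _boxcar_kernel_response(t_mid[i0:i1] - onsets[k], d, tau_rise, tau_decay) / gains[d]
        dff[:, i0:i1] += amp[:, int(cond)][:, None] * shape[None, :]

    rng = np.random.default_rng(seed)
    noise_sd = np.array([c.noise_sd for c in cells])[:, None]
    baseline = np.array([c.baseline_F for c in cells])[:, None]
    traces = baseline * (1.0 + dff + rng.normal(0.0, 1.0, dff.shape) * noise_sd)

    events = pd.DataFrame(
        {"onset_s": onsets, "condition": order[:, 0].astype(int), "repeat": order[:, 1].astype(int)}
    )
    cell_meta = pd.DataFrame(
        {
            "cell_id": np.arange(len(cells)),
            "cell_class": [c.cell_class for c in cells],
            "depth_um": [c.depth_um for c in cells],
            "fov_id": [c.fov_id for c in cells],
        }
    )
    return Recording(
        frame_rate_hz=frame_rate_hz,
        traces=traces,
        events=events,
        protocol=protocol,
        cell_meta=cell_meta,
        indicator=indicator,
        ground_truth=list(cells),
        seed=seed,
    )


def simulate_trial_table(
    protocol: StimulusProtocol | FlashGridProtocol,
    cells: list[CellGroundTruth],
    seed: int = 0,
    frame_rate_hz: float = 8.079,
) -> pd.DataFrame:
    """Trial-level shortcut: expected window-mean responses plus matched trial
    noise, without synthesizing traces.

    The per-trial noise SD equals the SD the window-mean estimator would have
    under the per-frame trace noise: noise_sd * sqrt(1/n_response_frames +
    1/n_baseline_frames).  Useful for population-scale studies where the trace
    -> dF/F0 round trip itself is not under test.
    """
    if not cells:
        raise InvalidParameterError("cells must be non-empty")
    indicator = cells[0].indicator
    stimulus_kind = "flash_square" if isinstance(protocol, FlashGridProtocol) else "grating"
    w = default_windows(stimulus_kind, indicator)
    d0 = condition_timing(protocol, 0)[0]
    n_base = max(int(round(w.baseline_pre_s * frame_rate_hz)), 2)
    n_resp = max(int(round((d0 + w.response_end_offset_s - w.response_start_offset_s) * frame_rate_hz)), 1)
    trial_sd_factor = np.sqrt(1.0 / n_resp + 1.0 / n_base)

    rng = np.random.default_rng(seed)
    n_cond = protocol.n_conditions
    amp = np.array([[expected_dff(c, protocol, j) for j in range(n_cond)] for c in cells])
    rows = []
    for cell_id, cell in enumerate(cells):
        sd = cell.noise_sd * trial_sd_factor
        for cond in range(n_cond):
            dff = amp[cell_id, cond] + rng.normal(0.0, sd, protocol.n_repeats)
            for rep in range(protocol.n_repeats):
                rows.append(
                    (cell_id, cond, rep, dff[rep], cell.baseline_F, cell.noise_sd * cell.baseline_F)
                )
    return pd.DataFrame(rows, columns=["cell_id", "condition", "repeat", "dff", "F0", "baseline_sd"])
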