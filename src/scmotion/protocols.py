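"""Stimulus protocols: condition sets, timing, and pseudo-random presentation order.

Conditions describe drifting-grating center-surround stimuli (and a flashing-square
receptive-field mapping grid) by label only; no pixel-level rendering is involved.
A direction-contrast set crosses 8 motion directions plus a blank for both center
and surround, giving 81 unique conditions; feature-contrast sets vary surround
phase, temporal frequency, or static orientation instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, InvalidParameterError

#: Motion directions used throughout (degrees, screen coordinates).
DIRECTIONS = tuple(range(0, 360, 45))
#: Static-grating orientations (degrees).
ORIENTATIONS = tuple(range(0, 180, 45))
#: Sentinel for a blank (gray) center or surround.
BLANK = None

GRATING_DURATION_S = 2.0
GRATING_ITI_S = 5.0

DRIFTING = "drifting"
ANTI_PHASE = "anti_phase"
TEMPORAL_FREQ = "temporal_freq"
STATIC_ORIENTATION = "static_orientation"

PROTOCOL_KINDS = (
    "direction_contrast",
    ANTI_PHASE,
    TEMPORAL_FREQ,
    STATIC_ORIENTATION,
    "rf_mapping",
)


@dataclass(frozen=True)
class StimulusCondition:
    """One labeled center-surround stimulus condition.

    ``center_direction`` / ``surround_direction`` are degrees (multiples of 45)
    or ``None`` for a blank (gray) component.  ``surround_param`` carries the
    surround temporal frequency in Hz for ``temporal_freq`` conditions (center
    fixed at 2 Hz), the phase offset in degrees for ``anti_phase``, and is
    unused otherwise.
    """

    center_direction: float | None
    surround_direction: float | None
    surround_kind: str = DRIFTING
    surround_param: float | None = None
    duration_s: float = GRATING_DURATION_S
    iti_s: float = GRATING_ITI_S

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.iti_s <= 0:
            raise InvalidParameterError("duration_s and iti_s must be positive")
        if self.surround_kind not in (DRIFTING, ANTI_PHASE, TEMPORAL_FREQ, STATIC_ORIENTATION):
            raise InvalidParameterError(f"unknown surround_kind {self.surround_kind!r}")
        for value in (self.center_direction, self.surround_direction):
            if value is not None and not 0.0 <= value < 360.0:
                raise InvalidParameterError(f"direction {value} outside [0, 360) degrees")
        if self.surround_kind == STATIC_ORIENTATION:
            for value in (self.center_direction, self.surround_direction):
                if value is not None and not 0 <= value <= 135:
                    raise InvalidParameterError("static orientations must lie in [0, 135] degrees")

    @property
    def is_all_gray(self) -> bool:
        return self.center_direction is None and self.surround_direction is None


@dataclass
class StimulusProtocol:
    """An ordered stimulus set: unique conditions plus a seeded presentation order.

    ``presentation_order`` is an (n_conditions * n_repeats, 2) integer array of
    (condition index, repeat index) pairs.  Conditions are permuted within each
    repeat block, mirroring the pseudo-random block design of the experiments.
    """

    conditions: list[StimulusCondition]
    n_repeats: int
    presentation_order: np.ndarray
    protocol_kind: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.protocol_kind not in PROTOCOL_KINDS:
            raise InvalidParameterError(f"unknown protocol_kind {self.protocol_kind!r}")
        if self.n_repeats < 1:
            raise InvalidParameterError("n_repeats must be >= 1")
        counts = np.bincount(self.presentation_order[:, 0], minlength=len(self.conditions))
        if not np.all(counts == self.n_repeats):
            raise IntegrityError("each condition must appear exactly n_repeats times")
        expected = {ANTI_PHASE: 8, TEMPORAL_FREQ: 16, STATIC_ORIENTATION: 25}.get(self.protocol_kind)
        if expected is not None and len(self.conditions) != expected:
            raise IntegrityError(
                f"{self.protocol_kind} protocol requires {expected} conditions, got {len(self.conditions)}"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def condition_table(self) -> pd.DataFrame:
        """Conditions as a DataFrame (NaN encodes a blank component)."""
        rows = [
            {
                "condition": i,
                "center_direction": np.nan if c.center_direction is None else c.center_direction,
                "surround_direction": np.nan if c.surround_direction is None else c.surround_direction,
                "surround_kind": c.surround_kind,
                "surround_param": np.nan if c.surround_param is None else c.surround_param,
                "duration_s": c.duration_s,
                "iti_s": c.iti_s,
            }
            for i, c in enumerate(self.conditions)
        ]
        return pd.DataFrame(rows).set_index("condition")


@dataclass
class FlashGridProtocol:
    """Flashing-square receptive-field mapping grid.

    A dark square of ``square_size_deg`` is flashed at each node of a
    ``grid_shape`` grid tiling ``extent_deg`` (centered on the origin of the
    stimulus patch), 1 s on / 3 s off, at least four repeats in pseudo-random
    order.  Grid positions are square centers, so they tile without overlap.
    """

    grid_shape: tuple[int, int] = (6, 6)
    square_size_deg: float = 5.0
    extent_deg: tuple[float, float] = (30.0, 30.0)
    on_s: float = 1.0
    off_s: float = 3.0
    n_repeats: int = 4
    presentation_order: np.ndarray = field(default=None)  # type: ignore[assignment]
    protocol_kind: str = "rf_mapping"
    seed: int | None = None

    def __post_init__(self) -> None:
        nx, ny = self.grid_shape
        if nx * self.square_size_deg > self.extent_deg[0] + 1e-9 or ny * self.square_size_deg > self.extent_deg[1] + 1e-9:
            raise InvalidParameterError("grid squares must tile the extent without overlap")
        if self.on_s <= 0 or self.off_s <= 0 or self.n_repeats < 1:
            raise InvalidParameterError("on_s, off_s must be positive and n_repeats >= 1")
        if self.presentation_order is None:
            self.presentation_order = _block_order(self.n_conditions, self.n_repeats, np.random.default_rng(self.seed))

    @property
    def n_conditions(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def grid_positions(self) -> np.ndarray:
        """(n_locations, 2) array of square-center positions in degrees."""
        nx, ny = self.grid_shape
        xs = (np.arange(nx) - (nx - 1) / 2) * self.square_size_deg
        ys = (np.arange(ny) - (ny - 1) / 2) * self.square_size_deg
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def _block_order(n_conditions: int, n_repeats: int, rng: np.random.Generator) -> np.ndarray:
    """Permute conditions within each repeat block."""
    blocks = []
    for repeat in range(n_repeats):
        perm = rng.permutation(n_conditions)
        blocks.append(np.column_stack([perm, np.full(n_conditions, repeat)]))
    return np.concatenate(blocks).astype(np.int64)


def build_direction_contrast_protocol(
    n_directions: int = 8, n_repeats: int = 4, seed: int = 0
) -> StimulusProtocol:
    """Full direction-contrast set: (n_directions + 1)^2 unique conditions.

    Includes the center-alone row (blank surround), the surround-alone column
    (blank center), and the all-gray condition.  With the default 8 directions
    this is the 81-condition (9 x 9) design.
    """
    if n_directions < 1 or n_repeats < 1:
        raise InvalidParameterError("n_directions and n_repeats must be >= 1")
    step = 360.0 / n_directions
    dirs: list[float | None] = [i * step for i in range(n_directions)]
    dirs.append(BLANK)
    conditions = [
        StimulusCondition(center_direction=c, surround_direction=s)
        for c in dirs
        for s in dirs
    ]
    order = _block_order(len(conditions), n_repeats, np.random.default_rng(seed))
    return StimulusProtocol(conditions, n_repeats, order, "direction_contrast", seed=seed)


def build_feature_contrast_protocol(kind: str, n_repeats: int = 4, seed: int = 0) -> StimulusProtocol:
    """Feature-contrast condition sets.

    ``anti_phase``: 8 conditions (each direction paired with a same-direction,
    180-degree out-of-phase surround).  ``temporal_freq``: 16 conditions (each
    direction paired with a 1 Hz or 4 Hz same-direction surround; center fixed
    at 2 Hz).  ``static_orientation``: 25 conditions (4 orientations + blank
    crossed for center and surround).
    """
    if n_repeats < 1:
        raise InvalidParameterError("n_repeats must be >= 1")
    if kind == ANTI_PHASE:
        conditions = [
            StimulusCondition(d, d, surround_kind=ANTI_PHASE, surround_param=180.0)
            for d in DIRECTIONS
        ]
    elif kind == TEMPORAL_FREQ:
        conditions = [
            StimulusCondition(d, d, surround_kind=TEMPORAL_FREQ, surround_param=tf)
            for tf in (1.0, 4.0)
            for d in DIRECTIONS
        ]
    elif kind == STATIC_ORIENTATION:
        oris: list[float | None] = list(map(float, ORIENTATIONS)) + [BLANK]
        conditions = [
            StimulusCondition(c, s, surround_kind=STATIC_ORIENTATION)
            for c in oris
            for s in oris
        ]
    else:
        raise InvalidParameterError(f"unknown feature-contrast kind {kind!r}")
    order = _block_order(len(conditions), n_repeats, np.random.default_rng(seed))
    return StimulusProtocol(conditions, n_repeats, order, kind, seed=seed)


def build_flash_grid_protocol(n_repeats: int = 4, seed: int = 0) -> FlashGridProtocol:
    """Default 6 x 6, 5-degree flashing-square mapping grid."""
    if n_repeats < 1:
        raise InvalidParameterError("n_repeats must be >= 1")
    return FlashGridProtocol(n_repeats=n_repeats, seed=seed)


def folded_direction_difference(theta_c: float, theta_s: float) -> float:
    """Folded center-surround direction difference in [0, 180] degrees.

    Clockwise and counterclockwise offsets are treated alike:
    min(|dc - ds|, 360 - |dc - ds|).
    """
    d = abs(theta_c - theta_s) % 360.0
    return min(d, 360.0 - d)
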