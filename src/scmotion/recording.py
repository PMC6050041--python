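"""The ``Recording`` container: traces + event log + cell metadata.

This is the pipeline's sole input: everything downstream (trial tables,
response matrices, tuning and modulation statistics) is computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .population import CellGroundTruth
from .protocols import FlashGridProtocol, StimulusProtocol


@dataclass
class Recording:
    """Per-ROI fluorescence traces with a stimulus event log.

    ``traces`` is (n_cells, n_frames) raw fluorescence; ``events`` has one row
    per stimulus presentation with columns ``onset_s``, ``condition`` and
    ``repeat``; ``cell_meta`` has one row per ROI (``cell_id``, ``cell_class``,
    ``depth_um``, ``fov_id``).  ``ground_truth`` is retained for synthetic
    recordings and is never consulted by the analysis stages.
    """

    frame_rate_hz: float
    traces: np.ndarray
    events: pd.DataFrame
    protocol: StimulusProtocol | FlashGridProtocol
    cell_meta: pd.DataFrame
    indicator: str = "fast"
    ground_truth: list[CellGroundTruth] | None = field(default=None, repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        n_cond = self.protocol.n_conditions
        cond = np.asarray(self.events["condition"])
        if cond.size and (cond.min() < 0 or cond.max() >= n_cond):
            raise IntegrityError("event condition index outside protocol range")
        if len(self.cell_meta) != self.traces.shape[0]:
            raise IntegrityError("cell_meta rows must match trace count")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_mid_times(self) -> np.ndarray:
        """Acquisition midpoint of each frame, seconds."""
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate_hz
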