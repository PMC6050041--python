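"""Receptive-field estimation from flashing-square grid responses.

The RF center is the response-weighted center of mass over the grid locations
where the cell passed the responsiveness criterion; coverage asks whether the
centroid falls within the grating patch; centroid dispersion summarizes the
2D scatter of RF centers within one imaging field of view as the
root-mean-squared distance from the mean centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NoRFError
from .protocols import FlashGridProtocol
from .traces import RESPONSIVENESS_SD_FACTOR, assess_responsiveness


@dataclass
class RFMap:
    """Grid responses and the derived RF center for one cell."""

    grid_responses: np.ndarray   # mean dF/F0 per grid location
    grid_positions: np.ndarray   # (n, 2) degrees
    responsive_mask: np.ndarray  # per-location responsiveness flags
    cell_id: int = -1

    @property
    def n_responsive(self) -> int:
        return int(np.count_nonzero(self.responsive_mask))

    @property
    def area_deg2(self) -> float:
        """RF size convention: number of significant squares x square area.
        (A package convention: 25 deg^2 per 5-degree square.)"""
        return self.n_responsive * 25.0

    def centroid(self) -> tuple[float, float]:
        return compute_rf_center(self.grid_responses, self.grid_positions, self.responsive_mask)


def compute_rf_center(
    grid_responses: np.ndarray, grid_positions: np.ndarray, responsive_mask: np.ndarray
) -> tuple[float, float]:
    """Center of mass sum(R_i r_i) / sum(R_i) over responsive grid locations.

    Non-responsive locations are excluded; with no responsive location the
    cell is unmappable and the no-RF signal is raised.
    """
    mask = np.asarray(responsive_mask, dtype=bool)
    if not mask.any():
        raise NoRFError("no responsive grid location; cell is unmappable")
    r = np.maximum(np.asarray(grid_responses, dtype=float)[mask], 0.0)
    pos = np.asarray(grid_positions, dtype=float)[mask]
    total = r.sum()
    if total <= 0:
        raise NoRFError("responsive locations have no positive response mass")
    center = (r[:, None] * pos).sum(axis=0) / total
    return float(center[0]), float(center[1])


def rf_map_from_trials(
    cell_trials: pd.DataFrame,
    protocol: FlashGridProtocol,
    sd_factor: float = RESPONSIVENESS_SD_FACTOR,
) -> RFMap:
    """Build an RFMap from one cell's flash-grid trial table, applying the
    same 2-SD responsiveness criterion per grid location."""
    _, flags = assess_responsiveness(cell_trials, sd_factor)
    n = protocol.n_conditions
    responses = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    means = cell_trials.groupby("condition")["dff"].mean()
    responses[means.index.to_numpy()] = means.to_numpy()
    mask[flags.index.to_numpy()] = flags.to_numpy()
    cell_id = int(cell_trials["cell_id"].iloc[0])
    return RFMap(responses, protocol.grid_positions(), mask, cell_id=cell_id)


def is_rf_covered(
    centroid: tuple[float, float],
    patch_center: tuple[float, float] = (0.0, 0.0),
    patch_radius_deg: float = 10.0,
) -> bool:
    """True iff the RF centroid lies within the grating patch (boundary
    inclusive at exactly the patch radius)."""
    d = np.hypot(centroid[0] - patch_center[0], centroid[1] - patch_center[1])
    return bool(d <= patch_radius_deg)


def centroid_dispersion(centroids: np.ndarray) -> float:
    """2D standard deviation of RF centroids within one field of view:
    sqrt(mean squared Euclidean distance from the mean centroid)."""
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2:
        raise InsufficientDataError("dispersion requires at least 2 centroids")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
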