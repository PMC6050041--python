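"""Center-surround response matrices and the divisive/multiplicative fits.

The 81-condition design is summarized per cell as a 9 x 9 matrix of mean
dF/F0 indexed by (center direction incl. blank, surround direction incl.
blank).  Matrices are circularly shifted so each cell's preferred center
direction sits at relative direction 0, then averaged into population tuning
curves per center-surround relationship (center alone, same-direction
surround, opposite surround, each intermediate direction difference).  A
straight line fitted to the with-surround curve against the center-alone
curve diagnoses the modulation geometry: slope < 1 with ~zero intercept is
divisive suppression, slope > 1 multiplicative potentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateFitError,
    IncompleteMatrixError,
    InsufficientDataError,
    InvalidParameterError,
)
from .protocols import StimulusProtocol, folded_direction_difference

DTHETA_VALUES = (0, 45, 90, 135, 180)


@dataclass
class ResponseMatrix:
    """Per-cell condition-mean matrix with per-trial values retained.

    ``values`` is (n+1, n+1) with direction indices 0..n-1 and the blank
    component last; ``trials`` is (n+1, n+1, n_repeats).
    """

    cell_id: int
    values: np.ndarray
    trials: np.ndarray
    directions: tuple[float, ...]
    aligned: bool = False
    alignment_shift: int = 0

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def center_alone(self) -> np.ndarray:
        """Mean response per center direction with a blank surround."""
        return self.values[: self.n_directions, self.n_directions]

    def surround_alone(self) -> np.ndarray:
        return self.values[self.n_directions, : self.n_directions]

    def cs_curve(self, dtheta: int) -> np.ndarray:
        """With-surround tuning curve at one folded direction difference.

        Intermediate differences (45/90/135) average the clockwise and
        counterclockwise off-diagonals.
        """
        n = self.n_directions
        k = int(round(dtheta / (360.0 / n)))
        block = self.values[:n, :n]
        idx = np.arange(n)
        fwd = block[idx, (idx + k) % n]
        if k % (n // 2) == 0:  # same direction or exact opposite: single diagonal
            return fwd
        bwd = block[idx, (idx - k) % n]
        return 0.5 * (fwd + bwd)


def build_matrix(cell_trials: pd.DataFrame, protocol: StimulusProtocol) -> ResponseMatrix:
    """Group one cell's trials into the (center x surround) response matrix."""
    if protocol.protocol_kind != "direction_contrast":
        raise InvalidParameterError("build_matrix requires a direction-contrast protocol")
    table = protocol.condition_table()
    dirs = sorted(set(table["center_direction"].dropna()))
    n = len(dirs)
    pos = {d: i for i, d in enumerate(dirs)}

    def axis_index(v: float) -> int:
        return n if np.isnan(v) else pos[v]

    present = set(cell_trials["condition"].unique())
    missing = set(table.index) - present
    if missing:
        raise IncompleteMatrixError(f"{len(missing)} conditions have no trials")
    n_rep = int(cell_trials.groupby("condition").size().max())
    values = np.full((n + 1, n + 1), np.nan)
    trials = np.full((n + 1, n + 1, n_rep), np.nan)
    for cond, sub in cell_trials.groupby("condition"):
        ci = axis_index(table.loc[cond, "center_direction"])
        si = axis_index(table.loc[cond, "surround_direction"])
        dff = sub.sort_values("repeat")["dff"].to_numpy()
        values[ci, si] = dff.mean()
        trials[ci, si, : dff.size] = dff
    cell_id = int(cell_trials["cell_id"].iloc[0])
    return ResponseMatrix(cell_id, values, trials, tuple(float(d) for d in dirs))


def align_matrix(matrix: ResponseMatrix, preferred_direction: float) -> ResponseMatrix:
    """Circularly shift both direction axes so the preferred center direction
    lands at relative direction 0; the blank row/column stays fixed.

    No-op on an already-aligned matrix (alignment is idempotent); the multiset
    of entries is conserved.
    """
    if matrix.aligned:
        return replace(matrix)
    n = matrix.n_directions
    step = 360.0 / n
    shift = int(round((preferred_direction % 360.0) / step)) % n
    idx = np.concatenate([(np.arange(n) + shift) % n, [n]])
    return ResponseMatrix(
        cell_id=matrix.cell_id,
        values=matrix.values[np.ix_(idx, idx)],
        trials=matrix.trials[np.ix_(idx, idx)],
        directions=matrix.directions,
        aligned=True,
        alignment_shift=shift,
    )


def population_curves(
    matrices: list[ResponseMatrix], normalize: bool = False
) -> dict[str, pd.DataFrame]:
    """Mean +/- s.e.m. tuning curves across aligned cells.

    Keys: ``center_alone``, ``same`` (direction difference 0), ``opposite``
    (180), and ``dtheta_45/90/135``.  Index is the center direction relative
    to preferred.  With ``normalize`` each cell's curves are divided by its
    peak center-alone response before averaging (off by default; raw-unit
    fits and normalized fits lead to the same conclusions).
    """
    if len(matrices) < 2:
        raise InsufficientDataError("population curves require at least 2 cells")
    n = matrices[0].n_directions
    rel_dirs = np.arange(n) * (360.0 / n)
    scales = np.ones(len(matrices))
    if normalize:
        scales = np.array([max(m.center_alone().max(), 1e-12) for m in matrices])

    def stack(getter) -> pd.DataFrame:
        arr = np.stack([getter(m) / s for m, s in zip(matrices, scales)])
        return pd.DataFrame(
            {"mean": arr.mean(axis=0), "sem": arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])},
            index=pd.Index(rel_dirs, name="relative_direction"),
        )

    out = {"center_alone": stack(lambda m: m.center_alone())}
    names = {0: "same", 45: "dtheta_45", 90: "dtheta_90", 135: "dtheta_135", 180: "opposite"}
    for d, name in names.items():
        out[name] = stack(lambda m, d=d: m.cs_curve(d))
    return out


@dataclass(frozen=True)
class PopulationFit:
    """OLS fit of a with-surround curve against the center-alone curve."""

    condition: int | str  # direction difference in degrees, or a feature tag
    slope: float
    intercept: float
    r_squared: float
    slope_ci_95: tuple[float, float]
    n_points: int


def fit_modulation(
    center_alone_curve: np.ndarray, cs_curve: np.ndarray, condition: int | str = ""
) -> PopulationFit:
    """Ordinary least squares of the with-surround responses on the
    center-alone responses (one point per center direction), with a t-based
    95% confidence interval on the slope."""
    x = np.asarray(center_alone_curve, dtype=float)
    y = np.asarray(cs_curve, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidParameterError("curves must be equal-length with at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("center-alone curve has zero variance")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return PopulationFit(
        condition=condition,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci_95=(float(ci[0]), float(ci[1])),
        n_points=int(x.size),
    )


def slopes_vs_delta_theta(
    matrices: list[ResponseMatrix], normalize: bool = False
) -> dict[int, PopulationFit]:
    """Population modulation fit at each folded direction difference."""
    curves = population_curves(matrices, normalize=normalize)
    center = curves["center_alone"]["mean"].to_numpy()
    names = {0: "same", 45: "dtheta_45", 90: "dtheta_90", 135: "dtheta_135", 180: "opposite"}
    return {
        d: fit_modulation(center, curves[name]["mean"].to_numpy(), condition=d)
        for d, name in names.items()
    }


def per_cell_fits(matrices: list[ResponseMatrix], r2_min: float = 0.5) -> pd.DataFrame:
    """Per-cell linear modulation fits at every direction difference.

    Cells whose center-alone curve has zero variance are flagged
    (``degenerate`` = True) rather than dropped; ``passes_filter`` applies the
    R^2 >= ``r2_min`` quality gate used for per-cell summaries.
    """
    rows = []
    for m in matrices:
        x = m.center_alone()
        degenerate = np.ptp(x) == 0
        for d in DTHETA_VALUES:
            if degenerate:
                rows.append((m.cell_id, d, np.nan, np.nan, np.nan, False, True))
                continue
            fit = fit_modulation(x, m.cs_curve(d), condition=d)
            rows.append(
                (m.cell_id, d, fit.slope, fit.intercept, fit.r_squared, fit.r_squared >= r2_min, False)
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "delta_theta", "slope", "intercept", "r_squared", "passes_filter", "degenerate"],
    )


def mean_filtered_slopes(fits: pd.DataFrame) -> pd.Series:
    """Mean per-cell slope per direction difference over filter-passing fits."""
    ok = fits[fits["passes_filter"]]
    return ok.groupby("delta_theta")["slope"].mean()


def _dtheta_pairs(n: int) -> dict[int, list[tuple[int, int]]]:
    step = 360.0 / n
    out: dict[int, list[tuple[int, int]]] = {d: [] for d in DTHETA_VALUES}
    for ci in range(n):
        for si in range(n):
            d = int(round(folded_direction_difference(ci * step, si * step)))
            out[d].append((ci, si))
    return out


def center_silent_curve(matrices: list[ResponseMatrix]) -> tuple[pd.DataFrame, float]:
    """Mean emergent response vs direction difference for center-silent cells.

    Averages, per cell, every center-surround combination sharing a folded
    direction difference, then across cells.  Returns the curve and the mean
    center-alone reference level (expected ~0 for center-silent cells).
    """
    if not matrices:
        raise InsufficientDataError("need at least one center-silent cell")
    n = matrices[0].n_directions
    pairs = _dtheta_pairs(n)
    per_cell = np.array(
        [[np.mean([m.values[ci, si] for ci, si in pairs[d]]) for d in DTHETA_VALUES] for m in matrices]
    )
    curve = pd.DataFrame(
        {
            "mean": per_cell.mean(axis=0),
            "sem": per_cell.std(axis=0, ddof=1) / np.sqrt(per_cell.shape[0]) if per_cell.shape[0] > 1 else np.nan,
        },
        index=pd.Index(DTHETA_VALUES, name="delta_theta"),
    )
    center_ref = float(np.mean([m.center_alone().mean() for m in matrices]))
    return curve, center_ref


def summation_comparison(matrices: list[ResponseMatrix]) -> pd.DataFrame:
    """Compare each C-S response with the sum of the component responses.

    For every true center-surround combination, difference = R_CS -
    (R_center_alone + R_surround_alone); returns per-cell means per folded
    direction difference (negative = sub-linear summation).
    """
    if not matrices:
        raise InsufficientDataError("need at least one cell")
    n = matrices[0].n_directions
    pairs = _dtheta_pairs(n)
    rows = []
    for m in matrices:
        center = m.center_alone()
        surround = m.surround_alone()
        for d in DTHETA_VALUES:
            diffs = [m.values[ci, si] - (center[ci] + surround[si]) for ci, si in pairs[d]]
            rows.append((m.cell_id, d, float(np.mean(diffs))))
    return pd.DataFrame(rows, columns=["cell_id", "delta_theta", "mean_difference"])


def feature_contrast_mi(
    trials: pd.DataFrame,
    protocol: StimulusProtocol,
    pref_dirs: pd.Series | None = None,
    r_pref_c: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cell modulation indices for feature-contrast protocols.

    For anti-phase and temporal-frequency sets, the preferred direction and
    the center-alone reference response come from the direction-contrast
    session (``pref_dirs``, ``r_pref_c`` indexed by cell_id).  The static-
    orientation set is self-contained: the preferred orientation and the
    center-alone reference are taken from its own blank-surround conditions,
    and the iso- (0 deg) and cross-oriented (90 deg) surrounds are compared.
    """
    from .tuning import modulation_index

    kind = protocol.protocol_kind
    table = protocol.condition_table()
    means = trials.groupby(["cell_id", "condition"])["dff"].mean().unstack()
    rows = []
    if kind == "static_orientation":
        oris = sorted(set(table["center_direction"].dropna()))
        center_alone_conds: dict[float, int] = {}
        cs_conds: dict[tuple[float, float], int] = {}
        for i, crow in table.iterrows():
            c, s = crow["center_direction"], crow["surround_direction"]
            if np.isnan(c):
                continue
            if np.isnan(s):
                center_alone_conds[c] = int(i)
            else:
                cs_conds[(c, s)] = int(i)
        for cell_id, row in means.iterrows():
            alone = np.array([row[center_alone_conds[o]] for o in oris])
            pref = oris[int(np.argmax(alone))]
            ref = float(row[center_alone_conds[pref]])
            iso = float(row[cs_conds[(pref, pref)]])
            cross = float(row[cs_conds[(pref, (pref + 90.0) % 180.0)]])
            rows.append((cell_id, "static_iso", modulation_index(iso, ref)))
            rows.append((cell_id, "static_cross", modulation_index(cross, ref)))
    elif kind in ("anti_phase", "temporal_freq"):
        if pref_dirs is None or r_pref_c is None:
            raise InvalidParameterError("drifting feature contrasts need pref_dirs and r_pref_c")
        for cell_id, row in means.iterrows():
            if cell_id not in pref_dirs.index or pd.isna(pref_dirs.loc[cell_id]):
                continue
            pref = float(pref_dirs.loc[cell_id])
            ref = float(r_pref_c.loc[cell_id])
            for cond, crow in table.iterrows():
                if crow["center_direction"] != pref:
                    continue
                if kind == "anti_phase":
                    tag = "anti_phase"
                else:
                    tag = "tf_low" if crow["surround_param"] <= 2.0 else "tf_high"
                rows.append((cell_id, tag, modulation_index(float(row[cond]), ref)))
    else:
        raise InvalidParameterError(f"not a feature-contrast protocol: {kind!r}")
    return pd.DataFrame(rows, columns=["cell_id", "tag", "mi"])
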