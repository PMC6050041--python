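"""End-to-end analysis of one direction-contrast recording.

Chains trial extraction, the responsiveness gate, response-matrix assembly,
preferred-direction assignment (including the center-silent rule), gDSI,
same/opposite-surround modulation indices, and the bootstrap classification
into a per-cell results table plus aligned matrices for population analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoPreferenceError
from .recording import Recording
from .surround import ResponseMatrix, align_matrix, build_matrix
from .traces import WindowSpec, assess_responsiveness, build_response_table, default_windows
from .tuning import (
    NON_RESPONSIVE,
    bootstrap_classify_batch,
    categorize_cell,
    compute_gdsi,
    preferred_direction,
)


@dataclass
class AnalysisResult:
    """Per-cell results plus the intermediate objects population stages need."""

    cells: pd.DataFrame
    matrices: dict[int, ResponseMatrix] = field(repr=False, default_factory=dict)
    trials: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def matrices_for(self, mask: pd.Series) -> list[ResponseMatrix]:
        """Aligned matrices of the cells selected by a boolean mask on
        ``cells`` (cells without a defined preference are skipped)."""
        ids = self.cells.loc[mask & self.cells["aligned"], "cell_id"]
        return [self.matrices[i] for i in ids]


def analyze_recording(
    recording: Recording,
    window: WindowSpec | None = None,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> AnalysisResult:
    """Run the full single-session analysis on a Recording.

    Returns a table with one row per cell: responsiveness flags, preferred
    direction and its source, gDSI (center-responsive cells only), the
    same/opposite-surround modulation indices and bootstrap classes, and the
    four-way response category for the opposite-surround comparison.
    """
    if window is None:
        window = default_windows("grating", recording.indicator)
    trials = build_response_table(recording, window)
    return analyze_trials(
        trials, recording.protocol, cell_meta=recording.cell_meta, n_boot=n_boot, alpha=alpha, seed=seed
    )


def analyze_trials(
    trials: pd.DataFrame,
    protocol,
    cell_meta: pd.DataFrame | None = None,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> AnalysisResult:
    """Single-session analysis starting from an extracted trial table."""
    table = protocol.condition_table()
    center_conds = table.index[
        table["center_direction"].notna() & table["surround_direction"].isna()
    ].to_numpy()
    cs_conds = table.index[
        table["center_direction"].notna() & table["surround_direction"].notna()
    ].to_numpy()
    n_dirs = int(table["center_direction"].nunique())
    step = 360.0 / n_dirs

    rows = []
    matrices: dict[int, ResponseMatrix] = {}
    boot_pairs: list[tuple[int, str, np.ndarray, np.ndarray]] = []
    for cell_id, sub in trials.groupby("cell_id"):
        responsive, flags = assess_responsiveness(sub)
        responsive_center = bool(flags.reindex(center_conds, fill_value=False).any())
        responsive_cs = bool(flags.reindex(cs_conds, fill_value=False).any())
        responsive_surround_alone = bool(
            flags.reindex(
                table.index[table["center_direction"].isna() & table["surround_direction"].notna()],
                fill_value=False,
            ).any()
        )
        center_silent = responsive_cs and not responsive_center
        matrix = build_matrix(sub, protocol)

        row = {
            "cell_id": cell_id,
            "responsive": responsive,
            "responsive_center": responsive_center,
            "responsive_cs": responsive_cs,
            "responsive_surround_alone": responsive_surround_alone,
            "center_silent": center_silent,
            "preferred_direction": np.nan,
            "preferred_source": "",
            "gdsi": np.nan,
            "r_pref_c": np.nan,
            "r_pref_same": np.nan,
            "r_pref_opp": np.nan,
            "mi_same": np.nan,
            "mi_opp": np.nan,
            "aligned": False,
        }
        if responsive_center:
            row["gdsi"] = compute_gdsi(matrix.center_alone(), np.asarray(matrix.directions))
        try:
            pref, source = preferred_direction(matrix.values, responsive_center)
        except NoPreferenceError:
            matrices[cell_id] = matrix
            rows.append(row)
            continue
        p = int(round(pref / step)) % n_dirs
        opp = (p + n_dirs // 2) % n_dirs
        from .tuning import modulation_index

        row.update(
            {
                "preferred_direction": pref,
                "preferred_source": source,
                "r_pref_c": matrix.values[p, n_dirs],
                "r_pref_same": matrix.values[p, p],
                "r_pref_opp": matrix.values[p, opp],
                "mi_same": modulation_index(matrix.values[p, p], matrix.values[p, n_dirs]),
                "mi_opp": modulation_index(matrix.values[p, opp], matrix.values[p, n_dirs]),
                "aligned": True,
            }
        )
        ref = matrix.trials[p, n_dirs]
        boot_pairs.append((cell_id, "same", ref, matrix.trials[p, p]))
        boot_pairs.append((cell_id, "opp", ref, matrix.trials[p, opp]))
        matrices[cell_id] = align_matrix(matrix, pref)
        rows.append(row)

    cells = pd.DataFrame(rows)

    # one vectorized bootstrap pass over all (cell, surround) pairs
    cells["boot_same"] = None
    cells["boot_opp"] = None
    if boot_pairs:
        A = np.stack([p[2] for p in boot_pairs])
        B = np.stack([p[3] for p in boot_pairs])
        labels = bootstrap_classify_batch(A, B, n_boot=n_boot, alpha=alpha, seed=seed)
        for (cell_id, which, _, _), label in zip(boot_pairs, labels):
            cells.loc[cells["cell_id"] == cell_id, f"boot_{'same' if which == 'same' else 'opp'}"] = label

    cells["category"] = [
        categorize_cell(b, bool(rc or rcs)) if (rc or rcs) else NON_RESPONSIVE
        for b, rc, rcs in zip(cells["boot_opp"], cells["responsive_center"], cells["responsive_cs"])
    ]
    if cell_meta is not None:
        cells = cells.merge(cell_meta, on="cell_id", how="left")
    return AnalysisResult(cells=cells, matrices=matrices, trials=trials)
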