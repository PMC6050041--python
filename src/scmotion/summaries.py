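"""Population summaries: depth profiles, selectivity correlations, and
cell-class comparisons.

These operate on the per-cell results table produced by the pipeline
(columns: cell_id, cell_class, depth_um, gdsi, mi_same, mi_opp, category,
...).  Distribution comparisons use standard two-sample tests
(Kolmogorov-Smirnov, Mann-Whitney U); the bespoke bootstrap lives in
``tuning``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

#: Depth bin edges in micrometers; labels follow the imaging-depth groupings.
DEPTH_BIN_EDGES = (0.0, 50.0, 90.0, 150.0, float("inf"))
DEPTH_BIN_LABELS = ("superficial", "60um", "120um", "180um")


def assign_depth_bins(
    depths: pd.Series,
    edges: tuple[float, ...] = DEPTH_BIN_EDGES,
    labels: tuple[str, ...] = DEPTH_BIN_LABELS,
) -> pd.Series:
    """Partition depths into non-overlapping bins [e_i, e_{i+1})."""
    return pd.cut(depths, bins=list(edges), labels=list(labels), right=False, include_lowest=True)


def depth_profile(
    results: pd.DataFrame,
    value_cols: tuple[str, ...] = ("gdsi", "mi_same", "mi_opp"),
    edges: tuple[float, ...] = DEPTH_BIN_EDGES,
    labels: tuple[str, ...] = DEPTH_BIN_LABELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(depth bin, cell class) summaries plus pairwise between-bin tests.

    Returns ``(summary, tests)``: the summary has n_cells and the median of
    each value column per bin; the tests table reports the two-sample KS
    statistic and p-value between every pair of non-empty bins per class and
    value column.  Empty bins are flagged (n_cells = 0) and excluded from
    tests.
    """
    results = results.copy()
    results["depth_bin"] = assign_depth_bins(results["depth_um"], edges, labels)
    summary_rows = []
    test_rows = []
    for (cls, dbin), sub in results.groupby(["cell_class", "depth_bin"], observed=False):
        row = {"cell_class": cls, "depth_bin": dbin, "n_cells": len(sub)}
        for col in value_cols:
            vals = sub[col].dropna()
            row[f"median_{col}"] = vals.median() if len(vals) else np.nan
        summary_rows.append(row)
    for cls, sub in results.groupby("cell_class"):
        for col in value_cols:
            groups = {
                dbin: g[col].dropna().to_numpy()
                for dbin, g in sub.groupby("depth_bin", observed=False)
            }
            occupied = [b for b, v in groups.items() if v.size >= 2]
            for b1, b2 in itertools.combinations(occupied, 2):
                ks = stats.ks_2samp(groups[b1], groups[b2])
                test_rows.append(
                    {
                        "cell_class": cls,
                        "value": col,
                        "bin_a": b1,
                        "bin_b": b2,
                        "ks_stat": ks.statistic,
                        "p_value": ks.pvalue,
                    }
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def mi_gdsi_correlation(
    results: pd.DataFrame, cell_class: str, mi_col: str = "mi_opp"
) -> tuple[float, float]:
    """Pearson correlation between a surround modulation index and gDSI
    across cells of one class.  Returns (r, p)."""
    sub = results[results["cell_class"] == cell_class][["gdsi", mi_col]].dropna()
    if len(sub) < 3:
        raise InsufficientDataError("correlation requires at least 3 cells")
    x = sub["gdsi"].to_numpy()
    y = sub[mi_col].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gdsi_split_comparison(
    results: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Modulation-index summaries per gDSI stratum (below/at-or-above the
    threshold) and surround relationship, with Mann-Whitney tests between
    strata.

    Intended for the inhibitory population, whose selectivity clusters split
    cleanly at gDSI = 0.5; callers pass an already-filtered results table.
    """
    sub = results.dropna(subset=["gdsi"]).copy()
    sub["stratum"] = np.where(sub["gdsi"] >= threshold, f"gdsi>={threshold}", f"gdsi<{threshold}")
    strata = sub["stratum"].unique()
    summary_rows = []
    test_rows = []
    for col, surround in (("mi_same", "same"), ("mi_opp", "opposite")):
        groups = {}
        for stratum, g in sub.groupby("stratum"):
            vals = g[col].dropna().to_numpy()
            groups[stratum] = vals
            summary_rows.append(
                {
                    "stratum": stratum,
                    "surround": surround,
                    "n": vals.size,
                    "mean_mi": vals.mean() if vals.size else np.nan,
                    "sem_mi": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                }
            )
        if len(strata) == 2 and all(groups[s].size > 0 for s in strata):
            u = stats.mannwhitneyu(*(groups[s] for s in sorted(groups)))
            test_rows.append({"surround": surround, "u_stat": u.statistic, "p_value": u.pvalue})
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def class_comparison(results: pd.DataFrame) -> dict:
    """Between-class comparison of surround modulation.

    Returns a dict with the four-category percentage table per class
    (rows sum to 100), and per-surround KS tests between the two classes'
    modulation-index distributions (when both classes are present).
    """
    categories = (
        results.groupby("cell_class")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        * 100.0
    )
    tests = []
    classes = sorted(results["cell_class"].unique())
    if len(classes) == 2:
        for col, surround in (("mi_same", "same"), ("mi_opp", "opposite")):
            a = results.loc[results["cell_class"] == classes[0], col].dropna()
            b = results.loc[results["cell_class"] == classes[1], col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                ks = stats.ks_2samp(a, b)
                tests.append(
                    {
                        "surround": surround,
                        "class_a": classes[0],
                        "class_b": classes[1],
                        "ks_stat": ks.statistic,
                        "p_value": ks.pvalue,
                    }
                )
    return {"category_percentages": categories, "tests": pd.DataFrame(tests)}
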