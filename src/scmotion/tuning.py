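"""Direction selectivity, surround modulation, and the bootstrap classifier.

gDSI is the magnitude of the response-weighted vector sum over directions
divided by the scalar response sum, |sum R_theta e^{i theta}| / sum R_theta,
with negative responses rectified to zero first; it is 0 for an untuned cell
and 1 for a cell responding to a single direction.

The modulation index compares the preferred-center response with and without a
surround, (R_CwS - R_C) / (R_CwS + R_C), clipped to [-1, 1] (values can escape
the interval only through negative dF/F0).

The bootstrap classifier pools the two conditions' trial values (4 + 4 = 8),
resamples 8 values with replacement 10,000 times, randomly splits each
resample 4/4 and differences the subset means to build a null distribution;
the observed mean difference is then compared with the null's 95% interval.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError, NoPreferenceError

POTENTIATED = "potentiated"
SUPPRESSED = "suppressed"
NON_MODULATED = "non_modulated"
NON_RESPONSIVE = "non_responsive"


def compute_gdsi(tuning_curve: np.ndarray, directions: np.ndarray | None = None, rectify: bool = True) -> float:
    """Global direction selectivity index of a tuning curve.

    Returns NaN (the undefined-gDSI signal) when the rectified curve sums to
    zero; such cells are excluded from selectivity analyses.
    """
    r = np.asarray(tuning_curve, dtype=float)
    if r.size < 2:
        raise InsufficientDataError("gDSI requires at least 2 directions")
    if directions is None:
        directions = np.arange(r.size) * (360.0 / r.size)
    theta = np.deg2rad(np.asarray(directions, dtype=float))
    if rectify:
        r = np.maximum(r, 0.0)
    total = r.sum()
    if total <= 0:
        return float("nan")
    return float(np.abs(np.sum(r * np.exp(1j * theta))) / total)


def preferred_direction(
    values: np.ndarray, responsive_center: bool, directions: np.ndarray | None = None
) -> tuple[float, str]:
    """Preferred direction from a (center x surround, blank last) mean matrix.

    Center-responsive cells: the center-alone direction with the peak mean
    response.  Center-silent cells: the center direction of the peak
    center-surround combination (surround not blank).  Ties break toward the
    lowest direction label; an all-non-positive candidate set raises the
    no-preference signal.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0] - 1
    if directions is None:
        directions = np.arange(n) * (360.0 / n)
    if responsive_center:
        row = values[:n, n]  # center alone: blank surround
        if np.all(row <= 0):
            raise NoPreferenceError("all center-alone responses non-positive")
        return float(directions[int(np.argmax(row))]), "center_alone"
    block = values[:n, :n]  # all true center-surround combinations
    if np.all(block <= 0):
        raise NoPreferenceError("all center-surround responses non-positive")
    c_idx = int(np.unravel_index(np.argmax(block), block.shape)[0])
    return float(directions[c_idx]), "center_silent_CS"


def modulation_index(r_pref_c_with_s: float | np.ndarray, r_pref_c: float | np.ndarray) -> float | np.ndarray:
    """(R_CwS - R_C) / (R_CwS + R_C), clipped to [-1, 1].

    Denominator-zero convention: the sign of the numerator (0 if both
    responses are 0).
    """
    num = np.asarray(r_pref_c_with_s, dtype=float) - np.asarray(r_pref_c, dtype=float)
    den = np.asarray(r_pref_c_with_s, dtype=float) + np.asarray(r_pref_c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where(den == 0.0, np.sign(num), num / den)
    mi = np.clip(mi, -1.0, 1.0)
    return float(mi) if mi.ndim == 0 else mi


def _bootstrap_null_bounds(
    pool: np.ndarray, n_per_group: int, n_boot: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """(m, 2) array of [alpha/2, 1 - alpha/2] null quantiles per pooled row.

    ``pool`` is (m, 2n); each resample draws 2n values with replacement and is
    split into two groups of n by an explicit random permutation.
    """
    m, two_n = pool.shape
    bounds = np.empty((m, 2))
    for i in range(m):
        idx = rng.integers(0, two_n, size=(n_boot, two_n))
        samp = pool[i][idx]
        perm = rng.random((n_boot, two_n)).argsort(axis=1)
        samp = np.take_along_axis(samp, perm, axis=1)
        diffs = samp[:, n_per_group:].mean(axis=1) - samp[:, :n_per_group].mean(axis=1)
        bounds[i] = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return bounds


def bootstrap_classify_batch(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized classifier over (m, n) trial arrays; returns an (m,) array of
    {potentiated, suppressed, non_modulated} labels for mean(B) - mean(A)."""
    A = np.atleast_2d(np.asarray(trials_a, dtype=float))
    B = np.atleast_2d(np.asarray(trials_b, dtype=float))
    if A.shape != B.shape:
        raise InvalidParameterError("trial groups must have matching shapes")
    if n_boot < 1000:
        raise InvalidParameterError("n_boot must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = B.mean(axis=1) - A.mean(axis=1)
    bounds = _bootstrap_null_bounds(np.concatenate([A, B], axis=1), A.shape[1], n_boot, alpha, rng)
    out = np.full(A.shape[0], NON_MODULATED, dtype=object)
    out[obs > bounds[:, 1]] = POTENTIATED
    out[obs < bounds[:, 0]] = SUPPRESSED
    return out


def bootstrap_classify(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Pooled-resampling significance classification of one condition pair.

    ``trials_a`` is the reference condition (e.g. preferred center alone),
    ``trials_b`` the compared condition (e.g. preferred center + surround).
    Deterministic given ``seed``.
    """
    a = np.asarray(trials_a, dtype=float).ravel()
    b = np.asarray(trials_b, dtype=float).ravel()
    if a.size != b.size:
        raise InvalidParameterError("trial counts must match between conditions")
    if a.size < 2:
        raise InsufficientDataError("need at least 2 trials per condition")
    return str(bootstrap_classify_batch(a[None, :], b[None, :], n_boot, alpha, seed)[0])


def categorize_cell(bootstrap_class: str | None, responsive_to_center_or_cs: bool) -> str:
    """Four-way response taxonomy for the preferred-center + opposite-surround
    comparison.

    Cells that respond to no condition involving the center stimulus
    (including surround-alone-only responders) are non-responsive; responsive
    cells carry their bootstrap class.
    """
    if not responsive_to_center_or_cs:
        return NON_RESPONSIVE
    if bootstrap_class not in (POTENTIATED, SUPPRESSED, NON_MODULATED):
        raise InvalidParameterError(f"invalid bootstrap class {bootstrap_class!r}")
    return bootstrap_class
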