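"""Validation statistics for the no-drive population.

Age structure (mean age, adult life expectancy, age quantiles) and Ripley's
L function, which measures departure from complete spatial randomness:
L(r) - r < 0 indicates a population more dispersed than random at scale r.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .engine import DemographyRecord


def age_summary(record: DemographyRecord | list[np.ndarray],
                death_ages: list[int] | None = None,
                max_age: int = 12) -> dict[str, float | None]:
    """Age structure over the recorded census steps.

    Parameters
    ----------
    record
        A :class:`DemographyRecord` from a recorded run, or a plain list of
        per-step age arrays (census taken after mortality, so newborn
        survivors appear at age 0).
    death_ages
        Ages at death (only used when `record` is a list of arrays).
    max_age
        Age for the reported cumulative fraction (default 12 steps).

    Returns mean age over all individual-step observations, adult life
    expectancy (mean age at death among individuals that survived their
    first step), and the fraction of observations at or below `max_age`.
    """
    if isinstance(record, DemographyRecord):
        censuses = record.census_ages
        deaths = record.death_ages
    else:
        censuses = record
        deaths = death_ages or []
    if len(censuses) < 2:
        raise ValueError("need at least two recorded censuses")
    ages = np.concatenate([np.asarray(a) for a in censuses]) \
        if censuses else np.array([])
    if ages.size == 0:
        return {"mean_age": None, "life_expectancy": None,
                "fraction_at_or_below": None}
    deaths = np.asarray(deaths)
    return {
        "mean_age": float(ages.mean()),
        "life_expectancy": float(deaths.mean()) if deaths.size else None,
        "fraction_at_or_below": float((ages <= max_age).mean()),
    }


def _translation_weights(dx: np.ndarray, dy: np.ndarray,
                         side: float) -> np.ndarray:
    """Translation edge-correction weight per ordered pair."""
    return (side * side) / ((side - np.abs(dx)) * (side - np.abs(dy)))


def ripley_K(x: np.ndarray, y: np.ndarray, side: float,
             radii: np.ndarray, correction: str = "translation"
             ) -> np.ndarray:
    """Ripley's K estimator on a square window.

    K(r) = A / (N (N-1)) * sum over ordered pairs with d <= r of w_ij,
    where w_ij is the translation edge-correction weight (or 1 with
    correction="none").  Pair discovery uses a KD-tree; per-radius sums run
    over pairs in ascending (i, j) order so results match an exhaustive
    pair loop exactly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    radii = np.atleast_1d(np.asarray(radii, float))
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if correction not in ("translation", "none"):
        raise ValueError("correction must be 'translation' or 'none'")
    n = x.size
    if n < 2:
        raise ValueError("need at least two points")
    rmax = radii.max()
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if pairs.size:
        # canonical ascending (i, j) order
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
    i, j = pairs[:, 0], pairs[:, 1]
    dx = x[i] - x[j]
    dy = y[i] - y[j]
    d = np.hypot(dx, dy)
    w = _translation_weights(dx, dy, side) if correction == "translation" \
        else np.ones(d.size)
    area = side * side
    k = np.empty(radii.size)
    for a, r in enumerate(radii):
        k[a] = 2.0 * np.sum(w[d <= r])  # unordered pairs counted twice
    return area / (n * (n - 1)) * k


def ripley_L_deviation(x: np.ndarray, y: np.ndarray, side: float,
                       radii: np.ndarray, correction: str = "translation"
                       ) -> np.ndarray:
    """L(r) - r with L = sqrt(K / pi); negative values indicate dispersion."""
    k = ripley_K(x, y, side, radii, correction=correction)
    return np.sqrt(k / np.pi) - np.atleast_1d(np.asarray(radii, float))
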