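"""Variance-based Sobol sensitivity analysis.

Saltelli's sampling scheme arranges a quasi-random Sobol sequence into two
base matrices A and B (n rows each) plus 2d cross matrices (AB_i with
column i of A replaced from B, and BA_i the reverse), for n(2d+2) model
evaluations in total.  From these the first-order indices S_i (lone
contribution of parameter i, averaged over the others), the second-order
indices S_ij (pairwise synergy) and the total-order indices ST_i (all
effects involving i) are estimated:

    S_i  = mean(f(B) * (f(AB_i) - f(A))) / V          (Saltelli 2010)
    ST_i = mean((f(A) - f(AB_i))^2) / (2 V)           (Jansen)
    S_ij = [mean(f(BA_i) f(AB_j)) - mean(f(A) f(B))] / V - S_i - S_j

with V the variance of the pooled A/B evaluations.  Confidence intervals
come from bootstrap resampling of the n sample rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import qmc


@dataclass
class SobolResult:
    """First-, second- and total-order indices with bootstrap CIs."""

    names: tuple[str, ...]
    first_order: np.ndarray
    total_order: np.ndarray
    second_order: dict[tuple[int, int], float]
    first_ci: np.ndarray
    total_ci: np.ndarray
    second_ci: dict[tuple[int, int], tuple[float, float]]
    n: int
    d: int

    def to_frame(self):
        """Long-format table: parameter(s), order, index, ci_low, ci_high."""
        import pandas as pd
        rows = []
        for i, name in enumerate(self.names):
            rows.append((name, "first", self.first_order[i],
                         self.first_ci[i, 0], self.first_ci[i, 1]))
            rows.append((name, "total", self.total_order[i],
                         self.total_ci[i, 0], self.total_ci[i, 1]))
        for (i, j), s in self.second_order.items():
            lo, hi = self.second_ci[(i, j)]
            rows.append((f"{self.names[i]}*{self.names[j]}", "second",
                         s, lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "order", "index",
                                           "ci_low", "ci_high"])


def design_size(n: int, d: int) -> int:
    """Total model evaluations of the Saltelli design: n (2d + 2)."""
    return n * (2 * d + 2)


def _bounds_arrays(bounds) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(bounds, "lower"):
        return bounds.lower, bounds.upper
    lower, upper = bounds
    return np.asarray(lower, float), np.asarray(upper, float)


def sobol_design(n: int, d: int, bounds=None, seed: int = 0,
                 second_order: bool = True) -> np.ndarray:
    """The n(2d+2) evaluation matrix for Sobol index estimation.

    Rows are ordered [A; B; AB_1..AB_d; BA_1..BA_d].  `bounds` may be None
    (unit hypercube), a (lower, upper) pair, or a ParameterSpace.  The
    BA blocks are only needed for second-order indices but are always
    generated so the design size matches n(2d+2).
    """
    if n < 1 or d < 1:
        raise ValueError("need n >= 1 and d >= 1")
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    base = sampler.random(n)
    a = base[:, :d]
    b = base[:, d:]
    blocks = [a, b]
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    for i in range(d):
        ba = b.copy()
        ba[:, i] = a[:, i]
        blocks.append(ba)
    design = np.vstack(blocks)
    if bounds is not None:
        lower, upper = _bounds_arrays(bounds)
        design = lower + design * (upper - lower)
    return design


def _indices_from_blocks(fa, fb, fab, fba, d):
    pooled = np.concatenate([fa, fb])
    v = pooled.var()
    if v == 0:
        z = np.zeros(d)
        return z, z.copy(), {(i, j): 0.0 for i in range(d)
                             for j in range(i + 1, d)}
    s1 = np.array([np.mean(fb * (fab[i] - fa)) for i in range(d)]) / v
    st = np.array([np.mean((fa - fab[i]) ** 2) for i in range(d)]) / (2 * v)
    s2 = {}
    mab = np.mean(fa * fb)
    for i in range(d):
        for j in range(i + 1, d):
            vij = np.mean(fba[i] * fab[j]) - mab
            s2[(i, j)] = vij / v - s1[i] - s1[j]
    return s1, st, s2


def sobol_indices(fn: Callable[[np.ndarray], np.ndarray], n: int, d: int,
                  bounds=None, seed: int = 0, n_boot: int = 100,
                  conf: float = 0.95, names: tuple[str, ...] | None = None
                  ) -> SobolResult:
    """Estimate Sobol indices of `fn` over a box-bounded input space.

    `fn` maps an (m, d) array to m outputs and is evaluated on the full
    n(2d+2) Saltelli design.  A constant function yields all-zero indices
    (with a warning).
    """
    design = sobol_design(n, d, bounds=bounds, seed=seed)
    out = np.asarray(fn(design), float).ravel()
    if out.size != n * (2 * d + 2):
        raise ValueError("fn returned the wrong number of outputs")
    fa = out[:n]
    fb = out[n:2 * n]
    fab = [out[(2 + i) * n:(3 + i) * n] for i in range(d)]
    fba = [out[(2 + d + i) * n:(3 + d + i) * n] for i in range(d)]
    if np.var(np.concatenate([fa, fb])) == 0:
        import warnings
        warnings.warn("function output has zero variance; all indices are 0")
    s1, st, s2 = _indices_from_blocks(fa, fb, fab, fba, d)

    rng = np.random.default_rng(seed + 1)
    qlo, qhi = (1 - conf) / 2, 1 - (1 - conf) / 2
    b1 = np.empty((n_boot, d))
    bt = np.empty((n_boot, d))
    b2 = {key: np.empty(n_boot) for key in s2}
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        r1, rt, r2 = _indices_from_blocks(
            fa[idx], fb[idx], [f[idx] for f in fab], [f[idx] for f in fba], d)
        b1[b] = r1
        bt[b] = rt
        for key in b2:
            b2[key][b] = r2[key]
    first_ci = np.quantile(b1, [qlo, qhi], axis=0).T
    total_ci = np.quantile(bt, [qlo, qhi], axis=0).T
    second_ci = {key: (float(np.quantile(vals, qlo)),
                       float(np.quantile(vals, qhi)))
                 for key, vals in b2.items()}
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(d))
    return SobolResult(names=tuple(names), first_order=s1, total_order=st,
                       second_order=s2, first_ci=first_ci, total_ci=total_ci,
                       second_ci=second_ci, n=n, d=d)


def fixed_parameter_function(fn: Callable[[np.ndarray], np.ndarray],
                             d_full: int, fixed: dict[int, float]
                             ) -> tuple[Callable, int]:
    """Freeze dimensions of `fn` at given values, reducing d accordingly.

    Returns (reduced function over the free dimensions, number of free
    dimensions); used for analyses with e.g. fitness and efficiency fixed.
    """
    free = [i for i in range(d_full) if i not in fixed]

    def wrapped(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        full = np.empty((x.shape[0], d_full))
        full[:, free] = x
        for i, val in fixed.items():
            full[:, i] = val
        return fn(full)

    return wrapped, len(free)
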