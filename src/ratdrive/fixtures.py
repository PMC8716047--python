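"""Analytic stand-ins for the simulator.

The full individual-based model costs seconds per evaluation; these cheap
deterministic surfaces reproduce the *shape* of its outcome space (a small
success region with an abrupt success/failure transition, mostly binary
suppression values) so the surrogate-modeling and sensitivity machinery can
be exercised in milliseconds.  They emulate only the outcome surface, not
any spatial dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ThresholdSurrogate:
    """Sharp success-corner surface on the unit hypercube.

    A point succeeds when every *active* coordinate exceeds its threshold
    (akin to drive fitness and efficiency both needing to be high); the
    margin is score = min_k (x_k - tau_k).  The suppression-like output is a
    steep sigmoid of the score (mostly 0 or 1), the composite-like output a
    wider tanh ramp in [-1, 1].  Optional binomial noise emulates averaging
    a finite number of stochastic replicates.

    The sharp-limit success volume is prod_k (1 - tau_k).
    """

    thresholds: tuple[float, ...] = (0.7, 0.7)
    active_dims: tuple[int, ...] | None = None
    suppression_sharpness: float = 0.01
    composite_width: float = 0.15
    replicates: int | None = None
    seed: int = 0

    def _score(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        dims = (self.active_dims if self.active_dims is not None
                else tuple(range(len(self.thresholds))))
        margins = np.stack([x[:, dim] - tau
                            for dim, tau in zip(dims, self.thresholds)])
        return margins.min(axis=0)

    def __call__(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (composite-like value, suppression-like value) per row."""
        score = self._score(x)
        supp = 1.0 / (1.0 + np.exp(-score / self.suppression_sharpness))
        comp = np.tanh(score / self.composite_width)
        if self.replicates:
            rng = np.random.default_rng(self.seed)
            supp = rng.binomial(self.replicates, supp) / self.replicates
            comp = np.clip(comp + rng.normal(0.0, 0.5 / self.replicates,
                                             comp.size), -1.0, 1.0)
        return comp, supp

    def success_volume(self) -> float:
        """Analytic fraction of the unit cube in the sharp success region."""
        return float(np.prod([1.0 - t for t in self.thresholds]))


def threshold_surrogate(point: np.ndarray,
                        boundary_spec: ThresholdSurrogate | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the threshold surface at `point` (rows in the unit cube)."""
    spec = boundary_spec if boundary_spec is not None else ThresholdSurrogate()
    return spec(point)


def ishigami(point: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """Ishigami benchmark: sin x1 + a sin^2 x2 + b x3^4 sin x1 on [-pi, pi]^3.

    Its Sobol indices are known in closed form (see
    :func:`ishigami_indices`), making it the standard oracle for
    variance-based sensitivity estimators.
    """
    p = np.atleast_2d(np.asarray(point, float))
    if p.shape[1] != 3:
        raise ValueError("ishigami expects 3-D input")
    x1, x2, x3 = p[:, 0], p[:, 1], p[:, 2]
    out = np.sin(x1) + a * np.sin(x2) ** 2 + b * x3 ** 4 * np.sin(x1)
    return out[0] if np.ndim(point) == 1 else out


def ishigami_indices(a: float = 7.0, b: float = 0.1) -> dict:
    """Closed-form variance and Sobol indices of the Ishigami function."""
    pi4 = np.pi ** 4
    v1 = 0.5 * (1.0 + b * pi4 / 5.0) ** 2
    v2 = a ** 2 / 8.0
    v13 = b ** 2 * pi4 ** 2 * (1.0 / 18.0 - 1.0 / 50.0)
    v = v1 + v2 + v13
    return {"variance": v, "S1": v1 / v, "S2": v2 / v, "S3": 0.0,
            "S13": v13 / v, "ST1": (v1 + v13) / v, "ST2": v2 / v,
            "ST3": v13 / v}
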