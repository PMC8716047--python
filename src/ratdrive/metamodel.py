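"""Gaussian-process surrogate over the drive parameter space.

The surrogate interpolates a scalar simulation outcome — either the
composite statistic in [-1, 1] or the suppression rate in [0, 1] — over the
11-13 dimensional parameter space, and reports a 95% confidence interval
with every prediction.  The kernel is Matern nu = 0.5 (absolute
exponential) with per-dimension lengthscales, suited to outcome surfaces
with abrupt success/failure transitions.  Hyperparameters (lengthscales,
signal variance, noise variance) are optimized by Adam on the log marginal
likelihood; the model is checkpointed periodically and the checkpoint with
the best validation score is kept.

Adaptive sampling grows the training set where the model is uncertain
(selection probability proportional to CI width w_i) or where the predicted
*outcome* is uncertain (w_i additionally devalued linearly as the predicted
mean approaches a certain outcome).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import scipy.linalg
from scipy.stats import qmc

from .params import (DEMOGRAPHIC_RANGES, DRIVE_RANGES, DriveType,
                     ParameterSet)

_LOG2PI = float(np.log(2.0 * np.pi))
_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Parameter-space designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpace:
    """Ordered box-bounded parameter space with unit-cube scaling."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.lower) / (self.upper - self.lower)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(u, float) * (self.upper - self.lower)

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return np.all((x >= self.lower - 1e-12) & (x <= self.upper + 1e-12),
                      axis=-1)


def drive_parameter_space(drive_type: DriveType,
                          with_resistance: bool = False) -> ParameterSpace:
    """The variable parameter space for one drive.

    Eight demographic parameters plus release percentage, drive fitness and
    efficiency (11 dims), plus resistance rate and relative r1 rate when
    resistance is modeled (13 dims).  Fitness/efficiency lower bounds are
    0.5 for homing drives without resistance and 0.75 otherwise.
    """
    if drive_type is DriveType.Y_SHREDDER and with_resistance:
        raise ValueError("resistance is not modeled for the Y-shredder")
    fe_min = 0.5 if (not with_resistance
                     and drive_type is not DriveType.Y_SHREDDER) else 0.75
    names, lo, hi = [], [], []
    for key, (mn, _, mx) in DEMOGRAPHIC_RANGES.items():
        names.append(key)
        lo.append(mn)
        hi.append(mx)
    for key, (mn, _, mx) in DRIVE_RANGES.items():
        if key in ("resistance_rate", "relative_r1_rate") and not with_resistance:
            continue
        if key in ("drive_fitness", "drive_efficiency"):
            mn = fe_min
        names.append(key)
        lo.append(mn)
        hi.append(mx)
    return ParameterSpace(tuple(names), np.array(lo, float),
                          np.array(hi, float))


def point_to_parameters(space: ParameterSpace, x: np.ndarray,
                        drive_type: DriveType | None,
                        **fixed) -> ParameterSet:
    """Materialize a design point as a full ParameterSet."""
    kwargs = dict(zip(space.names, np.asarray(x, float)))
    kwargs.update(fixed)
    return ParameterSet(drive_type=drive_type, **kwargs)


def latin_hypercube(n: int, bounds: ParameterSpace | tuple, seed: int
                    ) -> np.ndarray:
    """n Latin-hypercube points: one sample per stratum per dimension."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(bounds, ParameterSpace):
        lower, upper = bounds.lower, bounds.upper
    else:
        lower, upper = (np.asarray(b, float) for b in bounds)
    d = lower.size
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    u = sampler.random(n)
    return lower + u * (upper - lower)


# ---------------------------------------------------------------------------
# Matern nu = 0.5 Gaussian process
# ---------------------------------------------------------------------------

def _abs_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-dimension absolute differences, shape (na, nb, d)."""
    return np.abs(a[:, None, :] - b[None, :, :])


@dataclass
class GPModelHandle:
    """Trained surrogate with a (mean, 95% CI width) predict contract."""

    output_type: str                 # "composite" | "suppression_rate"
    space: ParameterSpace
    x_unit: np.ndarray               # training inputs in the unit cube
    y_raw: np.ndarray
    log_ls: np.ndarray
    log_sf2: float
    log_sn2: float
    y_mean: float
    y_std: float
    validation_score: float | None = None
    checkpoint_iteration: int | None = None
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def _factorize(self) -> None:
        ls = np.exp(self.log_ls)
        sf2 = np.exp(self.log_sf2)
        sn2 = np.exp(self.log_sn2)
        s = np.sqrt((( _abs_dists(self.x_unit, self.x_unit) / ls) ** 2
                     ).sum(axis=2))
        ky = sf2 * np.exp(-s)
        ky[np.diag_indices_from(ky)] += sn2 + 1e-10
        self._chol = np.linalg.cholesky(ky)
        yz = (self.y_raw - self.y_mean) / self.y_std if self.y_std > 0 \
            else np.zeros_like(self.y_raw)
        self._alpha = np.linalg.solve(ky, yz)

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and 95% CI width at each row of `x`.

        `x` is given in original parameter units.  The CI is on the latent
        function (observation noise excluded).
        """
        if self._chol is None:
            self._factorize()
        x = np.atleast_2d(np.asarray(x, float))
        u = self.space.to_unit(x)
        ls = np.exp(self.log_ls)
        sf2 = np.exp(self.log_sf2)
        if self.y_std == 0.0:
            mean = np.full(len(u), self.y_mean)
            return mean, np.zeros(len(u))
        means = np.empty(len(u))
        widths = np.empty(len(u))
        # chunked to bound the (n_test, n_train, d) intermediate
        chunk = max(1, int(2e7 / max(1, self.x_unit.shape[0] * u.shape[1])))
        for a in range(0, len(u), chunk):
            sub = u[a:a + chunk]
            s = np.sqrt((( _abs_dists(sub, self.x_unit) / ls) ** 2
                         ).sum(axis=2))
            kstar = sf2 * np.exp(-s)
            means[a:a + chunk] = kstar @ self._alpha
            v = np.linalg.solve(self._chol, kstar.T)
            var = np.maximum(sf2 - np.sum(v * v, axis=0), 0.0)
            widths[a:a + chunk] = 2.0 * _Z95 * np.sqrt(var)
        return (means * self.y_std + self.y_mean, widths * self.y_std)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model plus a manifest as JSON."""
        path = Path(path)
        payload = {
            "output_type": self.output_type,
            "names": list(self.space.names),
            "lower": self.space.lower.tolist(),
            "upper": self.space.upper.tolist(),
            "x_unit": self.x_unit.tolist(),
            "y_raw": self.y_raw.tolist(),
            "log_ls": self.log_ls.tolist(),
            "log_sf2": self.log_sf2,
            "log_sn2": self.log_sn2,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
        }
        blob = json.dumps(payload).encode()
        manifest = {
            "kernel": "matern-1/2 (absolute exponential), ARD",
            "output_type": self.output_type,
            "n_train": int(len(self.y_raw)),
            "validation_score": self.validation_score,
            "checkpoint_iteration": self.checkpoint_iteration,
            "training_set_sha256": hashlib.sha256(blob).hexdigest(),
        }
        path.write_text(json.dumps({"manifest": manifest, "model": payload}))

    @classmethod
    def load(cls, path: str | Path) -> "GPModelHandle":
        data = json.loads(Path(path).read_text())
        m = data["model"]
        space = ParameterSpace(tuple(m["names"]), np.array(m["lower"]),
                               np.array(m["upper"]))
        return cls(output_type=m["output_type"], space=space,
                   x_unit=np.array(m["x_unit"]), y_raw=np.array(m["y_raw"]),
                   log_ls=np.array(m["log_ls"]), log_sf2=m["log_sf2"],
                   log_sn2=m["log_sn2"], y_mean=m["y_mean"],
                   y_std=m["y_std"],
                   validation_score=data["manifest"]["validation_score"],
                   checkpoint_iteration=data["manifest"]["checkpoint_iteration"])


def _lml_and_grad(dists, y, log_ls, log_sf2, log_sn2):
    """Log marginal likelihood and gradient w.r.t. the log hyperparameters."""
    n = y.size
    ls = np.exp(log_ls)
    sf2 = np.exp(log_sf2)
    sn2 = np.exp(log_sn2)
    scaled2 = (dists / ls) ** 2    # (n, n, d)
    s = np.sqrt(scaled2.sum(axis=2))
    k = sf2 * np.exp(-s)
    ky = k.copy()
    ky[np.diag_indices(n)] += sn2 + 1e-10
    try:
        chol, low = scipy.linalg.cho_factor(ky, lower=True,
                                            check_finite=False)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        return -np.inf, np.zeros(log_ls.size + 2)
    alpha = scipy.linalg.cho_solve((chol, low), y, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    lml = -0.5 * y @ alpha - 0.5 * logdet - 0.5 * n * _LOG2PI
    kinv = scipy.linalg.cho_solve((chol, low), np.eye(n), check_finite=False)
    a = np.outer(alpha, alpha) - kinv
    grad = np.empty(log_ls.size + 2)
    ak = a * k
    s_safe = np.where(s > 0, s, 1.0)
    for j in range(log_ls.size):
        # d k / d log l_j = k * (dx_j / l_j)^2 / s  (0 on the diagonal)
        grad[j] = 0.5 * np.sum(ak * scaled2[:, :, j] / s_safe)
    grad[-2] = 0.5 * np.sum(ak)                   # d/dlog sf2
    grad[-1] = 0.5 * np.trace(a) * sn2            # d/dlog sn2
    return lml, grad


def train_gp(train_points: np.ndarray, train_values: np.ndarray,
             validation_points: np.ndarray, validation_values: np.ndarray,
             space: ParameterSpace, output_type: str = "composite",
             iterations: int = 30000, checkpoint_every: int = 1000,
             learning_rate: float = 0.05, metric: str = "rmse",
             seed: int = 0) -> GPModelHandle:
    """Fit the surrogate, keeping the best validation checkpoint.

    Hyperparameters are optimized by Adam on the log marginal likelihood for
    `iterations` steps; every `checkpoint_every` steps the interim model is
    scored on the validation set (`metric`: "rmse", lower better, or "f1",
    higher better) and the best-scoring checkpoint is returned.
    """
    x = np.atleast_2d(np.asarray(train_points, float))
    y = np.asarray(train_values, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training points")
    if not np.all(np.isfinite(y)):
        raise ValueError("training values must be finite")
    u = np.clip(space.to_unit(x), 0.0, 1.0)
    y_mean = float(y.mean())
    y_std = float(y.std())

    def handle(log_ls, log_sf2, log_sn2, score=None, it=None):
        return GPModelHandle(output_type=output_type, space=space,
                             x_unit=u, y_raw=y, log_ls=log_ls.copy(),
                             log_sf2=float(log_sf2), log_sn2=float(log_sn2),
                             y_mean=y_mean, y_std=y_std,
                             validation_score=score, checkpoint_iteration=it)

    d = u.shape[1]
    if y_std == 0.0:
        import warnings
        warnings.warn("degenerate training values (all identical); "
                      "returning a constant model")
        return handle(np.zeros(d), 0.0, np.log(1e-4))

    yz = (y - y_mean) / y_std
    dists = _abs_dists(u, u)
    theta = np.concatenate([np.log(np.full(d, 0.3)), [0.0], [np.log(0.05)]])
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    b1, b2, eps = 0.9, 0.999, 1e-8

    def val_score(h: GPModelHandle) -> float:
        # "rmse" compares predictions with validation values on the model's
        # own output scale; "f1" expects validation values that are
        # suppression rates in [0, 1].
        if metric == "f1":
            res = evaluate_model(h, validation_points, validation_values)
            p = res["precision"] or 0.0
            r = res["recall"]
            return -(0.0 if p + r == 0 else 2 * p * r / (p + r))
        mean, _ = h.predict(validation_points)
        return float(np.sqrt(np.mean((mean - validation_values) ** 2)))

    best = None
    for it in range(1, iterations + 1):
        lml, grad = _lml_and_grad(dists, yz, theta[:d], theta[d], theta[d + 1])
        if not np.isfinite(lml):
            break
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad * grad
        mh = m / (1 - b1 ** it)
        vh = v / (1 - b2 ** it)
        theta = theta + learning_rate * mh / (np.sqrt(vh) + eps)
        if it % checkpoint_every == 0 or it == iterations:
            h = handle(theta[:d], theta[d], theta[d + 1], it=it)
            score = val_score(h)
            if best is None or score < best[0]:
                best = (score, h)
    if best is None:
        return handle(theta[:d], theta[d], theta[d + 1])
    best[1].validation_score = best[0]
    return best[1]


def predict(model: GPModelHandle, points: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and 95% CI width (functional form of the method)."""
    if not isinstance(model, GPModelHandle):
        raise TypeError("predict requires a trained GPModelHandle")
    return model.predict(points)


# ---------------------------------------------------------------------------
# Adaptive sampling
# ---------------------------------------------------------------------------

def _weighted_choice_without_replacement(weights: np.ndarray, k: int,
                                         rng: np.random.Generator
                                         ) -> np.ndarray:
    total = weights.sum()
    if total <= 0 or not np.isfinite(total):
        # all-zero weights: uniform fallback
        return rng.choice(weights.size, size=k, replace=False)
    return rng.choice(weights.size, size=k, replace=False,
                      p=weights / total)


def adaptive_sample_uncertainty(model: GPModelHandle, candidates: np.ndarray,
                                k: int, rng: np.random.Generator
                                ) -> np.ndarray:
    """Select k candidate indices with probability proportional to CI width."""
    candidates = np.atleast_2d(candidates)
    if candidates.shape[0] == 0 or k > candidates.shape[0]:
        raise ValueError("need a nonempty candidate set with k <= |candidates|")
    _, w = model.predict(candidates)
    return _weighted_choice_without_replacement(w, k, rng)


def adaptive_sample_boundary(model: GPModelHandle, candidates: np.ndarray,
                             k: int, rng: np.random.Generator) -> np.ndarray:
    """Uncertainty sampling devalued toward certain outcomes.

    Composite models weight w_i * (1 - |v_i|), so points predicted at +-1
    (certain success/failure) are never drawn.  Suppression-rate models
    weight w_i * (1 - 2 |v_i - 0.5|), peaking at v = 0.5 and reaching zero
    at v in {0, 1}, mirroring the composite rule's behavior at |v| = 1.
    """
    candidates = np.atleast_2d(candidates)
    if candidates.shape[0] == 0 or k > candidates.shape[0]:
        raise ValueError("need a nonempty candidate set with k <= |candidates|")
    v, w = model.predict(candidates)
    if model.output_type == "suppression_rate":
        v = np.clip(v, 0.0, 1.0)
        weight = w * np.maximum(1.0 - 2.0 * np.abs(v - 0.5), 0.0)
    else:
        v = np.clip(v, -1.0, 1.0)
        weight = w * (1.0 - np.abs(v))
    return _weighted_choice_without_replacement(weight, k, rng)


# ---------------------------------------------------------------------------
# Accuracy metrics
# ---------------------------------------------------------------------------

def _rate_scale(output_type: str, predictions: np.ndarray) -> np.ndarray:
    """Map predictions onto the [0, 1] suppression-rate scale."""
    if output_type == "composite":
        return (np.asarray(predictions) + 1.0) / 2.0
    return np.asarray(predictions)


def evaluate_model(model: GPModelHandle, test_points: np.ndarray,
                   observed_suppression_rates: np.ndarray) -> dict:
    """RMSE, precision and recall against observed suppression rates.

    Composite predictions are scaled from [-1, 1] to [0, 1] before RMSE.
    A point is an actual positive when its observed rate is >= 0.5; the
    model predicts positive when it predicts >= 0.5 (suppression-rate tag)
    or >= 0 (composite tag).  Precision is None when there are no predicted
    positives.
    """
    obs = np.asarray(observed_suppression_rates, float)
    if np.any((obs < 0) | (obs > 1)):
        raise ValueError("observed suppression rates must lie in [0, 1]")
    pred, _ = model.predict(test_points)
    scaled = np.clip(_rate_scale(model.output_type, pred), 0.0, 1.0)
    rmse = float(np.sqrt(np.mean((scaled - obs) ** 2)))
    if model.output_type == "composite":
        predicted_pos = pred >= 0.0
    else:
        predicted_pos = pred >= 0.5
    actual_pos = obs >= 0.5
    tp = int(np.sum(predicted_pos & actual_pos))
    fp = int(np.sum(predicted_pos & ~actual_pos))
    fn = int(np.sum(~predicted_pos & actual_pos))
    precision = None if tp + fp == 0 else tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    return {"rmse": rmse, "precision": precision, "recall": recall,
            "tp": tp, "fp": fp, "fn": fn}


# ---------------------------------------------------------------------------
# Adaptive training loop
# ---------------------------------------------------------------------------

def adaptive_training_loop(evaluator: Callable[[np.ndarray], tuple],
                           space: ParameterSpace, *,
                           initial_n: int = 1000, batch: int = 1000,
                           final_n: int = 10000,
                           candidate_pool_n: int = 100000,
                           validation_n: int = 1000,
                           uncertainty_fraction: float = 1.0 / 9.0,
                           iterations: int = 30000,
                           checkpoint_every: int = 1000,
                           learning_rate: float = 0.05,
                           seed: int = 0) -> dict:
    """Grow the training set adaptively and retrain both surrogates.

    `evaluator(X)` returns (composite values, suppression rates) for the
    rows of X.  Each round draws a fresh Latin-hypercube candidate pool and
    selects `batch` new points; a fraction of the adaptive budget
    (`uncertainty_fraction`, default 1/9 as in a 1000:8000 split of 9000
    points) uses pure uncertainty sampling, the rest the outcome-boundary
    rule.  Half of every batch is chosen by the composite model and half by
    the suppression-rate model.  Returns the two models plus a manifest
    listing every batch with its strategy labels.
    """
    rng = np.random.default_rng(seed)
    x = latin_hypercube(initial_n, space, seed=int(rng.integers(2 ** 31)))
    comp, supp = evaluator(x)
    comp = np.asarray(comp, float)
    supp = np.asarray(supp, float)
    val_x = latin_hypercube(validation_n, space, seed=int(rng.integers(2 ** 31)))
    val_comp, val_supp = (np.asarray(a, float) for a in evaluator(val_x))

    manifest = [{"round": 0, "strategy": "latin_hypercube", "n": int(initial_n)}]

    def retrain():
        mc = train_gp(x, comp, val_x, val_comp, space, "composite",
                      iterations=iterations,
                      checkpoint_every=checkpoint_every,
                      learning_rate=learning_rate)
        ms = train_gp(x, supp, val_x, val_supp, space, "suppression_rate",
                      iterations=iterations,
                      checkpoint_every=checkpoint_every,
                      learning_rate=learning_rate)
        return mc, ms

    model_c, model_s = retrain()
    n_adaptive = final_n - initial_n
    n_uncert = int(round(uncertainty_fraction * n_adaptive))
    taken = 0
    rnd = 0
    while taken < n_adaptive:
        rnd += 1
        b = min(batch, n_adaptive - taken)
        pool = latin_hypercube(candidate_pool_n, space,
                               seed=int(rng.integers(2 ** 31)))
        strategy = "uncertainty" if taken < n_uncert else "boundary"
        sampler = (adaptive_sample_uncertainty if strategy == "uncertainty"
                   else adaptive_sample_boundary)
        half = b // 2
        idx_c = sampler(model_c, pool, half, rng)
        idx_s = sampler(model_s, pool, b - half, rng)
        chosen = pool[np.concatenate([idx_c, idx_s])]
        new_comp, new_supp = (np.asarray(a, float) for a in evaluator(chosen))
        x = np.vstack([x, chosen])
        comp = np.concatenate([comp, new_comp])
        supp = np.concatenate([supp, new_supp])
        taken += b
        manifest.append({"round": rnd, "strategy": strategy, "n": int(b),
                         "selected_by": ["composite"] * half
                         + ["suppression_rate"] * (b - half)})
        model_c, model_s = retrain()
    return {"composite_model": model_c, "suppression_model": model_s,
            "manifest": manifest,
            "train_x": x, "train_composite": comp, "train_suppression": supp,
            "validation_x": val_x, "validation_suppression": val_supp}
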