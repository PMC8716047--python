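"""Continuous-space population mechanics.

Competition, survival, mate finding, dispersal, migration, and calibration
of the density tuning coefficient that pins the carrying capacity.

The population lives on a square island with "reprising" boundaries: any
dispersal draw landing outside the arena is fully redrawn (direction and
distance) until it falls inside.  Density-dependent mortality acts on
newborns and newly arrived migrants only; established non-migrant adults
face a flat mortality of 1 - s0 per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import CalibrationError, ParameterSet

FEMALE = 0
MALE = 1

# Allele codes shared with the genetics module.
WT, DRIVE, R1, R2, Y = 0, 1, 2, 3, 4

_MAX_REDRAWS = 100_000


@dataclass
class Landscape:
    """Square arena with reprising boundaries."""

    side_length: float  # meters

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        s = self.side_length
        return (x >= 0) & (x <= s) & (y >= 0) & (y <= s)


class Population:
    """Struct-of-arrays container for the individuals of one simulation.

    Positions in meters; `sex` is 0 (female) / 1 (male); `age` counts time
    steps since birth (adults are age >= 1); `migrant` marks individuals due
    density-dependent mortality at the next survival evaluation; `a1`/`a2`
    are allele codes (males under the Y-shredder hold their X allele in `a1`
    and the Y sentinel in `a2`).
    """

    __slots__ = ("x", "y", "sex", "age", "migrant", "a1", "a2", "uid",
                 "_next_uid")

    def __init__(self, x, y, sex, age, migrant, a1, a2, uid=None,
                 next_uid=None):
        n = len(x)
        self.x = np.asarray(x, np.float64)
        self.y = np.asarray(y, np.float64)
        self.sex = np.asarray(sex, np.int8)
        self.age = np.asarray(age, np.int32)
        self.migrant = np.asarray(migrant, bool)
        self.a1 = np.asarray(a1, np.int8)
        self.a2 = np.asarray(a2, np.int8)
        self.uid = (np.arange(n, dtype=np.int64) if uid is None
                    else np.asarray(uid, np.int64))
        self._next_uid = int(n if next_uid is None else next_uid)

    def __len__(self) -> int:
        return self.x.size

    @property
    def adult(self) -> np.ndarray:
        return self.age >= 1

    def keep(self, mask: np.ndarray) -> None:
        for name in ("x", "y", "sex", "age", "migrant", "a1", "a2", "uid"):
            setattr(self, name, getattr(self, name)[mask])

    def append(self, x, y, sex, a1, a2) -> None:
        n_new = len(x)
        uid = np.arange(self._next_uid, self._next_uid + n_new, dtype=np.int64)
        self._next_uid += n_new
        self.x = np.concatenate([self.x, x])
        self.y = np.concatenate([self.y, y])
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.int8)])
        self.age = np.concatenate([self.age, np.zeros(n_new, np.int32)])
        self.migrant = np.concatenate([self.migrant, np.zeros(n_new, bool)])
        self.a1 = np.concatenate([self.a1, np.asarray(a1, np.int8)])
        self.a2 = np.concatenate([self.a2, np.asarray(a2, np.int8)])
        self.uid = np.concatenate([self.uid, uid])

    @classmethod
    def initial(cls, params: ParameterSet, rng: np.random.Generator
                ) -> "Population":
        """K adults placed uniformly at random, sexes drawn 50:50."""
        k = params.carrying_capacity
        side = params.island_side_m
        x = rng.uniform(0.0, side, k)
        y = rng.uniform(0.0, side, k)
        sex = (rng.random(k) < 0.5).astype(np.int8)
        age = np.ones(k, np.int32)
        return cls(x, y, sex, age, np.zeros(k, bool),
                   np.zeros(k, np.int8), np.zeros(k, np.int8))


# ---------------------------------------------------------------------------
# Competition kernel and edge compensation
# ---------------------------------------------------------------------------

def competition_weight(distance, R: float):
    """Gaussian competition weight exp(-d^2 / (2 sigma^2)), sigma = R/3.

    The kernel has a maximum of one at d = 0 and is truncated to zero
    outside the interaction distance R.
    """
    d = np.asarray(distance, np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if R <= 0:
        raise ValueError("interaction distance must be positive")
    sigma = R / 3.0
    w = np.exp(-(d * d) / (2.0 * sigma * sigma))
    w = np.where(d > R, 0.0, w)
    return float(w) if np.isscalar(distance) else w


class _EdgeTable:
    """Cached table of edge-compensation factors.

    The correction depends only on the distances to the nearest x-edge and
    y-edge in units of R (sigma is tied to R), so a single normalized table
    over (alpha, beta) in [0, 1]^2 serves every parameter set.  Two weight
    modes are supported: "area" divides the full disc area by the in-bounds
    disc area; "kernel_mass" divides the truncated-Gaussian kernel mass over
    the full disc by the mass over the in-bounds part.  Integrals are
    midpoint sums on a fine grid, assembled for all table nodes at once with
    a 2-D suffix sum.
    """

    N_GRID = 1600   # quadrature cells per axis over [-1, 1]
    N_TAB = 161     # table nodes per axis over [0, 1]

    def __init__(self, method: str = "area") -> None:
        n = self.N_GRID
        h = 2.0 / n
        mids = -1.0 + h * (np.arange(n) + 0.5)
        u, v = np.meshgrid(mids, mids, indexing="ij")
        r2 = u * u + v * v
        density = np.exp(-4.5 * r2) if method == "kernel_mass" else 1.0
        w = np.where(r2 <= 1.0, density, 0.0) * h * h
        # suffix[i, j] = mass of cells with u >= mids[i], v >= mids[j]
        suffix = np.cumsum(np.cumsum(w[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
        suffix = np.pad(suffix, ((0, 1), (0, 1)))
        self.full_mass = float(suffix[0, 0])
        alphas = np.linspace(0.0, 1.0, self.N_TAB)
        # cell i covers u in [-1 + i*h, -1 + (i+1)*h): first cell fully at
        # u >= -alpha has left edge >= -alpha.
        first = np.ceil((1.0 - alphas) / h - 1e-9).astype(int)
        self.table = suffix[np.ix_(first, first)]
        self.alphas = alphas

    def factor(self, ax: np.ndarray, ay: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of full_mass / mass(alpha_x, alpha_y)."""
        step = 1.0 / (self.N_TAB - 1)
        fx = np.clip(ax, 0.0, 1.0) / step
        fy = np.clip(ay, 0.0, 1.0) / step
        i = np.minimum(fx.astype(int), self.N_TAB - 2)
        j = np.minimum(fy.astype(int), self.N_TAB - 2)
        tx = fx - i
        ty = fy - j
        t = self.table
        mass = (t[i, j] * (1 - tx) * (1 - ty) + t[i + 1, j] * tx * (1 - ty)
                + t[i, j + 1] * (1 - tx) * ty + t[i + 1, j + 1] * tx * ty)
        return self.full_mass / mass


_edge_tables: dict[str, _EdgeTable] = {}


def _get_edge_table(method: str = "area") -> _EdgeTable:
    if method not in ("area", "kernel_mass"):
        raise ValueError("edge compensation method must be 'area' or "
                         "'kernel_mass'")
    if method not in _edge_tables:
        _edge_tables[method] = _EdgeTable(method)
    return _edge_tables[method]


def edge_compensation(x, y, R: float, landscape: Landscape,
                      method: str = "area"):
    """Scale factor (>= 1) compensating for interaction area lost at edges.

    Individuals whose interaction disc extends beyond the boundary have
    fewer competitors; their summed competition is scaled up to compensate
    for the missing area.  The default divides the full disc area by the
    in-bounds disc area (exactly 2 on a straight edge, 4 in a corner);
    method="kernel_mass" instead uses the ratio of truncated-Gaussian
    kernel masses, which discounts the sparsely weighted disc rim.
    """
    scalar = np.ndim(x) == 0 and np.ndim(y) == 0
    x = np.atleast_1d(np.asarray(x, np.float64))
    y = np.atleast_1d(np.asarray(y, np.float64))
    side = landscape.side_length
    if np.any((x < 0) | (x > side) | (y < 0) | (y > side)):
        raise ValueError("position outside the landscape")
    ax = np.minimum(x, side - x) / R
    ay = np.minimum(y, side - y) / R
    scale = np.ones(np.broadcast(x, y).shape)
    near = (ax < 1.0) | (ay < 1.0)
    if np.any(near):
        tab = _get_edge_table(method)
        scale[near] = tab.factor(ax[near], ay[near])
    return float(scale[0]) if scalar else scale


# ---------------------------------------------------------------------------
# Carrying-capacity calibration
# ---------------------------------------------------------------------------

def average_competition(params: ParameterSet, truncated: bool = False) -> float:
    """Expected per-individual competition at carrying capacity.

    2 pi sigma^2 * D * (1 + L/2), where D is the expected adult density per
    m^2 and the (1 + L/2) factor counts newborns, which both exert and
    receive competition in their birth step.  With `truncated=True` the
    kernel integral runs over the actual interaction disc of radius R
    (= 3 sigma) instead of the whole plane, multiplying the closed form by
    1 - exp(-9/2); the capacity calibration uses the truncated value since
    the simulated kernel is cut off at R.
    """
    sigma = params.sigma
    dens_m2 = params.density / 1e6
    mass = 2.0 * math.pi * sigma * sigma
    if truncated:
        mass *= 1.0 - math.exp(-4.5)
    return mass * dens_m2 * (1.0 + params.litter_size / 2.0)


def solve_density_tuning(params: ParameterSet) -> float:
    """Density tuning coefficient c calibrating the equilibrium size.

    Setting N(t+1) = N(t) = K in
        N(t+1) = N(t) (1-M) s0 + N(t) (L/2 + M) s_d
    gives s_d = (1 - (1-M) s0) / (L/2 + M); then
        c = (s0 - s_d) / avg_competition.
    """
    s0 = params.survival_rate
    M = params.migrant_frequency
    L = params.litter_size
    denom = L / 2.0 + M
    if denom <= 0:
        raise CalibrationError("L/2 + M must be positive")
    s_d = (1.0 - (1.0 - M) * s0) / denom
    if s_d > s0:
        raise CalibrationError(
            f"required density-dependent survival {s_d:.4f} exceeds the flat "
            f"survival rate {s0}; the population cannot equilibrate")
    return (s0 - s_d) / average_competition(params, truncated=True)


def equilibrium_density_survival(params: ParameterSet) -> float:
    """The density-dependent survival rate s_d implied at equilibrium."""
    s0 = params.survival_rate
    M = params.migrant_frequency
    return (1.0 - (1.0 - M) * s0) / (params.litter_size / 2.0 + M)


# ---------------------------------------------------------------------------
# Dispersal / migration
# ---------------------------------------------------------------------------

def disperse(origin_x, origin_y, mean_distance: float, landscape: Landscape,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Displace each origin by a uniform direction and Exp(mean) distance.

    Out-of-bounds results redraw the entire displacement (reprising).
    """
    x0 = np.atleast_1d(np.asarray(origin_x, np.float64)).copy()
    y0 = np.atleast_1d(np.asarray(origin_y, np.float64)).copy()
    x = np.empty_like(x0)
    y = np.empty_like(y0)
    pending = np.arange(x0.size)
    for _ in range(_MAX_REDRAWS):
        theta = rng.uniform(0.0, 2.0 * math.pi, pending.size)
        dist = rng.exponential(mean_distance, pending.size) \
            if mean_distance > 0 else np.zeros(pending.size)
        cx = x0[pending] + dist * np.cos(theta)
        cy = y0[pending] + dist * np.sin(theta)
        ok = landscape.contains(cx, cy)
        x[pending[ok]] = cx[ok]
        y[pending[ok]] = cy[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return x, y
    raise RuntimeError("reprising boundary failed to settle after "
                       f"{_MAX_REDRAWS} redraw rounds")


def migration_step(pop: Population, params: ParameterSet,
                   rng: np.random.Generator) -> Population:
    """Each adult migrates with probability M; migrants are flagged.

    Migrant displacement draws from Exp(avg_dispersal * multiplier).
    Juveniles never migrate.  The migrant flag triggers density-dependent
    mortality at the next survival evaluation.
    """
    adults = pop.adult
    move = adults & (rng.random(len(pop)) < params.migrant_frequency)
    idx = np.flatnonzero(move)
    if idx.size:
        landscape = Landscape(params.island_side_m)
        mean = params.avg_dispersal * params.adult_dispersal_multiplier
        nx, ny = disperse(pop.x[idx], pop.y[idx], mean, landscape, rng)
        pop.x[idx] = nx
        pop.y[idx] = ny
        pop.migrant[idx] = True
    return pop


# ---------------------------------------------------------------------------
# Mate choice
# ---------------------------------------------------------------------------

def select_mate(female_xy, male_x, male_y, R: float,
                rng: np.random.Generator) -> int:
    """Uniform random choice among adult males within distance R.

    Returns the index into the male arrays, or -1 if no male is in range.
    """
    fx, fy = female_xy
    d2 = (np.asarray(male_x) - fx) ** 2 + (np.asarray(male_y) - fy) ** 2
    cand = np.flatnonzero(d2 <= R * R)
    if cand.size == 0:
        return -1
    return int(cand[min(int(rng.random() * cand.size), cand.size - 1)])


def find_mates(female_x, female_y, male_x, male_y, params: ParameterSet,
               rng: np.random.Generator) -> np.ndarray:
    """Vectorized mate search for all females at once (cell-list kernel).

    Returns, per female, the index into the male arrays of the selected mate
    (-1 when no adult male lies within the home range).  The same male can
    be chosen by any number of females.
    """
    n_f = len(female_x)
    if n_f == 0 or len(male_x) == 0:
        return np.full(n_f, -1, np.int64)
    R = params.interaction_distance
    side = params.island_side_m
    cell_size, ncx, ncy = _kernels.grid_spec(side, R)
    start, order = _kernels.build_cell_list(
        np.ascontiguousarray(male_x), np.ascontiguousarray(male_y),
        cell_size, ncx, ncy)
    u = rng.random(n_f)
    return _kernels.choose_mates(
        np.ascontiguousarray(female_x), np.ascontiguousarray(female_y),
        np.ascontiguousarray(male_x), np.ascontiguousarray(male_y),
        R, cell_size, ncx, ncy, start, order, u)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def competition_totals(pop: Population, params: ParameterSet,
                       targets: np.ndarray | None = None) -> np.ndarray:
    """Edge-uncorrected summed competition for the target individuals."""
    if targets is None:
        targets = np.arange(len(pop))
    R = params.interaction_distance
    side = params.island_side_m
    cell_size, ncx, ncy = _kernels.grid_spec(side, R)
    start, order = _kernels.build_cell_list(pop.x, pop.y, cell_size, ncx, ncy)
    return _kernels.competition_sums(
        pop.x, pop.y, np.asarray(targets, np.int64), R, params.sigma,
        cell_size, ncx, ncy, start, order)


def survival_probabilities(pop: Population, tuning_c: float,
                           params: ParameterSet) -> np.ndarray:
    """Per-individual survival probability for the current step.

    Non-migrant adults survive with the flat rate s0.  Newborns and newly
    arrived migrants survive with s0 - c * (edge-compensated summed
    competition), clamped to [0, 1].  Drive carriers multiply either rate by
    the drive fitness parameter.
    """
    n = len(pop)
    p = np.full(n, params.survival_rate)
    dd = np.flatnonzero((pop.age == 0) | pop.migrant)
    if dd.size:
        comp = competition_totals(pop, params, dd)
        landscape = Landscape(params.island_side_m)
        scale = edge_compensation(pop.x[dd], pop.y[dd],
                                  params.interaction_distance, landscape)
        p[dd] = params.survival_rate - tuning_c * scale * comp
    if params.drive_fitness < 1.0:
        carrier = (pop.a1 == DRIVE) | (pop.a2 == DRIVE)
        p[carrier] *= params.drive_fitness
    return np.clip(p, 0.0, 1.0)


def survival_step(pop: Population, tuning_c: float, params: ParameterSet,
                  rng: np.random.Generator) -> Population:
    """Apply one round of mortality; migrant flags are cleared afterwards."""
    p = survival_probabilities(pop, tuning_c, params)
    survive = rng.random(len(pop)) < p
    pop.keep(survive)
    pop.migrant[:] = False
    return pop
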