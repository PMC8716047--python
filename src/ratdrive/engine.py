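"""Simulation lifecycle: initialization, equilibration, release, outcomes.

Each time step runs, in order: (1) reproduction, (2) mortality (including
density-dependent mortality of newborns and new migrants, and the optional
traditional-control removal), (3) migration, (4) age increment.  The
population is initialized at the expected carrying capacity, equilibrates
for 20 steps, then the drive is released and the simulation continues for
up to 500 further steps or until the population is eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from . import demography, genetics
from .demography import (DRIVE, FEMALE, MALE, R1, R2, WT, Y, Landscape,
                         Population)
from .params import DriveType, ParameterSet

EQUILIBRATION_STEPS = 20
MAX_POST_RELEASE_STEPS = 500
CAPACITY_WINDOW = 10


@dataclass
class SimulationResult:
    """Outcome record of a single run.

    `measured_capacity` averages the population over the ten steps before
    release; `elimination_step` counts post-release steps (1..500) and is
    None when the population persists.
    """

    measured_capacity: float
    min_pop: int
    final_pop: int
    drive_freq: float | None
    resistance_freq: float | None
    elimination_step: int | None
    eliminated: bool
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "measured_capacity": self.measured_capacity,
            "min_pop": self.min_pop,
            "final_pop": self.final_pop,
            "drive_freq": self.drive_freq,
            "resistance_freq": self.resistance_freq,
            "elimination_step": self.elimination_step,
            "eliminated": self.eliminated,
            "seed": self.seed,
        }


@dataclass
class DemographyRecord:
    """Optional per-run demographic bookkeeping for validation statistics."""

    pop_sizes: list[int] = field(default_factory=list)
    census_ages: list[np.ndarray] = field(default_factory=list)
    death_ages: list[int] = field(default_factory=list)
    positions: dict[int, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)
    census_range: tuple[int, int] = (100, 500)
    birth_cutoff: int = 100
    snapshot_steps: frozenset[int] = frozenset()
    snapshots: list[tuple[int, dict]] = field(default_factory=list)


def allele_frequencies(pop: Population,
                       drive_type: DriveType | None = None
                       ) -> dict[str, float] | None:
    """Allele frequencies over all allele slots (X slots only for Y-shredder).

    Returns None for an empty population.
    """
    if len(pop) == 0:
        return None
    alleles = np.concatenate([pop.a1, pop.a2])
    alleles = alleles[alleles != Y]
    total = alleles.size
    return {
        "wt": float(np.count_nonzero(alleles == WT) / total),
        "drive": float(np.count_nonzero(alleles == DRIVE) / total),
        "r1": float(np.count_nonzero(alleles == R1) / total),
        "r2": float(np.count_nonzero(alleles == R2) / total),
    }


def _reproduce(pop: Population, params: ParameterSet,
               rng: np.random.Generator) -> None:
    """Phase 1: mate finding, litters, gamete transmission, placement."""
    drive = params.drive_type
    adults = pop.adult
    female = adults & (pop.sex == FEMALE)
    if drive is DriveType.FEMALE_FERTILITY_HOMING:
        sterile = ((pop.a1 == DRIVE) | (pop.a1 == R2)) & \
                  ((pop.a2 == DRIVE) | (pop.a2 == R2))
        female &= ~sterile
    female_idx = np.flatnonzero(female)
    male_idx = np.flatnonzero(adults & (pop.sex == MALE))
    if female_idx.size == 0 or male_idx.size == 0:
        return
    mates = demography.find_mates(pop.x[female_idx], pop.y[female_idx],
                                  pop.x[male_idx], pop.y[male_idx],
                                  params, rng)
    mated = mates >= 0
    mothers = female_idx[mated]
    fathers = male_idx[mates[mated]]
    litters = rng.poisson(params.litter_size, mothers.size)
    mom = np.repeat(mothers, litters)
    dad = np.repeat(fathers, litters)
    n_off = mom.size
    if n_off == 0:
        return

    if drive is DriveType.Y_SHREDDER:
        father_x = pop.a1[dad]
        p_female = np.where(father_x == DRIVE,
                            0.5 + 0.5 * params.drive_efficiency, 0.5)
        is_female = rng.random(n_off) < p_female
        maternal = np.where(rng.random(n_off) < 0.5,
                            pop.a1[mom], pop.a2[mom]).astype(np.int8)
        a1 = np.where(is_female, father_x, maternal).astype(np.int8)
        a2 = np.where(is_female, maternal, Y).astype(np.int8)
        sex = np.where(is_female, FEMALE, MALE).astype(np.int8)
    else:
        if drive is None:
            a1 = np.zeros(n_off, np.int8)
            a2 = np.zeros(n_off, np.int8)
        else:
            a1 = genetics.homing_gametes(pop.a1[mom], pop.a2[mom], params, rng)
            a2 = genetics.homing_gametes(pop.a1[dad], pop.a2[dad], params, rng)
        sex = (rng.random(n_off) < 0.5).astype(np.int8)
        if drive is DriveType.VIABILITY_HOMING:
            disrupted = ((a1 == DRIVE) | (a1 == R2)) & \
                        ((a2 == DRIVE) | (a2 == R2))
            viable = ~disrupted
            mom, a1, a2, sex = mom[viable], a1[viable], a2[viable], sex[viable]
            n_off = mom.size
            if n_off == 0:
                return

    landscape = Landscape(params.island_side_m)
    ox, oy = demography.disperse(pop.x[mom], pop.y[mom],
                                 params.avg_dispersal, landscape, rng)
    pop.append(ox, oy, sex, a1, a2)


def _mortality(pop: Population, tuning_c: float, params: ParameterSet,
               rng: np.random.Generator, step: int,
               record: DemographyRecord | None) -> None:
    """Phase 2: survival draws plus optional traditional-control removal."""
    n = len(pop)
    p = demography.survival_probabilities(pop, tuning_c, params)
    survive = rng.random(n) < p
    if params.traditional_control_rate > 0.0 and n > 0:
        k = int(round(params.traditional_control_rate * n))
        if k > 0:
            culled = rng.choice(n, size=min(k, n), replace=False)
            survive[culled] = False
    if record is not None:
        died = ~survive
        birth_step = step - pop.age[died]
        keep = (pop.age[died] >= 1) & (birth_step > record.birth_cutoff)
        record.death_ages.extend(int(a) for a in pop.age[died][keep])
    pop.keep(survive)
    pop.migrant[:] = False
    if record is not None and record.census_range[0] <= step <= record.census_range[1]:
        record.census_ages.append(pop.age.copy())


def step_population(pop: Population, params: ParameterSet, tuning_c: float,
                    rng: np.random.Generator, step: int = 0,
                    record: DemographyRecord | None = None) -> Population:
    """Advance the population by one full time step.

    Phases: reproduction, mortality, migration, age increment.  Migrants
    flagged during this step's migration phase face density-dependent
    survival at their new location in the *next* step's mortality phase
    (the flag is cleared once consumed).
    """
    _reproduce(pop, params, rng)
    _mortality(pop, tuning_c, params, rng, step, record)
    demography.migration_step(pop, params, rng)
    pop.age += 1
    if record is not None:
        record.pop_sizes.append(len(pop))
        if step in record.positions:
            record.positions[step] = (pop.x.copy(), pop.y.copy())
        if step in record.snapshot_steps:
            record.snapshots.append((step, {
                "id": pop.uid.copy(), "x": pop.x.copy(), "y": pop.y.copy(),
                "sex": pop.sex.copy(), "age": pop.age.copy(),
                "genotype": genetics.genotype_codes(pop),
            }))
    return pop


def run_simulation(params: ParameterSet, seed: int, *,
                   record: DemographyRecord | None = None,
                   equilibration_steps: int = EQUILIBRATION_STEPS,
                   max_post_release_steps: int = MAX_POST_RELEASE_STEPS,
                   ) -> SimulationResult:
    """Run one complete simulation and record its outcome.

    The drive (if any, and if release_percentage > 0) is released after the
    equilibration phase; the run then continues for up to
    `max_post_release_steps` steps or until the population hits zero.
    """
    rng = np.random.default_rng(seed)
    tuning_c = demography.solve_density_tuning(params)
    pop = Population.initial(params, rng)
    sizes = []
    for t in range(1, equilibration_steps + 1):
        step_population(pop, params, tuning_c, rng, t, record)
        sizes.append(len(pop))
        if len(pop) == 0:
            break

    window = sizes[-CAPACITY_WINDOW:] if sizes else [0]
    measured_capacity = float(np.mean(window))

    releasing = (params.drive_type is not None
                 and params.release_percentage > 0 and len(pop) > 0)
    if releasing:
        genetics.release_drive(pop, params.release_percentage,
                               params.drive_type, rng)

    min_pop = len(pop)
    elimination_step = None
    for t_post in range(1, max_post_release_steps + 1):
        if len(pop) == 0:
            elimination_step = t_post - 1 if elimination_step is None else elimination_step
            break
        step_population(pop, params, tuning_c, rng,
                        equilibration_steps + t_post, record)
        n = len(pop)
        min_pop = min(min_pop, n)
        if n == 0:
            elimination_step = t_post
            break
    eliminated = len(pop) == 0

    freqs = allele_frequencies(pop, params.drive_type)
    if not np.isfinite(measured_capacity):
        raise RuntimeError("non-finite measured capacity")
    return SimulationResult(
        measured_capacity=measured_capacity,
        min_pop=int(min_pop),
        final_pop=len(pop),
        drive_freq=None if freqs is None else freqs["drive"],
        resistance_freq=None if freqs is None else freqs["r1"] + freqs["r2"],
        elimination_step=elimination_step,
        eliminated=eliminated,
        seed=seed,
    )


def composite_value(result: SimulationResult,
                    max_steps: int = MAX_POST_RELEASE_STEPS) -> float:
    """Continuous success/failure statistic in [-1, 1].

    1 - t_supp/500 when the population was eliminated at post-release step
    t_supp, else -min_pop / measured_capacity.  Values near one are rapid
    suppressions; zero is the weakest possible success; values near minus
    one are drives that left the population untouched.
    """
    if result.eliminated:
        if result.elimination_step is None:
            raise ValueError("eliminated result lacks an elimination step")
        return 1.0 - result.elimination_step / max_steps
    if result.measured_capacity <= 0:
        raise ValueError("measured capacity must be positive for failed runs")
    return -result.min_pop / result.measured_capacity


@dataclass
class ReplicateSummary:
    suppression_rate: float
    mean_composite: float
    mean_elimination_step: float | None
    results: list[SimulationResult]


def replicate_summary(params: ParameterSet, n_reps: int, seed_base: int,
                      ) -> ReplicateSummary:
    """Run n_reps independent replicates (seeds seed_base + i) and average.

    `mean_elimination_step` averages over successful replicates only and is
    None when no replicate eliminated the population.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = [run_simulation(params, seed_base + i) for i in range(n_reps)]
    elim = [r.elimination_step for r in results if r.eliminated]
    return ReplicateSummary(
        suppression_rate=sum(r.eliminated for r in results) / n_reps,
        mean_composite=float(np.mean([composite_value(r) for r in results])),
        mean_elimination_step=float(np.mean(elim)) if elim else None,
        results=results,
    )
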