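"""Drive genetics: gamete transmission, fertility/viability, sex biasing.

Allele codes: 0 = wild type (wt), 1 = drive (d), 2 = r1 resistance
(functional target gene), 3 = r2 resistance (disrupted target gene),
4 = Y chromosome sentinel.  Homing drives are autosomal; under the
Y-shredder the drive locus is X-linked, females carry two X alleles and
males carry one X allele (slot 1) plus Y (slot 2).

Homing occurs in germline cells at gamete formation.  Each gamete from a
drive/wild-type heterozygote first tests resistance-allele formation at
rate rho (a fraction `relative_r1_rate` of which yield r1, the rest r2);
only if no resistance forms can the wild-type allele be converted to drive
with probability e (the drive efficiency).  A higher resistance rate
therefore reduces the realized conversion rate at fixed efficiency.
"""

from __future__ import annotations

import math

import numpy as np

from .demography import DRIVE, FEMALE, MALE, R1, R2, WT, Y, Population
from .params import ConfigError, DriveType, ParameterSet

ALLELE_NAMES = {WT: "wt", DRIVE: "d", R1: "r1", R2: "r2", Y: "Y"}
_HOMING = (DriveType.FEMALE_FERTILITY_HOMING, DriveType.VIABILITY_HOMING)


class UnsupportedDriveError(ValueError):
    """Operation called for a drive type it does not apply to."""


def transmission_distribution(genotype: tuple[int, int], efficiency: float,
                              resistance_rate: float, relative_r1_rate: float,
                              drive_type: DriveType = DriveType.FEMALE_FERTILITY_HOMING
                              ) -> dict[int, float]:
    """Per-gamete allele probabilities for a homing-drive parent.

    Each parental allele is drawn with probability 1/2.  A wild-type allele
    drawn from a drive/wild-type heterozygote is subject to germline
    resistance formation and homing as described in the module docstring;
    all other alleles transmit unchanged.
    """
    if drive_type not in _HOMING:
        raise UnsupportedDriveError(
            "transmission_distribution applies to homing drives only")
    a1, a2 = genotype
    probs = {WT: 0.0, DRIVE: 0.0, R1: 0.0, R2: 0.0}
    het = {a1, a2} == {DRIVE, WT}
    for allele in (a1, a2):
        if het and allele == WT:
            rho, e = resistance_rate, efficiency
            probs[R1] += 0.5 * rho * relative_r1_rate
            probs[R2] += 0.5 * rho * (1.0 - relative_r1_rate)
            probs[DRIVE] += 0.5 * (1.0 - rho) * e
            probs[WT] += 0.5 * (1.0 - rho) * (1.0 - e)
        else:
            probs[allele] += 0.5
    return probs


def is_fertile_female(genotype: tuple[int, int], drive_type: DriveType) -> bool:
    """Fertility of a female under the female-fertility homing drive.

    The target gene is haplosufficient: a female is sterile iff both copies
    are disrupted, i.e. both alleles are drive or r2.
    """
    if drive_type is not DriveType.FEMALE_FERTILITY_HOMING:
        return True
    return not all(a in (DRIVE, R2) for a in genotype)


def is_viable(genotype: tuple[int, int], drive_type: DriveType) -> bool:
    """Viability of an offspring under the viability-target homing drive.

    Offspring with both alleles disrupted (drive or r2) are removed
    immediately when generated and are never placed in the population.
    """
    if drive_type is not DriveType.VIABILITY_HOMING:
        return True
    return not all(a in (DRIVE, R2) for a in genotype)


def female_offspring_probability(father_carries_drive: bool,
                                 efficiency: float) -> float:
    """P(offspring is female) under the Y-shredder.

    Shredding converts a fraction e of the normally male-destined half of
    offspring to females: P(F) = 0.5 + 0.5 e for carrier fathers, 0.5
    otherwise.
    """
    return 0.5 + 0.5 * efficiency if father_carries_drive else 0.5


def offspring_sex_and_x_allele(father_genotype: tuple[int, int],
                               mother_genotype: tuple[int, int],
                               efficiency: float,
                               rng: np.random.Generator
                               ) -> tuple[int, tuple[int, int]]:
    """Draw sex and alleles for one Y-shredder offspring.

    Daughters inherit the father's X allele plus one maternal X allele
    (50:50); sons inherit Y plus one maternal X allele.  Carrier fathers
    bias the sex ratio toward daughters.
    """
    father_x = father_genotype[0]
    carrier = father_x == DRIVE
    p_female = female_offspring_probability(carrier, efficiency)
    maternal = mother_genotype[0] if rng.random() < 0.5 else mother_genotype[1]
    if rng.random() < p_female:
        return FEMALE, (father_x, maternal)
    return MALE, (maternal, Y)


def fitness_multiplier(genotype: tuple[int, int], drive_fitness: float) -> float:
    """Per-step survival multiplier: drive_fitness for any drive carrier.

    The cost is dominant (equal for heterozygotes and homozygotes) and acts
    only on survival.
    """
    return drive_fitness if DRIVE in genotype else 1.0


def release_drive(pop: Population, release_percentage: float,
                  drive_type: DriveType, rng: np.random.Generator
                  ) -> np.ndarray:
    """Convert floor(release_percentage * N) individuals to drive carriers.

    Homing drives produce autosomal drive/wild-type heterozygotes; under the
    Y-shredder the drive replaces one X allele (males: the single X).
    Released individuals are flagged like new migrants so they immediately
    face density-dependent mortality.  Returns the released indices.
    """
    if not 0.0 < release_percentage <= 1.0:
        raise ConfigError("release_percentage must lie in (0, 1]")
    n_rel = int(math.floor(release_percentage * len(pop)))
    idx = rng.choice(len(pop), size=n_rel, replace=False)
    idx = np.sort(idx)
    pop.a1[idx] = DRIVE
    if drive_type is DriveType.Y_SHREDDER:
        # females: second X untouched; males: slot 2 is already Y
        pass
    else:
        pop.a2[idx] = WT
    pop.migrant[idx] = True
    return idx


# ---------------------------------------------------------------------------
# Vectorized offspring generation (used by the engine)
# ---------------------------------------------------------------------------

def homing_gametes(a1: np.ndarray, a2: np.ndarray, params: ParameterSet,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete allele per parent row (vectorized).

    `a1`/`a2` give the parental genotype for each required gamete; draws are
    independent across rows.
    """
    n = a1.size
    pick2 = rng.random(n) < 0.5
    chosen = np.where(pick2, a2, a1).astype(np.int8)
    het = ((a1 == DRIVE) & (a2 == WT)) | ((a1 == WT) & (a2 == DRIVE))
    u = rng.random(n)
    rho = params.resistance_rate
    e = params.drive_efficiency
    r1f = params.relative_r1_rate
    target = het & (chosen == WT)
    out = chosen.copy()
    out[target & (u < rho * r1f)] = R1
    out[target & (u >= rho * r1f) & (u < rho)] = R2
    out[target & (u >= rho) & (u < rho + (1.0 - rho) * e)] = DRIVE
    return out


def genotype_codes(pop: Population) -> np.ndarray:
    """Snapshot string codes like "wt,wt", "d,r2", "d,Y"."""
    names = np.array([ALLELE_NAMES[k] for k in range(5)])
    return np.char.add(np.char.add(names[pop.a1], ","), names[pop.a2])
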