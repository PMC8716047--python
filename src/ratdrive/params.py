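"""Model parameters for the island rodent suppression-drive simulation.

The model has eight demographic/ecological parameters and five drive-related
parameters.  Distances are handled in meters internally; the island side
length is configured in kilometers (as in the published parameter table) and
converted once on access.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


class DriveType(enum.Enum):
    """Suppression drive strategies.

    FEMALE_FERTILITY_HOMING
        Homing drive disrupting an essential, haplosufficient female
        fertility gene; drive-homozygous females are sterile.
    VIABILITY_HOMING
        Homing drive disrupting an essential, haplosufficient viability
        gene; drive-homozygous offspring are never generated.
    Y_SHREDDER
        Non-homing X-linked drive that destroys Y-bearing gametes in
        carrier males, biasing offspring toward females.
    """

    FEMALE_FERTILITY_HOMING = "female_fertility_homing"
    VIABILITY_HOMING = "viability_homing"
    Y_SHREDDER = "y_shredder"


#: (minimum, default, maximum) for each demographic/ecological parameter.
DEMOGRAPHIC_RANGES: dict[str, tuple[float, float, float]] = {
    "density": (600.0, 1000.0, 1500.0),          # individuals / km^2
    "island_side": (1.0, 2.0, 5.0),              # km
    "interaction_distance": (60.0, 75.0, 300.0), # m
    "avg_dispersal": (25.0, 250.0, 1000.0),      # m
    "survival_rate": (0.7, 0.9, 0.95),
    "litter_size": (2.0, 4.0, 8.0),
    "migrant_frequency": (0.0, 0.1, 0.5),
    "adult_dispersal_multiplier": (1.0, 2.0, 5.0),
}

#: (minimum, default, maximum) for drive parameters.  The fitness/efficiency
#: minimum is 0.5 when homing drives are modeled without resistance and 0.75
#: otherwise; range validation uses the permissive 0.5 bound.
DRIVE_RANGES: dict[str, tuple[float, float, float]] = {
    "release_percentage": (0.01, 0.1, 0.5),
    "drive_fitness": (0.5, 1.0, 1.0),
    "drive_efficiency": (0.5, 1.0, 1.0),
    "resistance_rate": (0.0, 0.0, 0.1),
    "relative_r1_rate": (0.0, 0.0, 0.02),
}


class ConfigError(ValueError):
    """Raised for invalid or out-of-range parameter configurations."""


class CalibrationError(ValueError):
    """Raised when no density tuning coefficient can equilibrate the system."""


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterization of one simulation.

    Attributes
    ----------
    density : float
        Expected population density, individuals per km^2.
    island_side : float
        Side length of the square island, km.
    interaction_distance : float
        Radius (m) of the home range / competition neighborhood.
    avg_dispersal : float
        Mean (m) of the exponential natal-dispersal distance.
    survival_rate : float
        Flat per-step survival probability of non-migrant adults (s0).
    litter_size : float
        Mean of the Poisson litter-size distribution (L).
    migrant_frequency : float
        Per-step migration probability of each adult (M).
    adult_dispersal_multiplier : float
        Factor applied to avg_dispersal for migrating adults.
    release_percentage : float
        Fraction of the population converted to drive heterozygotes at
        release; 0 means no release.
    drive_fitness : float
        Per-step survival multiplier for drive carriers (dominant cost).
    drive_efficiency : float
        Homing drives: germline conversion probability (e).  Y-shredder:
        fraction of the male-destined half of offspring converted to female.
    resistance_rate : float
        Probability (rho) that a wild-type allele in a drive/wild-type
        heterozygote germline becomes a resistance allele.
    relative_r1_rate : float
        Fraction of resistance events yielding functional r1 alleles.
    drive_type : DriveType or None
        Which drive is simulated; None disables drive mechanics entirely.
    traditional_control_rate : float
        Fraction of the population removed uniformly at random each step
        during the mortality phase (0 disables).
    """

    density: float = 1000.0
    island_side: float = 2.0
    interaction_distance: float = 75.0
    avg_dispersal: float = 250.0
    survival_rate: float = 0.9
    litter_size: float = 4.0
    migrant_frequency: float = 0.1
    adult_dispersal_multiplier: float = 2.0
    release_percentage: float = 0.1
    drive_fitness: float = 1.0
    drive_efficiency: float = 1.0
    resistance_rate: float = 0.0
    relative_r1_rate: float = 0.0
    drive_type: DriveType | None = None
    traditional_control_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("survival_rate", "drive_fitness", "drive_efficiency",
                     "resistance_rate", "relative_r1_rate", "migrant_frequency",
                     "traditional_control_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v!r} must lie in [0, 1]")
        if not 0.0 <= self.release_percentage <= 1.0:
            raise ConfigError("release_percentage must lie in [0, 1]")
        if self.island_side <= 0:
            raise ConfigError("island_side must be positive")
        if self.interaction_distance <= 0:
            raise ConfigError("interaction_distance must be positive")
        if self.interaction_distance >= self.island_side_m:
            raise ConfigError(
                "interaction_distance must be smaller than the island side")
        if self.avg_dispersal < 0 or self.litter_size < 0 or self.density <= 0:
            raise ConfigError("density/dispersal/litter_size out of range")

    # -- derived quantities -------------------------------------------------

    @property
    def island_side_m(self) -> float:
        """Island side length in meters."""
        return self.island_side * 1000.0

    @property
    def sigma(self) -> float:
        """Std. dev. (m) of the Gaussian competition kernel: R / 3."""
        return self.interaction_distance / 3.0

    @property
    def carrying_capacity(self) -> int:
        """Expected carrying capacity K = density * island area."""
        return int(round(self.density * self.island_side ** 2))

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["drive_type"] = self.drive_type.value if self.drive_type else None
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any], strict: bool = False) -> "ParameterSet":
        """Build a ParameterSet from a flat key/value mapping.

        Unknown keys raise :class:`ConfigError`.  In *strict* mode, values
        outside the published parameter-table ranges are also rejected.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown parameter keys: {', '.join(unknown)}")
        kwargs = dict(raw)
        dt = kwargs.get("drive_type")
        if isinstance(dt, str):
            try:
                kwargs["drive_type"] = DriveType(dt)
            except ValueError as exc:
                names = ", ".join(t.value for t in DriveType)
                raise ConfigError(
                    f"drive_type must be one of: {names} (got {dt!r})") from exc
        for key, val in kwargs.items():
            if key == "drive_type":
                continue
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ConfigError(f"parameter {key} must be numeric, got {val!r}")
        if strict:
            offenders = []
            for key, (lo, _, hi) in {**DEMOGRAPHIC_RANGES, **DRIVE_RANGES}.items():
                if key in kwargs and not lo <= float(kwargs[key]) <= hi:
                    offenders.append(f"{key}={kwargs[key]} outside [{lo}, {hi}]")
            if offenders:
                raise ConfigError("out-of-range values: " + "; ".join(offenders))
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text)


def load_parameters(path: str | Path, strict: bool = False) -> ParameterSet:
    """Parse a flat YAML/JSON parameter file; missing keys take defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a key/value mapping")
    return ParameterSet.from_dict(raw, strict=strict)


def paper_defaults(**overrides: Any) -> ParameterSet:
    """The default parameter preset (Table 1/2 default column)."""
    return ParameterSet(**overrides)
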