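"""Shared domain types for the SIP pipeline.

Conventions used throughout the package:

* isotope treatments are the strings ``"12C"`` and ``"13C"``;
* compartments are ``"bulk_soil"``, ``"rhizosphere"``, ``"endosphere"`` and
  ``"unplanted_control"``;
* buoyant densities are in g/mL, DNA masses in µg;
* the replicate field is a positive integer, or the string ``"pooled"`` for
  gradients run on DNA pooled across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

ISOTOPES = ("12C", "13C")
COMPARTMENTS = ("bulk_soil", "rhizosphere", "endosphere", "unplanted_control")
PLANTED_COMPARTMENTS = ("rhizosphere", "endosphere")
ROLES = ("exudate_metabolizer", "autotroph", "bystander")
FRACTION_CLASSES = ("H", "L")

Replicate = Union[int, str]


class ConfigurationError(ValueError):
    """Raised for invalid designs, models, or run configurations."""


class DataError(ValueError):
    """Raised for invalid or degenerate input data."""


def _check_isotope(isotope: str) -> str:
    if isotope not in ISOTOPES:
        raise ConfigurationError(f"unknown isotope {isotope!r}; expected one of {ISOTOPES}")
    return isotope


def _check_compartment(compartment: str) -> str:
    if compartment not in COMPARTMENTS:
        raise ConfigurationError(
            f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}"
        )
    return compartment


@dataclass(frozen=True)
class TaxonSpec:
    """A simulated taxon.

    ``atom_excess`` maps ``(isotope, compartment)`` to the ¹³C atom fraction
    excess A (0–1) that the taxon's DNA acquires under that treatment.
    Treatments absent from the map default to A = 0.
    """

    taxon_id: str
    genus: str
    phylum: str
    gc: float
    role: str
    atom_excess: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigurationError(f"taxon {self.taxon_id}: gc={self.gc} outside [0, 1]")
        if self.role not in ROLES:
            raise ConfigurationError(f"taxon {self.taxon_id}: unknown role {self.role!r}")
        for (isotope, compartment), a in self.atom_excess.items():
            _check_isotope(isotope)
            _check_compartment(compartment)
            if not 0.0 <= a <= 1.0:
                raise ConfigurationError(
                    f"taxon {self.taxon_id}: atom excess {a} outside [0, 1]"
                )
            if isotope == "12C" and a > 0:
                raise ConfigurationError(
                    f"taxon {self.taxon_id}: nonzero atom excess under 12C treatment"
                )

    def atom_excess_for(self, isotope: str, compartment: str) -> float:
        return float(self.atom_excess.get((isotope, compartment), 0.0))


@dataclass(frozen=True)
class CommunityProfile:
    """Relative-abundance profile of one sample (compartment × replicate)."""

    compartment: str
    replicate: Replicate
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_compartment(self.compartment)
        vals = np.asarray(list(self.proportions.values()), dtype=float)
        if vals.size == 0:
            raise DataError("empty community profile")
        if (vals < 0).any():
            raise DataError("negative proportion in community profile")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise DataError(f"proportions sum to {vals.sum()}, expected 1 ± 1e-9")


@dataclass(frozen=True)
class GradientModel:
    """Linear GC–buoyant-density model with a full-label density shift.

    density(gc, A) = rho0_intercept + rho0_slope_per_gc * gc
                     + A * delta_rho_full_label
    """

    rho0_intercept: float = 1.660
    rho0_slope_per_gc: float = 0.098
    delta_rho_full_label: float = 0.036
    band_sd: float = 0.006
    n_fractions: int = 12
    density_min: float = 1.690
    density_max: float = 1.760

    def __post_init__(self) -> None:
        if self.density_min >= self.density_max:
            raise ConfigurationError("density_min must be < density_max")
        if self.n_fractions < 4:
            raise ConfigurationError("need at least 4 gradient fractions")
        if self.band_sd <= 0:
            raise ConfigurationError("band_sd must be positive")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.density_min, self.density_max, self.n_fractions + 1)


@dataclass(frozen=True)
class SequencingModel:
    """Read-count and qPCR noise model for simulated fractions."""

    library_size: int = 50_000
    qpcr_noise_cv: float = 0.10
    copies_per_ug: float = 1e9

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        if self.qpcr_noise_cv < 0:
            raise ConfigurationError("qpcr_noise_cv must be non-negative")


@dataclass
class FractionProfile:
    """One gradient fraction: buoyant density, 16S copies, optional genus counts."""

    fraction_index: int
    density: float
    copies: float
    counts: Optional[dict[str, int]] = None
    taxon_mass: Optional[dict[str, float]] = None  # simulator truth, µg per taxon

    def __post_init__(self) -> None:
        if not 1.60 <= self.density <= 1.80:
            raise DataError(
                f"fraction {self.fraction_index}: density {self.density} outside [1.60, 1.80]"
            )
        if self.copies < 0:
            raise DataError(f"fraction {self.fraction_index}: negative copy number")


@dataclass
class GradientRun:
    """One ultracentrifugation gradient with its ordered fractions."""

    isotope: str
    compartment: str
    replicate: Replicate
    dna_mass_loaded: float
    fractions: list[FractionProfile]

    def __post_init__(self) -> None:
        _check_isotope(self.isotope)
        _check_compartment(self.compartment)
        idx = [f.fraction_index for f in self.fractions]
        if len(set(idx)) != len(idx):
            raise DataError("duplicate fraction_index within gradient run")

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions], dtype=float)

    @property
    def copies(self) -> np.ndarray:
        return np.array([f.copies for f in self.fractions], dtype=float)

    def copy_weighted_mean_density(self) -> float:
        c = self.copies
        total = c.sum()
        if total <= 0:
            raise DataError("gradient run has zero total copies")
        return float((c * self.densities).sum() / total)

    def sorted_by_density(self) -> list[FractionProfile]:
        return sorted(self.fractions, key=lambda f: f.density)


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identifier of a pooled fraction-class sample.

    String form: ``<isotope>_<compartment>_<replicate>_<fraction_class>``,
    e.g. ``13C_rhizosphere_1_H`` or ``13C_endosphere_pooled_L``.
    """

    isotope: str
    compartment: str
    fraction_class: str
    replicate: Replicate

    def __post_init__(self) -> None:
        _check_isotope(self.isotope)
        _check_compartment(self.compartment)
        if self.fraction_class not in FRACTION_CLASSES:
            raise ConfigurationError(
                f"fraction_class must be one of {FRACTION_CLASSES}, got {self.fraction_class!r}"
            )

    def __str__(self) -> str:
        return f"{self.isotope}_{self.compartment}_{self.replicate}_{self.fraction_class}"

    @classmethod
    def from_string(cls, key: str) -> "SampleKey":
        parts = key.split("_")
        if len(parts) < 4:
            raise DataError(f"malformed sample key {key!r}")
        isotope = parts[0]
        fraction_class = parts[-1]
        replicate: Replicate = parts[-2]
        compartment = "_".join(parts[1:-2])
        if replicate != "pooled":
            try:
                replicate = int(replicate)
            except ValueError as exc:
                raise DataError(f"malformed replicate in sample key {key!r}") from exc
        return cls(isotope, compartment, fraction_class, replicate)

    def matches(
        self,
        isotope: Optional[str] = None,
        compartment: Optional[str] = None,
        fraction_class: Optional[str] = None,
        replicate: Optional[Replicate] = None,
    ) -> bool:
        return (
            (isotope is None or self.isotope == isotope)
            and (compartment is None or self.compartment == compartment)
            and (fraction_class is None or self.fraction_class == fraction_class)
            and (replicate is None or self.replicate == replicate)
        )
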