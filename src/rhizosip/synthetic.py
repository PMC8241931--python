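"""Synthetic SIP study generator.

Simulates the full experimental structure the analysis pipeline expects:
a soil community with known ecological roles, ¹³C labeling of root-exudate
metabolizers (planted pots only) and of autotrophs (all ¹³CO₂ pots),
isopycnic CsCl gradient fractionation, per-fraction qPCR copy numbers and
multinomial amplicon read counts, plus CFU colonization assays.

Every generator takes an explicit ``numpy.random.Generator``;
:func:`simulate_study` derives deterministic child streams from a single
root seed so any subset of the dataset is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import (
    CommunityProfile,
    ConfigurationError,
    DataError,
    GradientModel,
    GradientRun,
    FractionProfile,
    Replicate,
    SequencingModel,
    TaxonSpec,
    COMPARTMENTS,
    PLANTED_COMPARTMENTS,
    ROLES,
)

# ---------------------------------------------------------------------------
# community design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeConfig:
    """A group of taxa sharing role, phylum and abundance/labeling parameters."""

    role: str
    genera: tuple[str, ...]
    phylum: str = "Proteobacteria"
    gc_range: tuple[float, float] = (0.35, 0.75)
    atom_excess: float = 0.5
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown clade role {self.role!r}")
        if len(self.genera) == 0:
            raise ConfigurationError(f"clade with role {self.role!r} names no genera")
        lo, hi = self.gc_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(f"invalid gc_range {self.gc_range}")
        if not 0.0 <= self.atom_excess <= 1.0:
            raise ConfigurationError(f"atom_excess {self.atom_excess} outside [0, 1]")


@dataclass(frozen=True)
class CommunityDesign:
    clades: tuple[CladeConfig, ...]
    proteobacteria_endosphere_boost: float = 8.0

    def __post_init__(self) -> None:
        if len(self.clades) == 0:
            raise ConfigurationError("community design has no clades")
        roles = {c.role for c in self.clades}
        missing = set(ROLES) - roles
        if missing:
            raise ConfigurationError(f"community design missing roles: {sorted(missing)}")
        if self.proteobacteria_endosphere_boost <= 0:
            raise ConfigurationError("proteobacteria_endosphere_boost must be positive")


def default_community_design(atom_excess: float = 0.5) -> CommunityDesign:
    """Study-shaped default community.

    GC ranges of the main clades are kept moderately narrow (0.56–0.60):
    with a half-label density shift of 0.018 g/mL, a community whose GC
    spread exceeds the label shift would smear unlabeled DNA across the
    heavy window and the GC-blind peak-offset fraction selection could not
    separate label from base composition. A genuinely high-GC minority
    clade is still present so the ¹²C-heavy control pool has real occupants,
    and the dual fold criterion against that control corrects residual GC
    overlap. Metabolizers are a low-abundance minority, as exudate feeders
    are in soil; a dominant labeled clade would drag the copy-number peak
    (and with it the light/heavy boundary) toward the labeled band.
    """
    gc = (0.56, 0.60)
    bystanders = tuple(f"Bystander{i:02d}" for i in range(1, 10))
    return CommunityDesign(
        clades=(
            CladeConfig(
                role="exudate_metabolizer",
                genera=("Pseudomonas", "Shinella", "Rhizobium", "Variovorax"),
                phylum="Proteobacteria",
                gc_range=gc,
                atom_excess=atom_excess,
                abundance_logmean=-1.3,
                abundance_logsd=0.8,
            ),
            CladeConfig(
                role="autotroph",
                genera=("Nitrosomonas", "Nitrosospira"),
                phylum="Proteobacteria",
                gc_range=gc,
                atom_excess=atom_excess,
                abundance_logmean=-0.8,
            ),
            CladeConfig(
                role="bystander",
                genera=bystanders,
                phylum="Proteobacteria",
                gc_range=gc,
                abundance_logmean=0.0,
            ),
            # minority slow clade that never acquires label
            CladeConfig(
                role="bystander",
                genera=("Streptomyces",),
                phylum="Actinobacteria",
                gc_range=gc,
                abundance_logmean=-1.5,
            ),
            # genuinely high-GC unlabeled clade (myxobacteria); its DNA
            # anchors the heavy window in both isotope treatments, so the
            # ¹²C-heavy control pool is not just the exponential tail of the
            # mid-GC band. Proteobacteria so the endosphere boost keeps its
            # share inside the root too.
            CladeConfig(
                role="bystander",
                genera=("Myxococcus", "Sorangium", "Haliangium"),
                phylum="Proteobacteria",
                gc_range=(0.70, 0.74),
                abundance_logmean=-0.7,
            ),
            CladeConfig(
                role="bystander",
                genera=("Chloroflexus", "Pirellula", "Bacillus"),
                phylum="other",
                gc_range=gc,
                abundance_logmean=-1.0,
            ),
        )
    )


def _atom_excess_map(role: str, a: float) -> dict[tuple[str, str], float]:
    if a == 0.0 or role == "bystander":
        return {}
    if role == "exudate_metabolizer":
        return {("13C", c): a for c in PLANTED_COMPARTMENTS}
    # autotrophs fix CO2 regardless of the plant
    return {("13C", c): a for c in COMPARTMENTS}


def build_taxa(design: CommunityDesign, rng: np.random.Generator) -> list[TaxonSpec]:
    """Materialize a :class:`CommunityDesign` into concrete taxa.

    GC contents are drawn uniformly from each clade's ``gc_range``; atom
    excess maps follow the clade role (bystanders never label; metabolizers
    label only in planted ¹³C compartments; autotrophs label in every ¹³C
    compartment including unplanted controls).
    """
    taxa: list[TaxonSpec] = []
    i = 0
    for clade in design.clades:
        for genus in clade.genera:
            lo, hi = clade.gc_range
            gc = float(rng.uniform(lo, hi))
            taxa.append(
                TaxonSpec(
                    taxon_id=f"t{i:03d}_{genus}",
                    genus=genus,
                    phylum=clade.phylum,
                    gc=gc,
                    role=clade.role,
                    atom_excess=_atom_excess_map(clade.role, clade.atom_excess),
                )
            )
            i += 1
    return taxa


# ---------------------------------------------------------------------------
# community profiles
# ---------------------------------------------------------------------------


def _clade_of(design: CommunityDesign, taxon: TaxonSpec) -> CladeConfig:
    for clade in design.clades:
        if taxon.genus in clade.genera and taxon.role == clade.role:
            return clade
    raise ConfigurationError(f"taxon {taxon.taxon_id} not covered by design clades")


def simulate_compartment_profiles(
    taxa: Sequence[TaxonSpec],
    design: CommunityDesign,
    rng: np.random.Generator,
    compartments: Sequence[str] = COMPARTMENTS,
    n_replicates: int = 3,
) -> list[CommunityProfile]:
    """Draw lognormal community profiles, one per (compartment, replicate).

    In the endosphere, Proteobacteria abundances are multiplied by the
    design's boost factor before renormalization, reproducing the
    Proteobacteria-dominated root interior.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    clades = [_clade_of(design, t) for t in taxa]
    for clade in clades:
        if clade.abundance_logsd <= 0:
            raise ConfigurationError("abundance_logsd must be positive")
    logmean = np.array([c.abundance_logmean for c in clades])
    logsd = np.array([c.abundance_logsd for c in clades])
    is_proteo = np.array([t.phylum == "Proteobacteria" for t in taxa])

    profiles = []
    for compartment in compartments:
        for rep in range(1, n_replicates + 1):
            x = np.exp(rng.normal(logmean, logsd))
            if compartment == "endosphere":
                x = np.where(is_proteo, x * design.proteobacteria_endosphere_boost, x)
            x = x / x.sum()
            profiles.append(
                CommunityProfile(
                    compartment=compartment,
                    replicate=rep,
                    proportions={t.taxon_id: float(p) for t, p in zip(taxa, x)},
                )
            )
    return profiles


def pool_replicate_dna(
    profiles: Sequence[CommunityProfile], mass_each: float = 0.2
) -> CommunityProfile:
    """Equal-mass pooling of replicate DNA extracts.

    Mixing the same DNA mass from each replicate makes the pooled
    composition the arithmetic mean of the replicate compositions.
    """
    if len(profiles) == 0:
        raise DataError("no profiles to pool")
    if mass_each <= 0:
        raise ConfigurationError("mass_each must be positive")
    compartments = {p.compartment for p in profiles}
    if len(compartments) != 1:
        raise DataError(f"cannot pool across compartments: {sorted(compartments)}")
    taxon_ids = list(profiles[0].proportions)
    if any(set(p.proportions) != set(taxon_ids) for p in profiles):
        raise DataError("profiles to pool cover different taxa")
    pooled = {
        tid: float(np.mean([p.proportions[tid] for p in profiles])) for tid in taxon_ids
    }
    total = sum(pooled.values())
    pooled = {tid: v / total for tid, v in pooled.items()}
    return CommunityProfile(
        compartment=profiles[0].compartment, replicate="pooled", proportions=pooled
    )


# ---------------------------------------------------------------------------
# gradient physics
# ---------------------------------------------------------------------------


def buoyant_density(gc: float, atom_excess: float, model: GradientModel) -> float:
    """Equilibrium buoyant density of DNA in a CsCl gradient, g/mL.

    Linear in GC content (Schildkraut-type relation) plus a label shift
    proportional to the ¹³C atom fraction excess.
    """
    if not 0.0 <= gc <= 1.0:
        raise DataError(f"gc={gc} outside [0, 1]")
    if not 0.0 <= atom_excess <= 1.0:
        raise DataError(f"atom_excess={atom_excess} outside [0, 1]")
    return (
        model.rho0_intercept
        + model.rho0_slope_per_gc * gc
        + atom_excess * model.delta_rho_full_label
    )


def simulate_gradient_run(
    profile: CommunityProfile,
    taxa: Sequence[TaxonSpec],
    isotope: str,
    dna_mass_loaded: float,
    gmodel: GradientModel,
    smodel: SequencingModel,
    rng: np.random.Generator,
    compartment: Optional[str] = None,
) -> GradientRun:
    """Fractionate one DNA sample on a simulated CsCl gradient.

    Each taxon's DNA bands as a Gaussian (sd ``band_sd``) centered at its
    buoyant density for the given treatment, integrated over equal-width
    density bins. Per fraction, 16S copies are the binned mass scaled to
    copies with multiplicative lognormal noise, and genus read counts are a
    multinomial draw proportional to in-bin mass.

    Fractions are indexed 1-based from the densest fraction.
    """
    if dna_mass_loaded <= 0:
        raise ConfigurationError("dna_mass_loaded must be positive")
    compartment = compartment or profile.compartment
    by_id = {t.taxon_id: t for t in taxa}
    missing = set(profile.proportions) - set(by_id)
    if missing:
        raise DataError(f"profile references unknown taxa: {sorted(missing)}")

    edges = gmodel.bin_edges
    n = gmodel.n_fractions
    taxon_ids = list(profile.proportions)
    mass_matrix = np.zeros((len(taxon_ids), n))  # taxon x bin, µg
    for row, tid in enumerate(taxon_ids):
        t = by_id[tid]
        mass = dna_mass_loaded * profile.proportions[tid]
        if mass == 0.0:
            continue
        mu = buoyant_density(t.gc, t.atom_excess_for(isotope, compartment), gmodel)
        cdf = norm.cdf(edges, loc=mu, scale=gmodel.band_sd)
        bin_mass = mass * np.diff(cdf)
        if bin_mass.sum() <= 0.0:
            raise DataError(
                f"taxon {tid} bands at {mu:.4f} g/mL, entirely outside the "
                f"fraction range [{gmodel.density_min}, {gmodel.density_max}]"
            )
        mass_matrix[row] = bin_mass

    centers = (edges[:-1] + edges[1:]) / 2.0
    fraction_mass = mass_matrix.sum(axis=0)

    # qPCR copies with mean-preserving multiplicative lognormal noise
    cv = smodel.qpcr_noise_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        noise = np.exp(rng.normal(-(sigma**2) / 2.0, sigma, size=n))
    else:
        noise = np.ones(n)
    copies = fraction_mass * smodel.copies_per_ug * noise

    # genus-level read counts per fraction
    genus_of = {tid: by_id[tid].genus for tid in taxon_ids}
    genera = sorted({genus_of[tid] for tid in taxon_ids})
    genus_index = {g: k for k, g in enumerate(genera)}
    genus_mass = np.zeros((len(genera), n))
    for row, tid in enumerate(taxon_ids):
        genus_mass[genus_index[genus_of[tid]]] += mass_matrix[row]

    fractions = []
    order = np.argsort(centers)[::-1]  # densest first, index 1
    for rank, b in enumerate(order, start=1):
        total = genus_mass[:, b].sum()
        if total > 0:
            reads = rng.multinomial(smodel.library_size, genus_mass[:, b] / total)
        else:
            reads = np.zeros(len(genera), dtype=int)
        fractions.append(
            FractionProfile(
                fraction_index=rank,
                density=float(centers[b]),
                copies=float(copies[b]),
                counts={g: int(reads[genus_index[g]]) for g in genera},
                taxon_mass={tid: float(mass_matrix[row, b]) for row, tid in enumerate(taxon_ids)},
            )
        )
    return GradientRun(
        isotope=isotope,
        compartment=compartment,
        replicate=profile.replicate,
        dna_mass_loaded=dna_mass_loaded,
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# CFU colonization assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CFUDesign:
    """Design of a genotype × strain root-colonization assay."""

    genotypes: tuple[str, ...] = ("Col-0", "cpr5", "pad4", "sid2-2")
    strains: tuple[str, ...] = ("M145", "M3")
    base_log10_cfu_per_g: float = 4.0
    genotype_effects: Mapping[str, float] = field(
        default_factory=lambda: {"cpr5": 0.8}
    )
    strain_effects: Mapping[str, float] = field(default_factory=dict)
    log10_sd: float = 0.4
    n_per_cell: int = 6
    n_plates: int = 3
    homogenate_volume_ul: float = 1000.0
    plated_volume_ul: float = 100.0
    dilution_factor: float = 1.0
    root_mass_range_g: tuple[float, float] = (0.05, 0.20)

    def cell_log10_mean(self, genotype: str, strain: str) -> float:
        return (
            self.base_log10_cfu_per_g
            + float(self.genotype_effects.get(genotype, 0.0))
            + float(self.strain_effects.get(strain, 0.0))
        )


def simulate_cfu_dataset(design: CFUDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate per-plant CFU counts.

    log10 cfu g⁻¹ is normal per design cell; plate colony counts are Poisson
    around the expected colonies given root mass, plated volume and dilution,
    averaged over ``n_plates`` replicate plates.
    """
    if design.n_per_cell < 2:
        raise ConfigurationError("n_per_cell must be >= 2 (ANOVA needs residual df)")
    if design.log10_sd <= 0:
        raise ConfigurationError("log10_sd must be positive")
    rows = []
    plant = 0
    for genotype in design.genotypes:
        for strain in design.strains:
            mu = design.cell_log10_mean(genotype, strain)
            for _ in range(design.n_per_cell):
                plant += 1
                log10_cfu = rng.normal(mu, design.log10_sd)
                cfu_g = 10.0**log10_cfu
                mass = rng.uniform(*design.root_mass_range_g)
                lam = (
                    cfu_g
                    * mass
                    * design.plated_volume_ul
                    / design.homogenate_volume_ul
                    / design.dilution_factor
                )
                plates = rng.poisson(lam, size=design.n_plates)
                rows.append(
                    {
                        "plant_id": f"plant{plant:03d}",
                        "genotype": genotype,
                        "strain": strain,
                        "colonies": float(plates.mean()),
                        "plated_volume_ul": design.plated_volume_ul,
                        "homogenate_volume_ul": design.homogenate_volume_ul,
                        "dilution_factor": design.dilution_factor,
                        "root_mass_g": mass,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Layout of the SIP study: replication, pooling, and loaded DNA masses."""

    n_replicates: int = 3
    rhizosphere_dna_ug: float = 1.5
    unplanted_dna_ug: float = 1.0
    endosphere_dna_ug: float = 0.6
    pooled_mass_each_ug: float = 0.2
    include_cfu: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


@dataclass
class StudyDataset:
    """Everything one simulated study produces, plus the generating truth."""

    seed: int
    taxa: list[TaxonSpec]
    profiles: dict[tuple[str, str, Replicate], CommunityProfile]  # (isotope, compartment, rep)
    runs: dict[tuple[str, str, Replicate], GradientRun]
    cfu: Optional[pd.DataFrame] = None

    def genera_with_role(self, role: str) -> set[str]:
        return {t.genus for t in self.taxa if t.role == role}

    @property
    def genus_of_taxon(self) -> dict[str, str]:
        return {t.taxon_id: t.genus for t in self.taxa}


_COMP_CODE = {c: i for i, c in enumerate(COMPARTMENTS)}
_ISO_CODE = {"12C": 1, "13C": 2}


def _stream(seed: int, *codes: int) -> np.random.Generator:
    """Deterministic child RNG keyed by integer codes under one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *codes]))


def _rep_code(replicate: Replicate) -> int:
    return 0 if replicate == "pooled" else int(replicate)


def simulate_study(
    community: Optional[CommunityDesign] = None,
    study: Optional[StudyDesign] = None,
    gmodel: Optional[GradientModel] = None,
    smodel: Optional[SequencingModel] = None,
    cfu_design: Optional[CFUDesign] = None,
    seed: int = 0,
) -> StudyDataset:
    """Simulate the full study.

    Gradients are run for: rhizosphere (both isotopes × replicates),
    unplanted ¹³C controls (replicates), and the endosphere (replicate DNA
    pooled into a single gradient per isotope — endosphere enrichment
    therefore has no replicate error). ¹²C and ¹³C pots are independent
    plants, so each isotope gets its own community draw.
    """
    community = community or default_community_design()
    study = study or StudyDesign()
    gmodel = gmodel or GradientModel()
    smodel = smodel or SequencingModel()

    taxa = build_taxa(community, _stream(seed, 99))

    profiles: dict[tuple[str, str, Replicate], CommunityProfile] = {}
    runs: dict[tuple[str, str, Replicate], GradientRun] = {}

    gradient_plan = {
        "rhizosphere": (("12C", "13C"), study.rhizosphere_dna_ug),
        "unplanted_control": (("13C",), study.unplanted_dna_ug),
        "endosphere": (("12C", "13C"), study.endosphere_dna_ug),
    }

    for compartment in COMPARTMENTS:
        isotopes = gradient_plan.get(compartment, (("12C", "13C"),))[0] if compartment != "bulk_soil" else ("12C", "13C")
        for isotope in isotopes:
            for rep in range(1, study.n_replicates + 1):
                prof_rng = _stream(seed, _COMP_CODE[compartment], rep, _ISO_CODE[isotope], 0)
                (profile,) = simulate_compartment_profiles(
                    taxa, community, prof_rng, compartments=[compartment], n_replicates=1
                )
                profile = replace(profile, replicate=rep)
                profiles[(isotope, compartment, rep)] = profile

    for compartment, (isotopes, dna_ug) in gradient_plan.items():
        for isotope in isotopes:
            if compartment == "endosphere":
                reps = [profiles[(isotope, compartment, r)] for r in range(1, study.n_replicates + 1)]
                pooled = pool_replicate_dna(reps, study.pooled_mass_each_ug)
                run_rng = _stream(seed, _COMP_CODE[compartment], 0, _ISO_CODE[isotope], 1)
                runs[(isotope, compartment, "pooled")] = simulate_gradient_run(
                    pooled, taxa, isotope, dna_ug, gmodel, smodel, run_rng
                )
            else:
                for rep in range(1, study.n_replicates + 1):
                    run_rng = _stream(seed, _COMP_CODE[compartment], rep, _ISO_CODE[isotope], 1)
                    runs[(isotope, compartment, rep)] = simulate_gradient_run(
                        profiles[(isotope, compartment, rep)],
                        taxa,
                        isotope,
                        dna_ug,
                        gmodel,
                        smodel,
                        run_rng,
                    )

    cfu = None
    if study.include_cfu:
        cfu = simulate_cfu_dataset(cfu_design or CFUDesign(), _stream(seed, 77))

    return StudyDataset(seed=seed, taxa=taxa, profiles=profiles, runs=runs, cfu=cfu)
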