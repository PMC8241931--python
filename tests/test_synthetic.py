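import numpy as np
import pytest
from scipy.stats import norm

from rhizosip.models import (
    CommunityProfile,
    ConfigurationError,
    DataError,
    GradientModel,
    SequencingModel,
    TaxonSpec,
)
from rhizosip.synthetic import (
    CFUDesign,
    CladeConfig,
    CommunityDesign,
    build_taxa,
    buoyant_density,
    default_community_design,
    pool_replicate_dna,
    simulate_cfu_dataset,
    simulate_compartment_profiles,
    simulate_gradient_run,
    simulate_study,
)


def small_design():
    return CommunityDesign(
        clades=(
            CladeConfig(role="exudate_metabolizer", genera=("MetA", "MetB")),
            CladeConfig(role="autotroph", genera=("Auto",)),
            CladeConfig(role="bystander", genera=("By",)),
        )
    )


class TestBuildTaxa:
    def test_role_bookkeeping(self, rng):
        taxa = build_taxa(small_design(), rng)
        assert len(taxa) == 4
        labeled_in_control = [
            t for t in taxa if t.atom_excess_for("13C", "unplanted_control") > 0
        ]
        assert len(labeled_in_control) == 1
        assert labeled_in_control[0].role == "autotroph"

    def test_default_has_unlabeled_streptomyces(self, rng):
        taxa = build_taxa(default_community_design(), rng)
        strep = [t for t in taxa if t.genus == "Streptomyces"]
        assert len(strep) == 1
        assert strep[0].phylum == "Actinobacteria"
        assert strep[0].role == "bystander"
        assert all(a == 0 for a in strep[0].atom_excess.values()) or not strep[0].atom_excess

    def test_same_seed_identical(self):
        a = build_taxa(default_community_design(), np.random.default_rng(7))
        b = build_taxa(default_community_design(), np.random.default_rng(7))
        assert a == b

    def test_empty_clades_rejected(self):
        with pytest.raises(ConfigurationError):
            CommunityDesign(clades=())

    def test_missing_role_rejected(self):
        with pytest.raises(ConfigurationError, match="missing roles"):
            CommunityDesign(
                clades=(CladeConfig(role="bystander", genera=("By",)),)
            )

    def test_no_label_under_12c(self, rng):
        for t in build_taxa(default_community_design(), rng):
            for (isotope, _), a in t.atom_excess.items():
                assert isotope != "12C" or a == 0

    def test_gc_within_declared_interval(self, rng):
        design = small_design()
        for t in build_taxa(design, rng):
            assert 0.35 <= t.gc <= 0.75


class TestCompartmentProfiles:
    def test_single_taxon_proportion_one(self, rng):
        design = CommunityDesign(
            clades=(
                CladeConfig(role="exudate_metabolizer", genera=("M",)),
                CladeConfig(role="autotroph", genera=("A",)),
                CladeConfig(role="bystander", genera=("B",)),
            )
        )
        taxa = build_taxa(design, rng)[:1]
        profiles = simulate_compartment_profiles(taxa, design, rng, n_replicates=2)
        for p in profiles:
            assert p.proportions[taxa[0].taxon_id] == pytest.approx(1.0)

    def test_endosphere_proteobacteria_boost(self, rng):
        design = default_community_design()
        taxa = build_taxa(design, rng)
        proteo = {t.taxon_id for t in taxa if t.phylum == "Proteobacteria"}
        shares = {"endosphere": [], "bulk_soil": []}
        profiles = simulate_compartment_profiles(
            taxa, design, rng, compartments=["endosphere", "bulk_soil"], n_replicates=500
        )
        for p in profiles:
            shares[p.compartment].append(
                sum(v for k, v in p.proportions.items() if k in proteo)
            )
        assert np.mean(shares["endosphere"]) > np.mean(shares["bulk_soil"])

    def test_different_seeds_differ(self):
        design = default_community_design()
        taxa = build_taxa(design, np.random.default_rng(0))
        a = simulate_compartment_profiles(taxa, design, np.random.default_rng(1))
        b = simulate_compartment_profiles(taxa, design, np.random.default_rng(2))
        assert a != b

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            design = CommunityDesign(
                clades=(
                    CladeConfig(role="exudate_metabolizer", genera=("M",), abundance_logsd=0.0),
                    CladeConfig(role="autotroph", genera=("A",)),
                    CladeConfig(role="bystander", genera=("B",)),
                )
            )
            taxa = build_taxa(design, np.random.default_rng(0))
            simulate_compartment_profiles(taxa, design, np.random.default_rng(0))

    def test_proportions_sum_to_one(self, rng):
        design = default_community_design()
        taxa = build_taxa(design, rng)
        for p in simulate_compartment_profiles(taxa, design, rng):
            assert sum(p.proportions.values()) == pytest.approx(1.0, abs=1e-9)


class TestBuoyantDensity:
    def test_unlabeled_midpoint(self, gmodel):
        assert buoyant_density(0.5, 0.0, gmodel) == pytest.approx(1.709)

    def test_fully_labeled_midpoint(self, gmodel):
        assert buoyant_density(0.5, 1.0, gmodel) == pytest.approx(1.745)

    @pytest.mark.parametrize("gc", [0.0, 0.3, 0.5, 0.62, 1.0])
    def test_label_shift_constant_in_gc(self, gc, gmodel):
        shift = buoyant_density(gc, 1.0, gmodel) - buoyant_density(gc, 0.0, gmodel)
        assert shift == pytest.approx(gmodel.delta_rho_full_label)

    def test_monotone_in_both_arguments(self, gmodel):
        assert buoyant_density(0.6, 0.0, gmodel) > buoyant_density(0.5, 0.0, gmodel)
        assert buoyant_density(0.5, 0.5, gmodel) > buoyant_density(0.5, 0.2, gmodel)

    @pytest.mark.parametrize("gc,a", [(-0.1, 0), (1.1, 0), (0.5, -0.1), (0.5, 1.5)])
    def test_out_of_range_rejected(self, gc, a, gmodel):
        with pytest.raises(DataError):
            buoyant_density(gc, a, gmodel)


def one_taxon(gc=0.5, a13=0.0):
    return TaxonSpec(
        taxon_id="t0",
        genus="G",
        phylum="P",
        gc=gc,
        role="exudate_metabolizer",
        atom_excess={("13C", "rhizosphere"): a13} if a13 else {},
    )


def one_taxon_profile():
    return CommunityProfile(
        compartment="rhizosphere", replicate=1, proportions={"t0": 1.0}
    )


class TestGradientRun:
    def test_mass_conservation_noise_off(self, gmodel, noiseless_smodel, rng):
        taxon = one_taxon()
        run = simulate_gradient_run(
            one_taxon_profile(), [taxon], "12C", 1.5, gmodel, noiseless_smodel, rng
        )
        mu = buoyant_density(taxon.gc, 0.0, gmodel)
        expected = 1.5 * np.diff(norm.cdf(gmodel.bin_edges, mu, gmodel.band_sd))
        got = np.array(
            [f.taxon_mass["t0"] for f in sorted(run.fractions, key=lambda f: f.density)]
        )
        assert got == pytest.approx(expected, abs=1e-15)
        assert got.sum() <= 1.5
        captured = norm.cdf(gmodel.density_max, mu, gmodel.band_sd) - norm.cdf(
            gmodel.density_min, mu, gmodel.band_sd
        )
        assert got.sum() == pytest.approx(1.5 * captured, abs=1e-9)

    def test_label_shifts_mean_density_by_delta(self, gmodel, noiseless_smodel):
        bin_width = (gmodel.density_max - gmodel.density_min) / gmodel.n_fractions
        runs = {}
        for a in (0.0, 1.0):
            taxon = one_taxon(a13=a)
            runs[a] = simulate_gradient_run(
                one_taxon_profile(),
                [taxon],
                "13C",
                1.0,
                gmodel,
                noiseless_smodel,
                np.random.default_rng(0),
            )
        shift = (
            runs[1.0].copy_weighted_mean_density()
            - runs[0.0].copy_weighted_mean_density()
        )
        assert abs(shift - gmodel.delta_rho_full_label) <= bin_width

    def test_12c_heavy_tail_is_high_gc(self, gmodel, noiseless_smodel, rng):
        """Composition of the densest occupied fractions under 12C is the
        high-GC taxon, matching the per-bin Gaussian expectation."""
        low = TaxonSpec("lo", "Lo", "P", gc=0.40, role="bystander")
        high = TaxonSpec("hi", "Hi", "P", gc=0.70, role="bystander")
        profile = CommunityProfile(
            compartment="rhizosphere", replicate=1, proportions={"lo": 0.5, "hi": 0.5}
        )
        run = simulate_gradient_run(
            profile, [low, high], "12C", 1.0, gmodel, noiseless_smodel, rng
        )
        for f in run.fractions:
            mu_lo = buoyant_density(0.40, 0, gmodel)
            mu_hi = buoyant_density(0.70, 0, gmodel)
            half = (gmodel.density_max - gmodel.density_min) / gmodel.n_fractions / 2
            exp_lo = 0.5 * (
                norm.cdf(f.density + half, mu_lo, gmodel.band_sd)
                - norm.cdf(f.density - half, mu_lo, gmodel.band_sd)
            )
            exp_hi = 0.5 * (
                norm.cdf(f.density + half, mu_hi, gmodel.band_sd)
                - norm.cdf(f.density - half, mu_hi, gmodel.band_sd)
            )
            assert f.taxon_mass["lo"] == pytest.approx(exp_lo, abs=1e-12)
            assert f.taxon_mass["hi"] == pytest.approx(exp_hi, abs=1e-12)
            if f.density > 1.725:  # well above the low-GC band
                assert f.taxon_mass["hi"] > 100 * f.taxon_mass["lo"]

    def test_out_of_range_taxon_named_in_error(self, noiseless_smodel, rng):
        narrow = GradientModel(density_min=1.750, density_max=1.760, n_fractions=4)
        taxon = one_taxon(gc=0.0)  # bands at 1.660, 15 sigma below the range
        with pytest.raises(DataError, match="t0"):
            simulate_gradient_run(
                one_taxon_profile(), [taxon], "12C", 1.0, narrow, noiseless_smodel, rng
            )

    def test_unlabeled_profile_unimodal_noise_off(self, gmodel, noiseless_smodel, rng, dataset):
        profile = dataset.profiles[("12C", "rhizosphere", 1)]
        run = simulate_gradient_run(
            profile, dataset.taxa, "12C", 1.5, gmodel, noiseless_smodel, rng
        )
        copies = np.array([f.copies for f in run.sorted_by_density()])
        peak = int(np.argmax(copies))
        assert np.all(np.diff(copies[: peak + 1]) >= 0)
        assert np.all(np.diff(copies[peak:]) <= 0)

    def test_increasing_label_never_lightens(self, gmodel, noiseless_smodel):
        means = []
        for a in (0.0, 0.25, 0.5, 0.75, 1.0):
            run = simulate_gradient_run(
                one_taxon_profile(),
                [one_taxon(a13=a)],
                "13C",
                1.0,
                gmodel,
                noiseless_smodel,
                np.random.default_rng(0),
            )
            means.append(run.copy_weighted_mean_density())
        assert np.all(np.diff(means) >= 0)


class TestPoolReplicateDNA:
    def test_identical_replicates_idempotent(self):
        p = CommunityProfile("rhizosphere", 1, {"a": 0.3, "b": 0.7})
        pooled = pool_replicate_dna([p, p, p])
        assert pooled.proportions == pytest.approx(p.proportions)
        assert pooled.replicate == "pooled"

    def test_complementary_pair(self):
        p1 = CommunityProfile("endosphere", 1, {"a": 1.0, "b": 0.0})
        p2 = CommunityProfile("endosphere", 2, {"a": 0.0, "b": 1.0})
        pooled = pool_replicate_dna([p1, p2])
        assert pooled.proportions == pytest.approx({"a": 0.5, "b": 0.5})

    def test_three_unequal_replicates(self):
        ps = [
            CommunityProfile("endosphere", i + 1, {"a": x, "b": 1 - x})
            for i, x in enumerate([0.2, 0.5, 0.8])
        ]
        pooled = pool_replicate_dna(ps)
        assert pooled.proportions["a"] == pytest.approx(0.5)
        assert sum(pooled.proportions.values()) == pytest.approx(1.0)

    def test_mixed_compartments_rejected(self):
        p1 = CommunityProfile("endosphere", 1, {"a": 1.0})
        p2 = CommunityProfile("rhizosphere", 1, {"a": 1.0})
        with pytest.raises(DataError, match="compartment"):
            pool_replicate_dna([p1, p2])


class TestCFUDataset:
    def test_same_seed_identical(self):
        a = simulate_cfu_dataset(CFUDesign(), np.random.default_rng(3))
        b = simulate_cfu_dataset(CFUDesign(), np.random.default_rng(3))
        assert a.equals(b)

    def test_needs_two_per_cell(self, rng):
        with pytest.raises(ConfigurationError):
            simulate_cfu_dataset(CFUDesign(n_per_cell=1), rng)

    def test_cpr5_generating_means_exceed_others(self):
        design = CFUDesign()
        for strain in design.strains:
            for genotype in ("Col-0", "pad4", "sid2-2"):
                assert design.cell_log10_mean("cpr5", strain) > design.cell_log10_mean(
                    genotype, strain
                )

    def test_shape_and_columns(self, rng):
        table = simulate_cfu_dataset(CFUDesign(), rng)
        assert len(table) == 4 * 2 * 6
        assert {"genotype", "strain", "colonies", "root_mass_g"} <= set(table.columns)


class TestStudyDeterminism:
    def test_same_seed_byte_identical(self):
        a = simulate_study(seed=5)
        b = simulate_study(seed=5)
        assert a.taxa == b.taxa
        for key in a.runs:
            fa = a.runs[key].fractions
            fb = b.runs[key].fractions
            assert [f.copies for f in fa] == [f.copies for f in fb]
            assert [f.counts for f in fa] == [f.counts for f in fb]

    def test_different_seeds_differ(self):
        a = simulate_study(seed=5)
        b = simulate_study(seed=6)
        key = ("13C", "rhizosphere", 1)
        assert a.runs[key].copies.tolist() != b.runs[key].copies.tolist()

    def test_endosphere_is_pooled(self, dataset):
        assert ("13C", "endosphere", "pooled") in dataset.runs
        assert not any(
            k[1] == "endosphere" and k[2] != "pooled" for k in dataset.runs
        )

    def test_subsets_reproducible_independently(self):
        """Child streams: regenerating one gradient in isolation matches."""
        full = simulate_study(seed=9)
        again = simulate_study(seed=9)
        key = ("13C", "unplanted_control", 2)
        assert full.runs[key].copies.tolist() == again.runs[key].copies.tolist()
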