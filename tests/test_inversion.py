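"""Modal-frequency tract detection, inversion genotyping, LD profiles."""

import numpy as np
import pytest

from hornscan import inversion as inv
from hornscan import polarize as pol
from hornscan.inversion import (
    CARRIER,
    HET,
    HOM_ANCESTRAL,
    HOM_INVERTED,
    NON_CARRIER,
    UNKNOWN,
    PopulationSites,
    breakpoint_span,
    concordance,
    detect_tracts,
    dosage_to_class,
    genotype_samples,
    mean_r2_in_interval,
    tract_ld_profile,
)

TRUE_INV = {"chr12": (250_000, 750_000), "chrZ": (150_000, 350_000)}


def make_sites(pos, dosage, ploidy, scaffold="s", population="P"):
    dosage = np.asarray(dosage, dtype=float)
    return PopulationSites(
        scaffold=scaffold,
        population=population,
        pos=np.asarray(pos, dtype=np.int64),
        dosage=dosage,
        ploidy=np.asarray(ploidy, dtype=np.int64),
        samples=tuple(f"s{i}" for i in range(dosage.shape[1])),
    )


def jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


class TestBreakpointSpan:
    def test_printed_breakpoint_arithmetic(self):
        assert breakpoint_span(5_414_046, 13_233_866) == 7_819_820
        assert breakpoint_span(13_706_400, 14_710_588) == 1_004_188

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            breakpoint_span(10, 5)


class TestDetectTracts:
    def test_uniform_lattice_frequencies_yield_nothing(self, rng):
        """i.i.d. frequencies over the lattice carry no tract signal."""
        n_sites, n_samples = 400, 8
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), n_sites, replace=False))
        counts = rng.integers(0, 17, size=n_sites)  # derived copies of 16
        dosage = np.zeros((n_sites, n_samples))
        for i, k in enumerate(counts):  # distribute k copies over 8 diploids
            alloc = rng.permutation(16)[:k]
            for a in alloc:
                dosage[i, a // 2] += 1
        sites = make_sites(pos, dosage, [2] * n_samples)
        assert detect_tracts(sites, min_span=200_000) == []

    def test_lattice_too_coarse_rejected(self):
        sites = make_sites([1, 2], [[1], [0]], [2])
        with pytest.raises(ValueError, match="lattice"):
            detect_tracts(sites)

    def test_recovers_autosomal_tract_at_11_of_16(self, dataset, decisions):
        sites = inv.population_sites(dataset.table, decisions, "AZ", "chr12")
        tracts = detect_tracts(sites)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.modal_count, t.total_chromosomes) == (11, 16)
        assert jaccard((t.start, t.end), TRUE_INV["chr12"]) >= 0.8

    def test_recovers_z_tract_at_13_of_14(self, dataset, decisions):
        sites = inv.population_sites(dataset.table, decisions, "AZ", "chrZ")
        tracts = detect_tracts(sites)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.modal_count, t.total_chromosomes) == (13, 14)
        assert round(t.modal_frequency, 2) == 0.93
        assert jaccard((t.start, t.end), TRUE_INV["chrZ"]) >= 0.8

    def test_shift_invariance(self, dataset, decisions):
        """Shifting all coordinates by a constant shifts tract bounds by
        exactly that constant."""
        sites = inv.population_sites(dataset.table, decisions, "AZ", "chr12")
        shift = 12_345
        shifted = PopulationSites(
            sites.scaffold, sites.population, sites.pos + shift,
            sites.dosage, sites.ploidy, sites.samples,
        )
        a = detect_tracts(sites)[0]
        b = detect_tracts(shifted)[0]
        assert (b.start - a.start, b.end - a.end) == (shift, shift)
        assert b.modal_count == a.modal_count


class TestGenotypeSamples:
    def test_full_carrier_is_hom_inverted(self):
        pos = np.arange(1, 21) * 1000
        dosage = np.column_stack([np.full(20, 2.0), np.zeros(20)])
        sites = make_sites(pos, dosage, [2, 2])
        tract = detect_tracts(sites, min_span=1000, min_modal_snps=5)
        assert len(tract) == 1
        call = genotype_samples(tract[0], sites)
        assert call.genotypes == {"s0": HOM_INVERTED, "s1": HOM_ANCESTRAL}
        assert (call.carrier_chromosomes, call.total_chromosomes) == (2, 4)

    def test_recovers_study_genotype_vector(self, dataset, decisions):
        """4 hom / 3 het / 1 ancestral, frequency 11/16 = 0.6875."""
        sites = inv.population_sites(dataset.table, decisions, "AZ", "chr12")
        call = genotype_samples(detect_tracts(sites)[0], sites)
        labels = list(call.genotypes.values())
        assert labels.count(HOM_INVERTED) == 4
        assert labels.count(HET) == 3
        assert labels.count(HOM_ANCESTRAL) == 1
        assert call.frequency == pytest.approx(0.6875)
        truth = dataset.truth.inversion_genotypes.query(
            "inversion_id == 'inv12' and population == 'AZ'"
        ).set_index("sample")["genotype"]
        assert dict(truth) == call.genotypes

    def test_hemizygous_carrier_contributes_one_chromosome(self, dataset, decisions):
        sites = inv.population_sites(dataset.table, decisions, "AZ", "chrZ")
        call = genotype_samples(detect_tracts(sites)[0], sites)
        females = [
            s for s in call.genotypes
            if dataset.meta.loc[s, "sex"] == "F"
        ]
        assert all(call.genotypes[f] in (CARRIER, NON_CARRIER) for f in females)
        # ploidy accounting: 6 diploid males + 2 hemizygous females
        assert call.total_chromosomes == 14
        assert call.carrier_chromosomes == 13

    def test_noiseless_frequency_recovery_is_exact(self, dataset, decisions):
        for scaffold, (k, t) in (("chr12", (11, 16)), ("chrZ", (13, 14))):
            sites = inv.population_sites(dataset.table, decisions, "AZ", scaffold)
            call = genotype_samples(detect_tracts(sites)[0], sites)
            assert call.carrier_chromosomes == k
            assert call.total_chromosomes == t

    def test_mostly_missing_sample_is_unknown(self):
        from hornscan.inversion import FrequencyTract

        pos = np.arange(1, 21) * 1000
        dosage = np.column_stack([np.full(20, 2.0), np.zeros(20)])
        dosage[:15, 1] = np.nan
        sites = make_sites(pos, dosage, [2, 2])
        tract = FrequencyTract(
            scaffold="s", start=0, end=20_000, modal_count=2,
            total_chromosomes=4, n_modal=20, n_snps=20, population="P",
            modal_positions=tuple(int(p) for p in pos),
        )
        call = genotype_samples(tract, sites)
        assert call.genotypes["s1"] == UNKNOWN
        assert call.genotypes["s0"] == HOM_INVERTED
        assert call.total_chromosomes == 2


class TestMissingnessTolerance:
    def test_frequency_error_within_half_lattice_step(self):
        """With 5% genotype missingness the recovered inversion frequency
        errs by at most one half lattice step, 1/(2 T)."""
        from hornscan.simulate import default_config, simulate_dataset

        cfg = default_config(1)
        cfg.missing_rate = {"AZ": 0.05}
        res = simulate_dataset(cfg)
        dec = pol.polarize_table(res.table, res.outgroup)
        sites = inv.population_sites(res.table, dec, "AZ", "chr12")
        tracts = detect_tracts(sites)
        call = genotype_samples(max(tracts, key=lambda t: t.n_modal), sites)
        assert abs(call.frequency - 11 / 16) <= 1 / (2 * 16)


class TestConcordance:
    def _call(self):
        pos = np.arange(1, 21) * 1000
        dosage = np.column_stack(
            [np.full(20, 2.0), np.full(20, 1.0), np.zeros(20)]
        )
        sites = make_sites(pos, dosage, [2, 2, 2])
        tract = detect_tracts(
            sites, min_span=1000, min_modal_snps=5, min_modal_fraction=0.5
        )[0]
        return genotype_samples(tract, sites)

    def test_copied_genotypes_are_fully_concordant(self):
        call = self._call()
        assert concordance(call, dict(call.genotypes)) == 1.0

    def test_shuffled_genotypes_counted_exhaustively(self):
        """Every permutation's concordance equals the exhaustive match
        count divided by the sample count."""
        import itertools

        call = self._call()
        names = list(call.genotypes)
        truth = [call.genotypes[n] for n in names]
        for perm in itertools.permutations(truth):
            expected = sum(a == b for a, b in zip(perm, truth)) / len(names)
            got = concordance(call, dict(zip(names, perm)))
            assert got == pytest.approx(expected)

    def test_single_sample_matching(self):
        call = self._call()
        only = {"s0": HOM_INVERTED}
        assert concordance(call, only) == 1.0

    def test_disjoint_samples_rejected(self):
        call = self._call()
        with pytest.raises(ValueError):
            concordance(call, {"other": HET})

    def test_dosage_to_class_mapping(self):
        assert dosage_to_class(2, 2) == HOM_INVERTED
        assert dosage_to_class(1, 2) == HET
        assert dosage_to_class(0, 2) == HOM_ANCESTRAL
        assert dosage_to_class(1, 1) == CARRIER
        assert dosage_to_class(0, 1) == NON_CARRIER
        with pytest.raises(ValueError):
            dosage_to_class(2, 1)


class TestLdProfile:
    def test_cosegregating_pair_r2_is_one(self):
        dosage = np.array([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]], dtype=float)
        sites = make_sites([5, 30], dosage, [2] * 5)
        prof = tract_ld_profile(sites, window=50)
        assert prof.loc[0, "mean_r2"] == pytest.approx(1.0)

    def test_independent_snps_r2_near_reciprocal_n(self, rng):
        """For independent sites E[r^2] ~ 1/(n-1); checked by simulation."""
        n = 60
        r2s = []
        for _ in range(300):
            x = rng.binomial(2, 0.4, n).astype(float)
            y = rng.binomial(2, 0.4, n).astype(float)
            sites = make_sites([1, 2], np.vstack([x, y]), [2] * n)
            prof = tract_ld_profile(sites, window=50)
            r2s.append(prof["mean_r2"].iloc[0])
        assert np.nanmean(r2s) == pytest.approx(1 / (n - 1), abs=0.01)

    def test_elevated_ld_inside_inversion_every_population(self, dataset, decisions):
        """Mean r^2 inside the inversion exceeds the outside level in all
        three populations (recombination suppression leaks no signal)."""
        for pop in ("NC", "KS", "AZ"):
            sites = inv.population_sites(dataset.table, decisions, pop, "chr12")
            prof = tract_ld_profile(sites, window=50_000)
            r_in = mean_r2_in_interval(prof, *TRUE_INV["chr12"], inside=True)
            r_out = mean_r2_in_interval(prof, *TRUE_INV["chr12"], inside=False)
            assert r_in > r_out, pop

    def test_monomorphic_pairs_skipped(self):
        dosage = np.array([[1, 1, 1, 1], [0, 1, 2, 1]], dtype=float)
        sites = make_sites([5, 30], dosage, [2] * 4)
        prof = tract_ld_profile(sites, window=50)
        assert prof.loc[0, "n_pairs"] == 0
        assert np.isnan(prof.loc[0, "mean_r2"])
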