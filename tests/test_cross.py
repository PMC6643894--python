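import math

import numpy as np
import pytest

from ectamapper.cross import (
    CrossConfig,
    MutantStrain,
    DEFAULT_EMS_SPECTRUM,
    gate_f2,
    haldane_r,
    make_sibling,
    mutagenize,
    simulate_cross,
    simulate_meiosis,
    simulate_pool_readcounts,
    synthetic_genome,
    synthetic_marker_map,
    write_pool_vcf,
)
from ectamapper.genome import Chromosome, GenomeBuild, Marker, MarkerMap
from ectamapper.variants import Variant, VariantSet


class TestConfig:
    def test_defaults_valid(self):
        CrossConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_f2": 0},
            {"depth": 0},
            {"error_rate": 0.5},
            {"error_rate": -0.1},
            {"mutation_rate": -1e-9},
            {"spectrum": {("G", "A"): 0.5}},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CrossConfig(**kwargs)

    def test_default_spectrum_sums_to_one(self):
        assert sum(DEFAULT_EMS_SPECTRUM.values()) == pytest.approx(1.0)
        assert DEFAULT_EMS_SPECTRUM[("G", "A")] + DEFAULT_EMS_SPECTRUM[("C", "T")] == (
            pytest.approx(0.87)
        )


class TestMutagenize:
    def test_zero_rate_empty(self, small_genome):
        cfg = CrossConfig(mutation_rate=0.0, seed=1)
        strain = mutagenize(small_genome, cfg, require_causal=False)
        assert len(strain.variants) == 0
        assert strain.causal is None

    def test_zero_rate_causal_required_error(self, small_genome):
        cfg = CrossConfig(mutation_rate=0.0, seed=1)
        with pytest.raises(ValueError, match="causal"):
            mutagenize(small_genome, cfg)

    def test_degenerate_transition_spectrum(self, small_genome):
        cfg = CrossConfig(
            mutation_rate=5e-5,
            spectrum={("G", "A"): 0.5, ("C", "T"): 0.5},
            seed=2,
        )
        strain = mutagenize(small_genome, cfg)
        assert len(strain.variants) > 0
        for v in strain.variants:
            assert (v.ref, v.alt) in {("G", "A"), ("C", "T")}

    def test_variant_positions_unique_and_ref_matches_genome(self, small_genome):
        cfg = CrossConfig(mutation_rate=5e-5, seed=3)
        strain = mutagenize(small_genome, cfg)
        keys = [(v.chrom, v.pos) for v in strain.variants]
        assert len(set(keys)) == len(keys)
        for v in strain.variants:
            assert small_genome.base_at(v.chrom, v.pos) == v.ref

    def test_count_is_poisson(self):
        """Mean variant count over many seeds matches mu x genome size."""
        genome = synthetic_genome(n_chromosomes=1, chrom_length=1_000_000, seed=9)
        cfg = CrossConfig(mutation_rate=1e-5)
        rng = np.random.default_rng(2024)
        counts = [
            len(mutagenize(genome, cfg, rng=rng, require_causal=False).variants)
            for _ in range(1000)
        ]
        mean = np.mean(counts)
        se = math.sqrt(10.0 / 1000)
        assert abs(mean - 10.0) <= 3 * se

    def test_causal_constrained_to_damaging_cds(self, small_genome):
        from ectamapper.genome import GeneModel
        from ectamapper.effects import annotate_variant

        gene = GeneModel(
            "g1", "chrI", "+", exons=((1001, 1999),), cds=((1001, 1999, 0),)
        )
        cfg = CrossConfig(mutation_rate=1e-5, seed=4)
        strain = mutagenize(
            small_genome, cfg, causal_genes=[gene], require_damaging=True
        )
        assert 1001 <= strain.causal.pos <= 1999
        anns = annotate_variant(strain.causal, [gene], small_genome)
        assert anns[0].effect_class in {"missense", "nonsense", "start_lost", "stop_lost"}

    def test_causal_must_be_member(self, small_genome):
        v = Variant("chrI", 10, "A", "T")
        with pytest.raises(ValueError, match="causal"):
            MutantStrain("s", VariantSet("s", []), v)


class TestHaldane:
    def test_closed_form(self):
        assert haldane_r(0) == 0.0
        assert haldane_r(50) == pytest.approx((1 - math.exp(-1)) / 2)
        assert haldane_r(1e6) == pytest.approx(0.5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-1)

    def test_monotone_and_bounded(self):
        d = np.linspace(0, 500, 200)
        r = np.array([haldane_r(x) for x in d])
        assert np.all(np.diff(r) > 0)
        assert r.max() < 0.5


class TestMeiosis:
    def test_negligible_genetic_length_returns_whole_parent(self):
        genome = GenomeBuild((Chromosome("c", 10),), cm_per_mb=5.0)
        hap_a = np.array([0, 0, 0])
        hap_b = np.array([1, 1, 1])
        rng = np.random.default_rng(0)
        for _ in range(200):
            g = simulate_meiosis((hap_a, hap_b), np.array([1, 5, 9]), genome, "c", rng)
            assert g.tolist() in ([0, 0, 0], [1, 1, 1])

    def test_empty_positions(self):
        genome = GenomeBuild((Chromosome("c", 100),))
        g = simulate_meiosis(
            (np.empty(0, int), np.empty(0, int)),
            np.empty(0, int),
            genome,
            "c",
            np.random.default_rng(0),
        )
        assert len(g) == 0

    def test_gamete_matches_a_parent_at_every_position(self):
        genome = GenomeBuild((Chromosome("c", 50_000_000),), cm_per_mb=5.0)
        pos = np.sort(np.random.default_rng(1).integers(1, 50_000_000, 40))
        hap_a = np.zeros(40, dtype=int)
        hap_b = np.ones(40, dtype=int)
        rng = np.random.default_rng(2)
        for _ in range(100):
            g = simulate_meiosis((hap_a, hap_b), pos, genome, "c", rng)
            assert set(np.unique(g)) <= {0, 1}

    def test_recombinant_fraction_matches_haldane(self):
        """Monte-Carlo recombinant fraction between two markers equals r(d)."""
        genome = GenomeBuild((Chromosome("c", 20_000_000),), cm_per_mb=5.0)
        d_cm = 20.0
        pos = np.array([1_000_000, 1_000_000 + int(d_cm / 5.0 * 1e6)])
        hap_a = np.zeros(2, dtype=int)
        hap_b = np.ones(2, dtype=int)
        rng = np.random.default_rng(7)
        n = 20_000
        rec = 0
        for _ in range(n):
            g = simulate_meiosis((hap_a, hap_b), pos, genome, "c", rng)
            rec += g[0] != g[1]
        r = haldane_r(d_cm)
        se = math.sqrt(r * (1 - r) / n)
        assert abs(rec / n - r) <= 3 * se


@pytest.fixture(scope="module")
def linked_setup():
    genome = GenomeBuild(
        (Chromosome("c1", 10_000_000), Chromosome("c2", 10_000_000)), cm_per_mb=5.0
    )
    causal = Variant("c1", 2_000_000, "G", "A")
    strain = MutantStrain("s", VariantSet("s", [causal]), causal)
    markers = MarkerMap(
        [
            Marker("c1", 2_000_000, "A", "T"),  # at the causal site
            Marker("c1", 6_000_000, "A", "T"),  # 20 cM away
            Marker("c2", 5_000_000, "A", "T"),  # unlinked
        ]
    )
    return genome, strain, markers


class TestCross:
    def test_selection_zeroes_causal_marker(self, linked_setup):
        genome, strain, markers = linked_setup
        cfg = CrossConfig(n_f2=40, seed=5)
        pool = simulate_cross(strain, markers, genome, cfg)
        assert pool.map_allele_freq[0] == 0.0

    def test_unlinked_marker_near_half(self, linked_setup):
        genome, strain, markers = linked_setup
        cfg = CrossConfig(n_f2=1000, seed=6)
        pool = simulate_cross(strain, markers, genome, cfg)
        se = math.sqrt(1 / (8 * 1000))
        assert abs(pool.map_allele_freq[2] - 0.5) <= 3.5 * se

    def test_linked_marker_frequency_is_recombination_fraction(self, linked_setup):
        """Mean pooled frequency at 20 cM equals haldane_r(20) over replicates."""
        genome, strain, markers = linked_setup
        cfg = CrossConfig(n_f2=50, seed=8)
        rng = np.random.default_rng(8)
        freqs = [
            simulate_cross(strain, markers, genome, cfg, rng=rng).map_allele_freq[1]
            for _ in range(200)
        ]
        r = haldane_r(20.0)
        se = np.std(freqs, ddof=1) / math.sqrt(len(freqs))
        assert abs(np.mean(freqs) - r) <= 3 * se

    def test_no_causal_rejected(self, linked_setup):
        genome, _strain, markers = linked_setup
        strain = MutantStrain("s", VariantSet("s", []), None)
        with pytest.raises(ValueError, match="causal"):
            simulate_cross(strain, markers, genome, CrossConfig(n_f2=5, seed=1))

    def test_causal_chromosome_without_markers_rejected(self, linked_setup):
        genome, strain, _markers = linked_setup
        markers = MarkerMap([Marker("c2", 5_000_000, "A", "T")])
        with pytest.raises(ValueError, match="marker"):
            simulate_cross(strain, markers, genome, CrossConfig(n_f2=5, seed=1))


class TestGate:
    def test_all_dim_events_rejected(self):
        assert gate_f2([(100, 1.0), (110, 2.0)], (90, 120), 10.0) == []

    def test_single_event_inside_both_gates(self):
        assert gate_f2([(50, 99), (100, 99), (100, 1)], (90, 120), 10.0) == [1]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(11)
        events = [(float(s), float(f)) for s, f in rng.uniform(0, 100, (500, 2))]
        got = gate_f2(events, (25.0, 75.0), 50.0)
        want = [
            i for i, (s, f) in enumerate(events) if 25.0 <= s <= 75.0 and f >= 50.0
        ]
        assert got == want


class TestReadcounts:
    def test_error_free_causal_marker_has_zero_map_reads(self):
        genome = GenomeBuild((Chromosome("c1", 10_000_000),), cm_per_mb=5.0)
        causal = Variant("c1", 2_000_000, "G", "A")
        strain = MutantStrain("s", VariantSet("s", [causal]), causal)
        markers = MarkerMap([Marker("c1", 2_000_000, "A", "T")])
        cfg = CrossConfig(n_f2=30, error_rate=0.0, seed=12)
        pool = simulate_cross(strain, markers, genome, cfg)
        counts = simulate_pool_readcounts(pool, markers, cfg)
        assert counts.map_count[0] == 0

    def test_observed_frequency_expectation_with_errors(self):
        """E[observed f] = f(1-eps) + (1-f)eps; at f=0.5 this stays 0.5."""
        from ectamapper.cross import F2Pool

        markers = MarkerMap(
            [Marker("c1", (i + 1) * 1000, "A", "T") for i in range(500)]
        )
        genotypes = np.ones((20, 500), dtype=np.int8)  # every animal het: f = 0.5
        pool = F2Pool(markers, genotypes)
        cfg = CrossConfig(n_f2=20, depth=40, error_rate=0.1, seed=13)
        counts = simulate_pool_readcounts(pool, markers, cfg)
        f_obs = counts.map_count / counts.depth
        se = np.std(f_obs, ddof=1) / math.sqrt(len(f_obs))
        assert abs(np.mean(f_obs) - 0.5) <= 3 * se

    def test_identical_seeds_give_identical_vcf_bytes(self, tmp_path):
        genome = GenomeBuild((Chromosome("c1", 10_000_000),), cm_per_mb=5.0)
        causal = Variant("c1", 2_000_000, "G", "A")
        strain = MutantStrain("s", VariantSet("s", [causal]), causal)
        markers = MarkerMap(
            [Marker("c1", p, "A", "T") for p in (1_000_000, 2_000_000, 9_000_000)]
        )
        cfg = CrossConfig(n_f2=20, seed=99)
        paths = []
        for name in ("a.vcf", "b.vcf"):
            pool = simulate_cross(strain, markers, genome, cfg)
            counts = simulate_pool_readcounts(pool, markers, cfg)
            p = tmp_path / name
            write_pool_vcf(counts, genome, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestSibling:
    def test_sibling_shares_genome_plus_private_noise(self, small_genome):
        cfg = CrossConfig(mutation_rate=5e-5, seed=14)
        strain = mutagenize(small_genome, cfg)
        rng = np.random.default_rng(15)
        sib = make_sibling(strain, small_genome, cfg, rng, "sib1")
        assert strain.causal in sib.variants
        assert strain.variants.keys <= sib.variants.keys
        n_private = len(sib.variants) - len(strain.variants)
        assert n_private == round(0.05 * len(strain.variants))
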