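"""Screen simulator: sampling conservation, growth law, determinism."""

import numpy as np
import pytest

from cxxxscreen.library_space import enumerate_cxxx
from cxxxscreen.simulate import (
    DEFAULT_RULE_TABLES,
    SimulationConfig,
    apply_sequencing_errors,
    assign_fitness,
    build_naive_library,
    default_fitness_model,
    grow_population,
    sequence_reads,
    simulate_rho1_screen,
    simulate_screen,
)


class TestConfig:
    def test_defaults_are_study_conditions(self):
        c = SimulationConfig()
        assert c.library_size == 8000
        assert c.cfu_count == 150_000
        assert c.replicates == 10
        assert c.doublings == 8.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"library_size": 0},
            {"replicates": -1},
            {"base_error_rate": 1.5},
            {"doublings": -1.0},
            {"naive_abundance_dispersion": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestNaiveLibrary:
    def test_colony_counts_conserved(self, rng):
        config = SimulationConfig(library_size=100, cfu_count=5000, replicates=4)
        p, colonies = build_naive_library(config, rng)
        assert colonies.shape == (4, 100)
        assert (colonies.sum(axis=1) == 5000).all()
        assert p.shape == (100,)
        assert (p > 0).all()
        assert p.sum() == pytest.approx(1.0)

    def test_high_dispersion_approaches_symmetry(self, rng):
        config = SimulationConfig(
            library_size=2, cfu_count=10_000, replicates=1,
            naive_abundance_dispersion=1e6,
        )
        p, colonies = build_naive_library(config, rng)
        assert abs(colonies[0, 0] - 5000) < 300  # ~E = 5000 in the symmetric limit

    def test_deterministic_under_fixed_seed(self):
        config = SimulationConfig(library_size=50, cfu_count=1000, replicates=2)
        a = build_naive_library(config, np.random.default_rng(9))
        b = build_naive_library(config, np.random.default_rng(9))
        assert np.array_equal(a[1], b[1]) and np.allclose(a[0], b[0])


class TestGrowth:
    def test_doubling_law(self):
        assert grow_population(np.array([1.0]), np.array([1.0]), 8)[0] == 256
        assert grow_population(np.array([1.0]), np.array([0.0]), 8)[0] == 1

    def test_relative_growth_ratio(self):
        grown = grow_population(np.array([1.0, 1.0]), np.array([1.0, 0.5]), 8)
        assert grown[0] / grown[1] == pytest.approx(16.0)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            grow_population(np.array([-1.0]), np.array([0.5]), 8)
        with pytest.raises(ValueError):
            grow_population(np.array([1.0]), np.array([1.5]), 8)


class TestFitnessModels:
    def test_shunted_maximal_canonical_low_at_restrictive_temp(self):
        model = default_fitness_model("Ydj1", "42C")
        idx = {v: i for i, v in enumerate(enumerate_cxxx())}
        table = DEFAULT_RULE_TABLES[("Ydj1", "42C")]
        assert model.fitness[idx["CSFL"]] == max(table.values())  # shunted
        assert model.fitness[idx["CVLL"]] < model.fitness[idx["CSFL"]]
        assert model.fitness[idx["CVLL"]] < model.fitness[idx["CASQ"]]  # canonical < unmodified
        assert model.fitness[idx["CARL"]] == min(table.values())  # restrictive

    def test_rho1_viability_split(self):
        model = default_fitness_model("Rho1")
        idx = {v: i for i, v in enumerate(enumerate_cxxx())}
        assert model.viable_mask[idx["CVLL"]]  # canonical viable
        assert model.viable_mask[idx["CSFL"]]  # shunted viable
        assert not model.viable_mask[idx["CASQ"]]
        assert not model.viable_mask[idx["CARL"]]

    def test_all_variants_covered(self):
        model = default_fitness_model("Ydj1", "37C")
        assert model.fitness.shape == (8000,)
        assert np.all((model.fitness >= 0) & (model.fitness <= 1))

    def test_unmapped_category_is_error(self):
        with pytest.raises(KeyError):
            assign_fitness({"shunted": 1.0}, "Ydj1", "42C", library_size=100)


class TestErrorChannel:
    def test_zero_error_rate_is_identity(self, rng):
        counts = np.array([5, 0, 7] + [0] * 97)
        new, rejected = apply_sequencing_errors(counts, 0.0, rng, library_size=100)
        assert np.array_equal(new, counts)
        assert rejected == 0

    def test_reads_conserved_up_to_rejections(self, rng):
        counts = rng.multinomial(50_000, np.full(100, 0.01))
        new, rejected = apply_sequencing_errors(counts, 0.01, rng, library_size=100)
        assert new.sum() + rejected == counts.sum()
        assert (new >= 0).all()

    def test_errors_move_reads_between_variants(self, rng):
        counts = np.zeros(8000, dtype=int)
        counts[0] = 100_000
        new, rejected = apply_sequencing_errors(counts, 0.01, rng)
        assert new[0] < 100_000
        assert new.sum() + rejected == 100_000
        assert (new[1:] > 0).any()


class TestReadSimulation:
    def test_exact_depth_and_content_without_errors(self, rng):
        config = SimulationConfig(
            library_size=8000, base_error_rate=0.0, replicates=1,
        )
        counts = np.zeros(8000, dtype=int)
        from cxxxscreen.library_space import preferred_coding_dna, variant_index

        counts[variant_index()["CVLL"]] = 3
        records = sequence_reads(counts, config, rng)
        assert len(records) == 3
        expected = (
            config.anchor_left + preferred_coding_dna("CVLL") + config.anchor_right
        )
        for seq, qual in records:
            assert seq == expected
            assert len(qual) == len(seq)

    def test_depth_conservation_with_errors(self, rng):
        config = SimulationConfig(library_size=50, base_error_rate=0.05)
        counts = rng.multinomial(500, np.full(50, 0.02))
        records = sequence_reads(counts, config, rng)
        assert len(records) == 500

    def test_empty_abundances_rejected(self, rng):
        config = SimulationConfig(library_size=10)
        with pytest.raises(ValueError):
            sequence_reads(np.zeros(10, dtype=int), config, rng)


class TestScreenDeterminism:
    def test_identical_tables_across_runs(self):
        config = SimulationConfig(
            library_size=100, cfu_count=2000, replicates=2,
            read_depth_per_replicate=1000, seed=77,
        )
        a = simulate_screen(config)
        b = simulate_screen(config)
        for cond in a.tables:
            assert a.tables[cond].totals() == b.tables[cond].totals()
            assert np.array_equal(a.true_counts[cond], b.true_counts[cond])

    def test_read_depth_conserved_every_replicate(self, small_screen):
        config = small_screen.config
        for cond, counts in small_screen.true_counts.items():
            assert (counts.sum(axis=1) == config.read_depth_per_replicate).all()

    def test_observed_reads_at_most_depth(self, small_screen):
        # sequencing errors can reject reads (stop codons) but never create them
        config = small_screen.config
        for cond, table in small_screen.tables.items():
            for rep, counter in table.counts.items():
                accepted = sum(counter.values())
                rejected = sum(table.rejections[rep].values())
                assert accepted + rejected == config.read_depth_per_replicate


class TestRhoColonySimulation:
    def test_all_parent_when_gene_conversion_total(self, rng):
        cs = simulate_rho1_screen(
            n_colonies=20, gene_conversion_fraction=1.0, rng=rng
        )
        assert all(s == cs.parent_dna for s in cs.sequences)

    def test_unique_dna_equals_distinct_protein_without_synonyms(self, rng):
        cs = simulate_rho1_screen(
            n_colonies=50, gene_conversion_fraction=0.0,
            duplicate_pick_fraction=0.0, rng=rng, synonymous_codons=False,
        )
        from cxxxscreen.rho1 import dedup_hits

        report, _, _ = dedup_hits(cs.sequences, cs.parent_dna)
        assert report.n_unique_dna == report.n_distinct_protein

    def test_colony_count_conserved(self, rng):
        cs = simulate_rho1_screen(n_colonies=200, rng=rng)
        assert len(cs.sequences) == 200

    def test_invalid_fractions_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_rho1_screen(gene_conversion_fraction=1.5, rng=rng)

    def test_no_viable_variants_is_error(self, rng):
        from cxxxscreen.simulate import FitnessModel

        dead = FitnessModel("Rho1", "viability", np.zeros(100))
        with pytest.raises(ValueError, match="viable"):
            simulate_rho1_screen(fitness_model=dead, rng=rng)
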