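"""Roulette selection, mutation, fixation and arrival-of-the-frequent
dynamics."""

import numpy as np
import pytest
from scipy import stats

from simbias.evolution import (EvolutionConfig, ExtinctionError,
                               FixationRecord, fitness,
                               fixation_frequency_table,
                               fixation_symmetry_fraction, next_generation,
                               run_many, run_to_fixation)
from simbias.polyomino import PolyominoGPMap
from simbias.sampling import estimate_phenotype_frequencies
from simbias.shapes import SymmetryClass


def _key_of_size(s):
    """A dummy phenotype key of a shape with s cells (8 bytes per cell)."""
    return bytes(8 * s)


class TestFitness:
    def test_und_is_zero_under_every_protocol(self):
        for protocol in ("unit", "random", "size"):
            assert fitness(None, protocol, 16, {}, np.random.default_rng(0)) \
                == 0.0

    def test_size_protocol_printed_values(self):
        assert fitness(_key_of_size(16), "size", 16) == 1.0
        assert fitness(_key_of_size(12), "size", 16) == pytest.approx(0.2)
        assert fitness(_key_of_size(20), "size", 16) == pytest.approx(0.2)

    def test_unit_protocol(self):
        assert fitness(_key_of_size(3), "unit", 16) == 1.0

    def test_random_protocol_cached_per_structure(self):
        rng = np.random.default_rng(1)
        cache = {}
        v1 = fitness(_key_of_size(4), "random", 16, cache, rng)
        v2 = fitness(_key_of_size(4), "random", 16, cache, rng)
        assert v1 == v2
        assert 0.0 <= v1 <= 1.0

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            fitness(_key_of_size(1), "frequency", 16)


class TestNextGeneration:
    def test_uniform_fitness_resamples_parents(self):
        rng = np.random.default_rng(0)
        pop = np.eye(8, 24, dtype=np.uint8)
        out = next_generation(pop, np.ones(8), mu=0.0, rng=rng)
        assert out.shape == pop.shape
        parent_rows = {r.tobytes() for r in pop}
        assert all(r.tobytes() in parent_rows for r in out)

    def test_single_fit_genome_sweeps(self):
        rng = np.random.default_rng(1)
        pop = np.arange(5 * 8, dtype=np.uint8).reshape(5, 8) % 2
        fit = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        out = next_generation(pop, fit, mu=0.0, rng=rng)
        assert all(np.array_equal(r, pop[2]) for r in out)

    def test_expected_mutation_count_is_mu_per_genome(self):
        rng = np.random.default_rng(2)
        N, L, mu = 50, 96, 0.5
        pop = np.zeros((N, L), dtype=np.uint8)
        total = 0
        reps = 200
        for _ in range(reps):
            out = next_generation(pop, np.ones(N), mu=mu, rng=rng)
            total += int(out.sum())
        mean_per_genome = total / (reps * N)
        assert mean_per_genome == pytest.approx(mu, rel=0.15)

    def test_all_zero_fitness_is_extinction(self):
        with pytest.raises(ExtinctionError):
            next_generation(np.zeros((4, 8), dtype=np.uint8), np.zeros(4),
                            0.1, np.random.default_rng(0))

    def test_selection_is_fitness_proportionate(self):
        # chi-square goodness of fit of selection counts against f_i/sum f
        rng = np.random.default_rng(3)
        fit = np.array([0.1, 0.2, 0.3, 0.4])
        pop = np.arange(4, dtype=np.uint8)[:, None] * np.ones(
            (4, 8), dtype=np.uint8)
        counts = np.zeros(4)
        draws = 10_000
        for _ in range(draws // 4):
            out = next_generation(pop, fit, mu=0.0, rng=rng)
            for r in out:
                counts[r[0]] += 1
        expected = draws * fit / fit.sum()
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01


class TestRunToFixation:
    def test_monomorphic_optimal_population_fixes_at_hold(self):
        cfg = EvolutionConfig(n_tiles=1, bits_per_color=2,
                              population_size=10, mutation_rate=0.0,
                              fitness_protocol="size", target_size=1,
                              fixation_hold=10, seed=4)
        init = np.zeros((10, 8), dtype=np.uint8)  # all-neutral -> monomer
        rec = run_to_fixation(cfg, run_id=0, initial_population=init)
        assert rec is not None
        assert rec.generation == cfg.fixation_hold
        assert rec.size == 1
        assert rec.symmetry.label == "D4"

    def test_size_protocol_fixes_target_size(self):
        cfg = EvolutionConfig(n_tiles=2, bits_per_color=3,
                              population_size=40, mutation_rate=0.1,
                              fitness_protocol="size", target_size=2,
                              max_generations=2000, seed=8)
        gp = PolyominoGPMap(2, 3, master_seed=8)
        fixed_sizes = [run_to_fixation(cfg, gp, rid).size
                       for rid in range(5)]
        assert fixed_sizes == [2] * 5

    def test_timeout_returns_none(self):
        cfg = EvolutionConfig(n_tiles=2, bits_per_color=3,
                              population_size=20, mutation_rate=0.1,
                              fitness_protocol="size", target_size=16,
                              max_generations=5, seed=0)
        # a 16-cell target is unreachable for a 2-tile map in 5 generations
        assert run_to_fixation(cfg, run_id=0) is None


class TestSymmetryFraction:
    @staticmethod
    def _rec(run_id, label):
        return FixationRecord(run_id, _key_of_size(4), 1,
                              SymmetryClass(label), 4)

    def test_all_in_classes(self):
        recs = [self._rec(i, "D4") for i in range(3)]
        assert fixation_symmetry_fraction(recs, {"D4", "C4"}) == 1.0

    def test_none_in_classes(self):
        recs = [self._rec(i, "C1") for i in range(3)]
        assert fixation_symmetry_fraction(recs, {"D4", "C4"}) == 0.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            fixation_symmetry_fraction([], {"D4"})


class TestArrivalOfTheFrequent:
    def test_unit_fitness_fixations_track_sampling_probability(self):
        # on S(2, 8): phenotypes that are frequent under uniform genotype
        # sampling also fix more often under neutral (unit) fitness
        cfg = EvolutionConfig(n_tiles=2, bits_per_color=3,
                              population_size=30, mutation_rate=0.1,
                              fitness_protocol="unit", max_generations=400,
                              seed=21)
        gp = PolyominoGPMap(2, 3, master_seed=21)
        exp = run_many(cfg, 200, gp)
        assert len(exp.records) >= 150
        evo = fixation_frequency_table(exp.records)
        samp = estimate_phenotype_frequencies(2, 3, num_samples=30_000,
                                              seed=22)
        shared = set(evo.counts) & set(samp.counts)
        assert len(shared) >= 3
        ev = [evo.probability(k) for k in shared]
        sp = [samp.probability(k) for k in shared]
        rho, p = stats.spearmanr(ev, sp)
        assert rho > 0
        assert p < 0.05
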