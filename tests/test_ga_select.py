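"""Genetic-algorithm operators and the planted-optimum evolution contract."""

import numpy as np
import pytest

from savpred.ga_select import (
    GAConfig,
    crossover_step,
    evolve,
    initialize,
    mutation_step,
    selection_step,
)


def bit_count(mask):
    return float(mask.sum())


class TestInitialize:
    def test_reproducible_and_zeroed_incumbents(self):
        cfg = GAConfig(population_size=4, generations=1, seed=42)
        s1 = initialize(5, cfg)
        s2 = initialize(5, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(s1.population, s2.population))
        assert s1.generation == 0
        assert not s1.alpha.any() and not s1.beta.any()
        assert s1.alpha_fitness == -np.inf

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=5)


class TestSelection:
    def test_alpha_is_half_max_and_population_alternates(self):
        cfg = GAConfig(population_size=4, generations=1, seed=0)
        state = initialize(6, cfg)
        state.population = [
            np.array([1, 1, 1, 0, 0, 0], dtype=np.uint8),  # half 1, best
            np.array([1, 0, 0, 0, 0, 0], dtype=np.uint8),
            np.array([0, 0, 0, 0, 0, 1], dtype=np.uint8),  # half 2
            np.array([0, 0, 0, 1, 1, 0], dtype=np.uint8),  # half 2, best
        ]
        selection_step(state, bit_count)
        assert np.array_equal(state.alpha, [1, 1, 1, 0, 0, 0])
        assert np.array_equal(state.beta, [0, 0, 0, 1, 1, 0])
        assert np.array_equal(state.population[0], state.alpha)
        assert np.array_equal(state.population[1], state.beta)
        distinct = {m.tobytes() for m in state.population}
        assert len(distinct) == 2

    def test_elitism_keeps_previous_incumbent(self):
        cfg = GAConfig(population_size=4, generations=1, seed=0)
        state = initialize(4, cfg)
        state.alpha = np.array([1, 1, 1, 1], dtype=np.uint8)
        state.alpha_fitness = 4.0
        state.population = [np.zeros(4, dtype=np.uint8) for _ in range(4)]
        state.population[0][0] = 1  # best current half-1 member has fitness 1
        selection_step(state, bit_count)
        assert np.array_equal(state.alpha, [1, 1, 1, 1])
        assert state.alpha_fitness == 4.0


class TestMutation:
    def test_second_half_hamming_distance_exactly_one(self):
        cfg = GAConfig(population_size=8, generations=1, seed=7)
        state = initialize(12, cfg)
        before = [m.copy() for m in state.population]
        mutation_step(state)
        for prev, cur in zip(before[4:], state.population[4:]):
            assert int((prev != cur).sum()) == 1

    def test_zero_rate_leaves_first_half_unchanged(self):
        cfg = GAConfig(population_size=8, generations=1,
                       mutation_threshold=0.0, seed=7)
        state = initialize(12, cfg)
        before = [m.copy() for m in state.population]
        mutation_step(state)
        for prev, cur in zip(before[:4], state.population[:4]):
            assert np.array_equal(prev, cur)


class TestCrossover:
    def test_suffix_swap(self):
        cfg = GAConfig(population_size=4, generations=1,
                       crossover_threshold=1.0, seed=1)
        state = initialize(5, cfg)
        state.population[0] = np.zeros(5, dtype=np.uint8)
        state.population[1] = np.ones(5, dtype=np.uint8)
        state.rng = np.random.default_rng(0)
        crossover_step(state)
        cut = int((state.population[0] == 1).argmax()) or 5
        a, b = state.population[0], state.population[1]
        assert np.array_equal(a[:cut], np.zeros(cut, dtype=np.uint8))
        assert np.array_equal(a[cut:], np.ones(5 - cut, dtype=np.uint8))
        assert np.array_equal(b[:cut], np.ones(cut, dtype=np.uint8))

    def test_gate_closed_leaves_pairs_unchanged(self):
        cfg = GAConfig(population_size=4, generations=1,
                       crossover_threshold=0.0, seed=1)
        state = initialize(5, cfg)
        before = [m.copy() for m in state.population]
        crossover_step(state)
        assert all(np.array_equal(p, c) for p, c in zip(before, state.population))

    def test_locus_multisets_conserved(self):
        cfg = GAConfig(population_size=8, generations=1,
                       crossover_threshold=1.0, seed=3)
        state = initialize(10, cfg)
        before = np.stack(state.population)
        crossover_step(state)
        after = np.stack(state.population)
        for p in range(4):
            pair_before = np.sort(before[2 * p:2 * p + 2], axis=0)
            pair_after = np.sort(after[2 * p:2 * p + 2], axis=0)
            assert np.array_equal(pair_before, pair_after)


class TestEvolve:
    def test_bit_count_reaches_all_ones(self):
        cfg = GAConfig(population_size=8, generations=30, seed=5)
        best, fit, trace = evolve(8, bit_count, cfg)
        assert best.all() and fit == 8.0

    def test_trace_is_non_decreasing(self):
        for seed in range(3):
            cfg = GAConfig(population_size=8, generations=15, seed=seed)
            _, _, trace = evolve(10, bit_count, cfg)
            assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_determinism(self):
        cfg = GAConfig(population_size=8, generations=10, seed=9)
        r1 = evolve(12, bit_count, cfg)
        r2 = evolve(12, bit_count, cfg)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1] and r1[2] == r2[2]

    def test_all_zero_mask_never_returned(self):
        # fitness rewards emptiness, but the adapter forbids the zero mask
        cfg = GAConfig(population_size=8, generations=10, seed=2)
        best, _, _ = evolve(6, lambda m: -bit_count(m), cfg)
        assert best.sum() == 1
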