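"""Genetic algorithm over binary feature masks.

A solution is an m-bit mask: bit j keeps descriptor j. Each generation applies
three operators in order:

* **selection** — the best mask of each population half (including the
  incumbent alpha/beta, so best fitness never decreases) fills the next
  population, alpha in odd slots and beta in even slots;
* **mutation** — first half: every bit flips independently with probability
  mu0 = 0.1; second half: exactly one uniformly chosen bit flips;
* **crossover** — adjacent pairs undergo one-point crossover with probability
  mu1 = 0.5 at a uniform internal cut.

At generation 0 alpha and beta are the all-zero mask with sentinel fitness
-inf. The fitness adapter also assigns -inf to all-zero candidates so the
returned mask always keeps at least one descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Mask = np.ndarray  # uint8 0/1 vector


@dataclass
class GAConfig:
    population_size: int = 40
    generations: int = 50
    mutation_threshold: float = 0.1   # mu0
    crossover_threshold: float = 0.5  # mu1
    seed: int = 0

    def __post_init__(self):
        if self.population_size % 2 or self.population_size < 4:
            raise ValueError("population size must be even and >= 4")
        for t in (self.mutation_threshold, self.crossover_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class GAState:
    population: list[Mask]
    alpha: Mask
    beta: Mask
    alpha_fitness: float
    beta_fitness: float
    generation: int
    rng: np.random.Generator
    config: GAConfig


def mask_key(mask: Mask) -> bytes:
    return np.asarray(mask, dtype=np.uint8).tobytes()


def initialize(m: int, config: GAConfig) -> GAState:
    """Random fair-coin population; alpha/beta start as the zero mask, -inf."""
    if m < 1:
        raise ValueError("mask length must be >= 1")
    rng = np.random.default_rng(config.seed)
    population = [
        rng.integers(0, 2, size=m, dtype=np.uint8)
        for _ in range(config.population_size)
    ]
    zero = np.zeros(m, dtype=np.uint8)
    return GAState(
        population=population,
        alpha=zero.copy(),
        beta=zero.copy(),
        alpha_fitness=-np.inf,
        beta_fitness=-np.inf,
        generation=0,
        rng=rng,
        config=config,
    )


def selection_step(state: GAState, fitness: Callable[[Mask], float]) -> GAState:
    """Update alpha/beta over each half plus the incumbents; repopulate by
    alternating alpha (odd 1-based slots) and beta (even slots)."""
    n = len(state.population)
    half = n // 2
    for mask in state.population[:half]:
        f = fitness(mask)
        if f > state.alpha_fitness:
            state.alpha, state.alpha_fitness = mask.copy(), f
    for mask in state.population[half:]:
        f = fitness(mask)
        if f > state.beta_fitness:
            state.beta, state.beta_fitness = mask.copy(), f
    state.population = [
        (state.alpha if (i + 1) % 2 == 1 else state.beta).copy() for i in range(n)
    ]
    state.generation += 1
    return state


def mutation_step(state: GAState) -> GAState:
    """First half: per-bit flips at rate mu0; second half: one forced flip."""
    half = len(state.population) // 2
    mu0 = state.config.mutation_threshold
    for i in range(half):
        mask = state.population[i]
        flips = state.rng.random(mask.shape[0]) < mu0
        mask[flips] ^= 1
    for i in range(half, len(state.population)):
        mask = state.population[i]
        j = int(state.rng.integers(0, mask.shape[0]))
        mask[j] ^= 1
    return state


def crossover_step(state: GAState) -> GAState:
    """One-point crossover of adjacent pairs with probability mu1."""
    m = state.population[0].shape[0]
    if m == 1:
        return state
    mu1 = state.config.crossover_threshold
    for p in range(len(state.population) // 2):
        if state.rng.random() < mu1:
            a = state.population[2 * p]
            b = state.population[2 * p + 1]
            cut = int(state.rng.integers(1, m))
            a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
    return state


def evolve(
    m: int,
    fitness: Callable[[Mask], float],
    config: GAConfig,
) -> tuple[Mask, float, list[float]]:
    """Run the GA; return (best mask, its fitness, best-so-far trace).

    ``fitness`` must be deterministic for a given mask. Evaluations are cached
    by mask bits because selection duplicates masks heavily; all-zero masks
    score -inf so the winner keeps at least one feature.
    """
    cache: dict[bytes, float] = {}

    def cached_fitness(mask: Mask) -> float:
        if not mask.any():
            return -np.inf
        key = mask_key(mask)
        if key not in cache:
            cache[key] = float(fitness(mask))
        return cache[key]

    state = initialize(m, config)
    trace: list[float] = []
    for _ in range(config.generations):
        selection_step(state, cached_fitness)
        trace.append(max(state.alpha_fitness, state.beta_fitness))
        mutation_step(state)
        crossover_step(state)
    # final population may hold an improvement not yet selected
    selection_step(state, cached_fitness)
    trace.append(max(state.alpha_fitness, state.beta_fitness))
    if state.alpha_fitness >= state.beta_fitness:
        best, best_fit = state.alpha, state.alpha_fitness
    else:
        best, best_fit = state.beta, state.beta_fitness
    return best.copy(), float(best_fit), trace


def write_trace(trace: Sequence[float], path) -> None:
    """Fitness trace as TSV (generation, best_fitness)."""
    with open(path, "w") as fh:
        fh.write("generation\tbest_fitness\n")
        for g, f in enumerate(trace):
            fh.write(f"{g}\t{f:.6f}\n")
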