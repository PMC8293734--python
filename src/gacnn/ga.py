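"""Genetic-algorithm trainer for the CNN's flattened weight vector.

Each chromosome is the full flat weight vector of the network
(:func:`gacnn.network.flatten_weights`); each gene is one scalar weight.
Fitness is the classification error rate (FP + FN) / N on the current
evaluation batch, minimized.  One generation = evaluate fitness, sort,
keep the best ``num_parents`` unchanged (elitism), refill the remaining
slots with single-point crossover of cyclically paired parents followed
by mutation of at most one gene per offspring.

With elitism and a fixed evaluation set, the best fitness is
monotonically non-increasing across generations.  Under mini-batch
fitness the per-generation values are noisy, so the reported best
solution is the best-ever member by its recorded fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import network as net
from ._batching import BatchCycler

__all__ = [
    "GAConfig",
    "Population",
    "GAResult",
    "fitness",
    "select_parents",
    "single_point_crossover",
    "mutate",
    "evolve_generation",
    "train_ga",
    "population_parameter_count",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    num_parents: int = 8
    mutation_rate: float = 0.1
    mutation_range: float = 1.0  # half-width of the uniform gene increment
    mutation_mode: str = "per_offspring"  # or "per_gene"
    generations: int = 100
    batch_size: int = 32
    init_dist: str = "uniform"
    seed: int = 0
    fitness_mode: str = "minibatch"  # or "fullbatch"
    keep_both_offspring: bool = False

    def __post_init__(self):
        if not 2 <= self.num_parents <= self.population_size:
            raise ValueError("need 2 <= num_parents <= population_size")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.mutation_range <= 0:
            raise ValueError("mutation_range must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.fitness_mode not in ("minibatch", "fullbatch"):
            raise ValueError("fitness_mode must be 'minibatch' or 'fullbatch'")
        if self.mutation_mode not in ("per_offspring", "per_gene"):
            raise ValueError("mutation_mode must be 'per_offspring' or 'per_gene'")


@dataclass
class Population:
    members: list[np.ndarray]
    fitness: list[float] | None = None
    generation: int = 0

    def __post_init__(self):
        lengths = {m.size for m in self.members}
        if len(lengths) > 1:
            raise ValueError("all chromosomes must share one length")
        if self.fitness is not None and len(self.fitness) != len(self.members):
            raise ValueError("fitness must align index-wise with members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GAResult:
    best_weights: np.ndarray
    best_fitness: float
    best_fitness_history: list[float] = field(default_factory=list)
    final_population: Population | None = None
    config: GAConfig | None = None


def fitness(spec: net.NetworkSpec, weights: np.ndarray, images: np.ndarray, labels: np.ndarray) -> float:
    """Classification error rate (FP + FN) / N of the chromosome on a batch."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("fitness needs a non-empty batch")
    ws = net.restore_weights(weights, spec)
    pred = net.predict(spec, ws, images)
    return float(np.mean(pred != labels))


def select_parents(population: Population, k: int) -> list[np.ndarray]:
    """The k lowest-error members, best first; ties broken by lower index."""
    if population.fitness is None:
        raise ValueError("population fitness has not been computed")
    if not 1 <= k <= len(population):
        raise ValueError(f"k={k} out of range for population of {len(population)}")
    order = np.argsort(np.asarray(population.fitness), kind="stable")
    return [population.members[i] for i in order[:k]]


def single_point_crossover(
    p1: np.ndarray, p2: np.ndarray, point: int
) -> tuple[np.ndarray, np.ndarray]:
    """Swap tails at ``point``: offspring are p1[:point]+p2[point:] and vice versa."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.size != p2.size:
        raise ValueError(f"parent length mismatch: {p1.size} vs {p2.size}")
    if not 1 <= point <= p1.size - 1:
        raise ValueError(f"crossover point {point} outside [1, {p1.size - 1}]")
    c1 = np.concatenate([p1[:point], p2[point:]])
    c2 = np.concatenate([p2[:point], p1[point:]])
    return c1, c2


def mutate(
    offspring: np.ndarray,
    rate: float,
    mutation_range: float,
    rng: int | np.random.Generator,
    mode: str = "per_offspring",
) -> np.ndarray:
    """Perturb genes with uniform(-range, +range) increments.

    ``per_offspring`` (default): with probability ``rate`` exactly one
    uniformly chosen gene is perturbed, otherwise the offspring is
    returned unchanged.  ``per_gene``: every gene is independently
    perturbed with probability ``rate``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if mutation_range <= 0:
        raise ValueError("mutation_range must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.array(offspring, dtype=float, copy=True)
    if mode == "per_offspring":
        if rng.random() < rate:
            gene = rng.integers(out.size)
            out[gene] += rng.uniform(-mutation_range, mutation_range)
    elif mode == "per_gene":
        hits = rng.random(out.size) < rate
        out[hits] += rng.uniform(-mutation_range, mutation_range, int(hits.sum()))
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    return out


def evolve_generation(
    population: Population, config: GAConfig, rng: np.random.Generator
) -> Population:
    """One elitist generational replacement step.

    The ``num_parents`` fittest members survive unchanged; the remaining
    slots are filled by single-point crossover of cyclically paired
    parents (pair i is parents i and i+1 mod k) at a random cut, then
    mutation.  By default one offspring per pair is kept; with
    ``keep_both_offspring`` both enter before the next pair is used.
    """
    parents = select_parents(population, config.num_parents)
    length = parents[0].size
    children: list[np.ndarray] = []
    n_children = config.population_size - config.num_parents
    pair_i = 0
    while len(children) < n_children:
        p1 = parents[pair_i % len(parents)]
        p2 = parents[(pair_i + 1) % len(parents)]
        point = int(rng.integers(1, length)) if length > 1 else 1
        c1, c2 = single_point_crossover(p1, p2, point)
        batch = (c1, c2) if config.keep_both_offspring else (c1,)
        for c in batch:
            if len(children) < n_children:
                children.append(
                    mutate(c, config.mutation_rate, config.mutation_range, rng,
                           config.mutation_mode)
                )
        pair_i += 1
    return Population(
        members=[p.copy() for p in parents] + children,
        fitness=None,
        generation=population.generation + 1,
    )


def train_ga(spec: net.NetworkSpec, train_set, config: GAConfig) -> GAResult:
    """Evolve the flat weight vector of ``spec`` on a labeled dataset.

    ``train_set`` is a :class:`gacnn.data.Dataset` (or any object with
    ``pixels_array()`` and ``labels_array()``).  Per generation, fitness
    is evaluated either on the next mini-batch (cycling through the
    training set in seeded shuffled order) or on the full set.  Returns
    the best-ever member by recorded fitness plus the per-generation
    best-fitness history (length ``generations + 1``, including the
    initial population).
    """
    images = train_set.pixels_array()
    labels = train_set.labels_array()
    if labels.size == 0:
        raise ValueError("empty training set")

    master = np.random.SeedSequence(config.seed)
    init_seq, evo_seq, batch_seq = master.spawn(3)
    init_rngs = [np.random.default_rng(s) for s in init_seq.spawn(config.population_size)]
    evo_rng = np.random.default_rng(evo_seq)
    batch_rng = np.random.default_rng(batch_seq)

    members = [
        net.flatten_weights(net.init_weights(spec, config.init_dist, rng))
        for rng in init_rngs
    ]
    population = Population(members=members, generation=0)
    cycler = BatchCycler(labels.size, config.batch_size, batch_rng)

    best_vec: np.ndarray | None = None
    best_fit = np.inf
    history: list[float] = []
    for gen in range(config.generations + 1):
        if config.fitness_mode == "fullbatch":
            bx, by = images, labels
        else:
            idx = cycler.next_batch()
            bx, by = images[idx], labels[idx]
        fits = [fitness(spec, m, bx, by) for m in population.members]
        population.fitness = fits
        gen_best = int(np.argmin(fits))
        history.append(fits[gen_best])
        if fits[gen_best] < best_fit:
            best_fit = fits[gen_best]
            best_vec = population.members[gen_best].copy()
        if gen < config.generations:
            population = evolve_generation(population, config, evo_rng)
    assert best_vec is not None
    return GAResult(
        best_weights=best_vec,
        best_fitness=best_fit,
        best_fitness_history=history,
        final_population=population,
        config=config,
    )


def population_parameter_count(weights_per_solution: int, population_size: int) -> int:
    """Total parameters held by a population (per-solution count x members)."""
    if weights_per_solution < 0 or population_size < 0:
        raise ValueError("counts must be non-negative")
    return int(weights_per_solution) * int(population_size)
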