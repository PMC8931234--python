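"""Population dynamics on polyomino genotypes.

A population of N binary genomes evolves by fitness-proportionate
(roulette-wheel) selection with replacement followed by point mutation; no
crossover and no elitism.  UND phenotypes always have fitness zero; bounded
shapes are scored by one of three protocols:

* ``unit`` — every non-UND shape has fitness 1 (neutral evolution over the
  viable part of the map);
* ``random`` — each newly encountered shape draws a fitness uniformly on
  [0, 1], fixed for the rest of the run and redrawn between runs;
* ``size`` — a shape of s cells has fitness 1 / (|s - s*| + 1), peaking at
  the target size s*.

The headline experiment evolves S(16, 64) populations (N = 100, mu = 0.1
expected mutations per genome per generation) under size fitness with
s* = 16 and records which 16-cell shape *fixes* in each run; the fixed
shapes are then tallied by symmetry class, where the strong excess of D4
and C4 shapes relative to their share of the morphospace is the signature
of biased variation.

The mutation rate is interpreted as expected mutations per genome per
generation and applied per locus at rate mu / L; set ``per_locus=True`` to
apply mu at each locus literally.  Fixation is operationalized as one
optimal-fitness phenotype carried by more than ``fixation_share`` of the
population for ``fixation_hold`` consecutive generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polyomino import PolyominoGPMap, genotype_seed
from .shapes import SymmetryClass, symmetry_class
from ._kernels import key_to_cells


class ExtinctionError(RuntimeError):
    """Every genome in the population has fitness zero."""


_PROTOCOLS = ("unit", "random", "size")


@dataclass
class EvolutionConfig:
    """Parameters of one evolutionary run (defaults match the headline
    experiment)."""

    n_tiles: int = 16
    bits_per_color: int = 6
    population_size: int = 100
    mutation_rate: float = 0.1
    per_locus: bool = False
    fitness_protocol: str = "size"
    target_size: int = 16
    max_generations: int = 5000
    fixation_share: float = 0.5
    fixation_hold: int = 10
    cutoff: int = 16
    repeats: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.fitness_protocol not in _PROTOCOLS:
            raise ValueError(f"unknown fitness protocol "
                             f"{self.fitness_protocol!r}; choose from "
                             f"{_PROTOCOLS}")
        if not 0.0 <= self.mutation_rate <= 1.0 and not self.per_locus:
            raise ValueError("per-genome mutation rate outside [0, 1] only "
                             "makes sense with per_locus=False")
        if not 0.0 < self.fixation_share <= 1.0:
            raise ValueError("fixation_share must be in (0, 1]")
        if self.fixation_hold < 1 or self.population_size < 1:
            raise ValueError("fixation_hold and population_size must be "
                             ">= 1")

    @property
    def genome_length(self) -> int:
        return 4 * self.n_tiles * self.bits_per_color


@dataclass(frozen=True)
class FixationRecord:
    """Outcome of one run: the first optimal phenotype to fix."""

    run_id: int
    fixed_key: bytes
    generation: int
    symmetry: SymmetryClass
    size: int

    @property
    def cells(self):
        return key_to_cells(self.fixed_key)


def fitness(phenotype_key, protocol: str, target_size: int,
            random_values: dict | None = None,
            run_rng: np.random.Generator | None = None) -> float:
    """Fitness of one phenotype key (None = UND -> 0) under a protocol.

    ``random_values`` caches the per-run lazily drawn values of the random
    protocol.
    """
    if protocol not in _PROTOCOLS:
        raise ValueError(f"unknown fitness protocol {protocol!r}")
    if phenotype_key is None:
        return 0.0
    if protocol == "unit":
        return 1.0
    if protocol == "size":
        s = len(phenotype_key) // 8
        return 1.0 / (abs(s - target_size) + 1)
    if random_values is None or run_rng is None:
        raise ValueError("random protocol needs a per-run value cache and "
                         "rng")
    if phenotype_key not in random_values:
        random_values[phenotype_key] = float(run_rng.random())
    return random_values[phenotype_key]


def next_generation(population: np.ndarray, fitnesses: np.ndarray,
                    mu: float, rng: np.random.Generator,
                    per_locus: bool = False) -> np.ndarray:
    """Roulette-wheel selection with replacement, then point mutation.

    ``population`` is an (N, L) 0/1 array.  Each of the N slots draws a
    parent with probability proportional to fitness; clones then receive
    independent per-locus bit flips at rate mu/L (or mu if ``per_locus``).
    """
    pop = np.asarray(population)
    fit = np.asarray(fitnesses, dtype=float)
    if pop.shape[0] != fit.shape[0]:
        raise ValueError("population and fitness lengths differ")
    total = fit.sum()
    if total <= 0:
        raise ExtinctionError("all genomes have zero fitness")
    N, L = pop.shape
    idx = rng.choice(N, size=N, replace=True, p=fit / total)
    offspring = pop[idx].copy()
    rate = mu if per_locus else mu / L
    n_flips = rng.binomial(N * L, rate)
    if n_flips:
        flat = rng.choice(N * L, size=n_flips, replace=False)
        offspring.reshape(-1)[flat] ^= 1
    return offspring


def _optimal(key, cfg: EvolutionConfig) -> bool:
    """Whether a phenotype key sits at the fitness optimum of the protocol."""
    if key is None:
        return False
    if cfg.fitness_protocol == "size":
        return len(key) // 8 == cfg.target_size
    return True


def run_to_fixation(config: EvolutionConfig,
                    gp_map: PolyominoGPMap | None = None,
                    run_id: int = 0,
                    initial_population: np.ndarray | None = None):
    """One evolutionary run; returns a FixationRecord or None on timeout.

    The run starts from N i.i.d. uniform random genomes (unless an initial
    population is given) and stops at the first optimum phenotype whose
    carrier share exceeds ``fixation_share`` for ``fixation_hold``
    consecutive generations.  Phenotype evaluation is memoized per genotype
    within the run.
    """
    cfg = config
    if gp_map is None:
        gp_map = PolyominoGPMap(cfg.n_tiles, cfg.bits_per_color, cfg.cutoff,
                                cfg.repeats, master_seed=cfg.seed)
    rng = np.random.default_rng((cfg.seed, run_id))
    N, L = cfg.population_size, cfg.genome_length
    if initial_population is None:
        pop = rng.integers(0, 2, (N, L), dtype=np.uint8)
    else:
        pop = np.array(initial_population, dtype=np.uint8)
    memo: dict = {}
    random_values: dict = {}
    candidate = None
    streak = 0
    for gen in range(cfg.max_generations):
        keys = []
        fresh_idx = []
        fresh_cols = []
        for i in range(N):
            gbytes = pop[i].tobytes()
            if gbytes in memo:
                keys.append(memo[gbytes])
            else:
                keys.append(gbytes)  # placeholder, resolved below
                fresh_idx.append(i)
                fresh_cols.append(gbytes)
        if fresh_idx:
            cols = gp_map.bits_to_colors(pop[fresh_idx])
            seeds = np.array([genotype_seed(cols[j], cfg.seed)
                              for j in range(len(fresh_idx))],
                             dtype=np.int64)
            new_keys = gp_map.phenotype_keys_batch(cols, seeds)
            for j, i in enumerate(fresh_idx):
                memo[fresh_cols[j]] = new_keys[j]
                keys[i] = new_keys[j]
        fit = np.array([fitness(k, cfg.fitness_protocol, cfg.target_size,
                                random_values, rng) for k in keys])
        # fixation bookkeeping: share of the most common optimal phenotype
        tally: dict = {}
        for k in keys:
            if _optimal(k, cfg):
                tally[k] = tally.get(k, 0) + 1
        leader = max(tally, key=tally.get) if tally else None
        if leader is not None and tally[leader] > cfg.fixation_share * N:
            streak = streak + 1 if leader == candidate else 1
            candidate = leader
        else:
            candidate, streak = None, 0
        if candidate is not None and streak >= cfg.fixation_hold:
            # 1-based: a population monomorphic at an optimum from the start
            # fixes at generation == fixation_hold
            return FixationRecord(run_id, candidate, gen + 1,
                                  symmetry_class(key_to_cells(candidate)),
                                  len(candidate) // 8)
        pop = next_generation(pop, fit, cfg.mutation_rate, rng,
                              cfg.per_locus)
    return None


@dataclass
class EvolutionExperiment:
    """Aggregate of many runs: fixation records plus failure tallies."""

    records: list = field(default_factory=list)
    timeouts: int = 0
    extinctions: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.records) + self.timeouts + self.extinctions


def run_many(config: EvolutionConfig, n_runs: int,
             gp_map: PolyominoGPMap | None = None) -> EvolutionExperiment:
    """Run ``n_runs`` independent replicates (seeded from config.seed)."""
    cfg = config
    if gp_map is None:
        gp_map = PolyominoGPMap(cfg.n_tiles, cfg.bits_per_color, cfg.cutoff,
                                cfg.repeats, master_seed=cfg.seed)
    exp = EvolutionExperiment()
    for run_id in range(n_runs):
        try:
            rec = run_to_fixation(cfg, gp_map, run_id)
        except ExtinctionError:
            exp.extinctions += 1
            continue
        if rec is None:
            exp.timeouts += 1
        else:
            exp.records.append(rec)
    return exp


def fixation_symmetry_fraction(records, classes) -> float:
    """Fraction of fixation records whose symmetry label is in ``classes``."""
    records = list(records)
    if not records:
        raise ValueError("no fixation records")
    labels = {c.label if isinstance(c, SymmetryClass) else str(c)
              for c in classes}
    hits = sum(1 for r in records if r.symmetry.label in labels)
    return hits / len(records)


def fixation_frequency_table(records):
    """Counts of fixed phenotype keys across runs (for comparison against
    random-sampling P(p), the arrival-of-the-frequent check)."""
    from .sampling import FrequencyTable

    records = list(records)
    counts: dict = {}
    for r in records:
        counts[r.fixed_key] = counts.get(r.fixed_key, 0) + 1
    return FrequencyTable(counts, n_samples=len(records), n_und=0)
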