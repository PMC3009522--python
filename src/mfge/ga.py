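"""Niched genetic algorithm over fixed-length gene-subset chromosomes.

A chromosome is a string of 15 slots, each holding a gene code (1-based) or
the empty marker 0; its decoded subset is the set of non-zero codes, which
are kept pairwise distinct.  Initialization and mutation sample genes from
the gene frequency map, so filter-favoured genes enter the population more
often.  The population (default 100) is split into two niches of 50 evolved
separately with tournament selection (size 3), single-point crossover
(p=0.7) and chained multi-point mutation (0.1, then 0.25 for each further
point); every 10 generations the best chromosome of each niche migrates to
the other.  An iteration stops at generation 100 or when a niche's mean
pairwise Jaccard similarity reaches 0.9; the outer loop repeats the whole
evolution (default 100 iterations), collecting each iteration's best
subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .ensemble import FitnessValue
from .mapping import GeneFrequencyMap, PoolExhaustedError, draw_gene

log = logging.getLogger(__name__)

__all__ = [
    "Chromosome",
    "GAConfig",
    "SubsetRecord",
    "SubsetCollection",
    "init_chromosome",
    "crossover",
    "mutate",
    "mutation_count",
    "tournament_select",
    "migrate",
    "population_similarity",
    "run_iteration",
    "run_ge",
]

EMPTY = 0


@dataclass
class Chromosome:
    """Fixed-length slot string; non-zero entries are distinct gene codes."""

    slots: np.ndarray
    fitness: FitnessValue | None = None

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=np.int64)

    def decode(self) -> frozenset[int]:
        return frozenset(int(s) for s in self.slots if s != EMPTY)

    @property
    def subset_size(self) -> int:
        return int((self.slots != EMPTY).sum())

    def is_valid(self, size: int) -> bool:
        nz = self.slots[self.slots != EMPTY]
        return len(self.slots) == size and len(nz) == len(set(nz.tolist()))

    def copy(self) -> "Chromosome":
        return Chromosome(self.slots.copy(), self.fitness)


@dataclass
class GAConfig:
    """Engine settings; the defaults are the reference configuration."""

    iterations: int = 100
    population_size: int = 100
    niches: int = 2
    migration_interval: int = 10
    migration_count: int = 1
    chromosome_size: int = 15
    crossover_prob: float = 0.7
    mutation_prob: float = 0.1
    mutation_chain_prob: float = 0.25
    tournament_size: int = 3
    max_generations: int = 100
    similarity_threshold: float = 0.9
    # expected initial subset size 6 of 15 slots (midpoint of the 2-10
    # operating band): fill_prob = 6/15
    fill_prob: float = 0.4
    elitism: int = 1
    w1: float = 0.5
    w2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size % self.niches:
            raise ValueError("population_size must be divisible by niches")
        for p in (self.crossover_prob, self.mutation_prob,
                  self.mutation_chain_prob, self.fill_prob,
                  self.similarity_threshold):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")

    @property
    def niche_size(self) -> int:
        return self.population_size // self.niches


@dataclass
class SubsetRecord:
    """One GE iteration's harvest: best subset plus convergence metadata."""

    genes: frozenset[str]
    termination_generation: int
    size: int
    fitness: FitnessValue


@dataclass
class SubsetCollection:
    records: list[SubsetRecord] = field(default_factory=list)
    fold_id: int | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def mean_termination_generation(self) -> float:
        return float(np.mean([r.termination_generation for r in self.records]))

    def mean_subset_size(self) -> float:
        return float(np.mean([r.size for r in self.records]))


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def init_chromosome(
    fmap: GeneFrequencyMap,
    size: int,
    fill_prob: float,
    rng: np.random.Generator,
) -> Chromosome:
    """Fill each slot with probability ``fill_prob`` by a frequency-map draw
    (excluding genes already present), else leave it empty; an all-empty
    chromosome is redrawn."""
    while True:
        slots = np.full(size, EMPTY, dtype=np.int64)
        present: set[int] = set()
        for i in range(size):
            if rng.random() < fill_prob:
                try:
                    code = draw_gene(fmap, present, rng=rng)
                except PoolExhaustedError:
                    break
                slots[i] = code
                present.add(code)
        if present:
            return Chromosome(slots)


def crossover(
    a: Chromosome, b: Chromosome, p_c: float, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover with probability ``p_c``; duplicate genes
    introduced by the tail swap are repaired by zeroing the later slot."""
    if len(a.slots) != len(b.slots):
        raise ValueError("parent length mismatch")
    if rng.random() >= p_c:
        return a.copy(), b.copy()
    size = len(a.slots)
    cut = int(rng.integers(1, size))
    s1 = np.concatenate([a.slots[:cut], b.slots[cut:]])
    s2 = np.concatenate([b.slots[:cut], a.slots[cut:]])
    return Chromosome(_dedup(s1)), Chromosome(_dedup(s2))


def _dedup(slots: np.ndarray) -> np.ndarray:
    seen: set[int] = set()
    out = slots.copy()
    for i, s in enumerate(out):
        if s == EMPTY:
            continue
        if s in seen:
            out[i] = EMPTY
        else:
            seen.add(int(s))
    return out


def mutation_count(p_m: float, p_chain: float, rng: np.random.Generator) -> int:
    """Number of point mutations under the chained law:
    P(M >= 1) = ``p_m``, P(M >= r+1 | M >= r) = ``p_chain``, hence
    E[M] = p_m / (1 - p_chain)."""
    if rng.random() >= p_m:
        return 0
    m = 1
    while rng.random() < p_chain:
        m += 1
    return m


def mutate(
    c: Chromosome,
    fmap: GeneFrequencyMap,
    p_m: float,
    p_chain: float,
    rng: np.random.Generator,
    empty_prob: float = 0.6,
) -> Chromosome:
    """Chained multi-point mutation (see :func:`mutation_count` for the
    law governing the number of points).

    Each point mutation picks a uniform slot and writes either the empty
    marker (probability ``empty_prob``, the slot-empty rate used at
    initialization) or a frequency-map draw excluding genes already
    present — so subsets can shrink as well as grow.
    """
    out = c.copy()
    out.fitness = None
    for _ in range(mutation_count(p_m, p_chain, rng)):
        i = int(rng.integers(len(out.slots)))
        if rng.random() < empty_prob:
            out.slots[i] = EMPTY
        else:
            present = set(out.slots[out.slots != EMPTY].tolist()) - {int(out.slots[i])}
            try:
                out.slots[i] = draw_gene(fmap, present, rng=rng)
            except PoolExhaustedError:
                out.slots[i] = EMPTY
    return out


def _fitness_key(c: Chromosome) -> tuple[float, int]:
    f = c.fitness.combined if c.fitness is not None else -1.0
    return (f, -c.subset_size)


def tournament_select(
    pop: list[Chromosome], size: int, rng: np.random.Generator
) -> Chromosome:
    """Draw ``size`` chromosomes with replacement; return the best combined
    fitness, ties broken by smaller subset then earlier index."""
    idx = rng.integers(len(pop), size=size)
    best = None
    for i in sorted(int(j) for j in idx):
        if best is None or _fitness_key(pop[i]) > _fitness_key(best):
            best = pop[i]
    return best


def migrate(niches: list[list[Chromosome]], count: int = 1) -> list[list[Chromosome]]:
    """Copy each niche's top ``count`` chromosomes over the worst ``count``
    of the next niche (ring topology); niche sizes are preserved."""
    if len(niches) < 2:
        raise ValueError("migration needs >= 2 niches")
    tops = [
        sorted(n, key=_fitness_key, reverse=True)[:count] for n in niches
    ]
    out = []
    for j, niche in enumerate(niches):
        incoming = tops[(j - 1) % len(niches)]
        worst = sorted(range(len(niche)), key=lambda i: _fitness_key(niche[i]))[:count]
        new = list(niche)
        for slot, mig in zip(worst, incoming):
            new[slot] = mig.copy()
        out.append(new)
    return out


def population_similarity(pop: list[Chromosome]) -> float:
    """Mean pairwise Jaccard similarity of decoded subsets (empty vs empty
    counts as 1)."""
    n = len(pop)
    if n == 0:
        raise ValueError("empty population")
    if n == 1:
        return 1.0
    codes = sorted({int(s) for c in pop for s in c.slots if s != EMPTY})
    if not codes:
        return 1.0
    pos = {c: i for i, c in enumerate(codes)}
    M = np.zeros((n, len(codes)), dtype=bool)
    for i, c in enumerate(pop):
        for s in c.slots:
            if s != EMPTY:
                M[i, pos[int(s)]] = True
    inter = (M.astype(np.int32) @ M.T.astype(np.int32)).astype(float)
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.where(union == 0, 1, union), 1.0)
    iu = np.triu_indices(n, k=1)
    return float(jac[iu].mean())


# ---------------------------------------------------------------------------
# Evolution loops
# ---------------------------------------------------------------------------

FitnessFn = Callable[[frozenset[int]], FitnessValue]


def _evaluate(pop: list[Chromosome], fitness_fn: FitnessFn) -> None:
    for c in pop:
        if c.fitness is None:
            c.fitness = fitness_fn(c.decode())


def run_iteration(
    fitness_fn: FitnessFn,
    fmap: GeneFrequencyMap,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[Chromosome, int]:
    """One full evolution: returns (best-ever chromosome, termination
    generation).

    Generational replacement with elitism (best of each niche carried
    over), migration every ``migration_interval`` generations, termination
    at ``max_generations`` or when the pooled population's mean pairwise
    similarity reaches the threshold.  Pooling matters: the niches evolve
    apart, so population-level convergence requires migration to spread
    one consensus subset across both niches.
    """
    niches = [
        [init_chromosome(fmap, cfg.chromosome_size, cfg.fill_prob, rng)
         for _ in range(cfg.niche_size)]
        for _ in range(cfg.niches)
    ]
    for n in niches:
        _evaluate(n, fitness_fn)
    best = max((c for n in niches for c in n), key=_fitness_key).copy()

    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        new_niches = []
        for niche in niches:
            elite = sorted(niche, key=_fitness_key, reverse=True)[: cfg.elitism]
            new = [e.copy() for e in elite]
            while len(new) < cfg.niche_size:
                p1 = tournament_select(niche, cfg.tournament_size, rng)
                p2 = tournament_select(niche, cfg.tournament_size, rng)
                c1, c2 = crossover(p1, p2, cfg.crossover_prob, rng)
                for child in (c1, c2):
                    if len(new) < cfg.niche_size:
                        child = mutate(
                            child, fmap, cfg.mutation_prob,
                            cfg.mutation_chain_prob, rng,
                            empty_prob=1.0 - cfg.fill_prob,
                        )
                        if child.subset_size == 0:
                            child = init_chromosome(
                                fmap, cfg.chromosome_size, cfg.fill_prob, rng
                            )
                        new.append(child)
            new_niches.append(new)
        niches = new_niches
        for n in niches:
            _evaluate(n, fitness_fn)
        cand = max((c for n in niches for c in n), key=_fitness_key)
        if _fitness_key(cand) > _fitness_key(best):
            best = cand.copy()
        if cfg.niches >= 2 and gen % cfg.migration_interval == 0:
            niches = migrate(niches, cfg.migration_count)
        pooled = [c for n in niches for c in n]
        if population_similarity(pooled) >= cfg.similarity_threshold:
            break
    return best, gen


def run_ge(
    fitness_fn: FitnessFn,
    fmap: GeneFrequencyMap,
    cfg: GAConfig,
    seed: int | None = None,
) -> SubsetCollection:
    """Outer genetic-ensemble loop: ``cfg.iterations`` independent
    evolutions, each contributing its best subset and convergence metadata.

    Seeding fans out through a :class:`numpy.random.SeedSequence`, so the
    whole collection is reproducible from one master seed and any single
    iteration can be replayed in isolation.
    """
    if cfg.iterations < 1:
        raise ValueError("iterations must be >= 1")
    master = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(cfg.iterations)
    coll = SubsetCollection(seed=master)
    for it, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        best, gen = run_iteration(fitness_fn, fmap, cfg, rng)
        genes = frozenset(fmap.id_of(c) for c in best.decode())
        coll.records.append(
            SubsetRecord(genes, gen, best.subset_size, best.fitness)
        )
        log.info(
            "iteration %d: gen=%d size=%d combined=%.4f genes=%s",
            it, gen, best.subset_size,
            best.fitness.combined if best.fitness else float("nan"),
            ",".join(sorted(genes)),
        )
    return coll


def scaled_config(cfg: GAConfig, **overrides) -> GAConfig:
    """Convenience: a copy of ``cfg`` with fields replaced."""
    return replace(cfg, **overrides)
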