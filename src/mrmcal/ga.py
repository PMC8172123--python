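"""Real-valued genetic algorithm over flattened rule matrices.

Minimizing, generational GA with size-2 tournament selection, 10% elitism,
per-gene arithmetic ("uniform continuous") crossover, and a mutation
probability that grows linearly with the generation counter,
r_m = 0.01 + 0.002 * g_n.  Two non-standard additions: candidates whose
simulations die before the first clinical sampling time are replaced by
viable same-generation candidates (non-viability criterion), and every
candidate whose envelope lies inside the clinical ranges is retained in an
append-only bioplausible ensemble archive (ensemble retainment criterion).

The loop is fully deterministic given one root seed: replicate seeds for
candidate evaluation are derived from (root_seed, generation, candidate
index), so evaluations are stateless, independent, and schedule-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import abm, fitness as fit
from .fitness import Candidate, ClinicalTargets
from .mrm import GENE_MAX, GENE_MIN


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary hyperparameters.

    The full-scale study configuration is population 1024, 250 generations,
    50 replicates per candidate; the defaults here are the desk-scale
    equivalents (population 64, 30 generations, 10 replicates) used
    throughout the test suite.
    """

    population_size: int = 64
    max_generations: int = 30
    tournament_size: int = 2
    elite_fraction: float = 0.10
    mutation_base: float = 0.01
    mutation_increment: float = 0.002
    gene_min: float = GENE_MIN
    gene_max: float = GENE_MAX
    replicates_per_candidate: int = 10
    root_seed: int = 0
    fitness_ceiling: float | None = None
    per_gene_beta: bool = True
    per_gene_mutation: bool = False
    nonviable_mode: str = "any"
    range_mode: str = "max"
    max_redraws: int = 20

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction outside (0, 1)")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.replicates_per_candidate < 1:
            raise ValueError("replicates_per_candidate must be >= 1")
        if self.gene_min >= self.gene_max:
            raise ValueError("gene bounds inverted")

    @classmethod
    def full_scale(cls, **overrides) -> "GAConfig":
        base = dict(
            population_size=1024, max_generations=250, replicates_per_candidate=50
        )
        base.update(overrides)
        return cls(**base)

    @property
    def elite_count(self) -> int:
        return math.floor(self.elite_fraction * self.population_size)


@dataclass
class EnsembleMember:
    genome: np.ndarray
    fitness: float
    generation: int
    mortality_rate: float


class EnsembleArchive:
    """Append-only archive of bioplausible candidates; identical genomes are
    stored once."""

    def __init__(self) -> None:
        self.members: list[EnsembleMember] = []
        self._seen: set[bytes] = set()

    def add(self, candidate: Candidate, generation: int) -> bool:
        if not candidate.bioplausible:
            raise ValueError("only bioplausible candidates enter the ensemble")
        key = np.ascontiguousarray(candidate.genome).tobytes()
        if key in self._seen:
            return False
        self._seen.add(key)
        self.members.append(
            EnsembleMember(
                genome=candidate.genome.copy(),
                fitness=candidate.fitness,
                generation=generation,
                mortality_rate=(
                    candidate.envelope.mortality_rate
                    if candidate.envelope is not None
                    else float("nan")
                ),
            )
        )
        return True

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def genome_ranges(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-gene min/max across the archive (the ensemble's spread)."""
        if not self.members:
            raise ValueError("empty archive")
        arr = np.stack([m.genome for m in self.members])
        return arr.min(axis=0), arr.max(axis=0)


@dataclass
class DiversityEntry:
    generation: int
    per_gene_range: np.ndarray
    total: float


@dataclass
class GAState:
    """Full evolutionary trace returned by :func:`evolve`."""

    config: GAConfig
    generation: int = 0
    population: list[Candidate] = field(default_factory=list)
    archive: EnsembleArchive = field(default_factory=EnsembleArchive)
    best_fitness_trace: list[float] = field(default_factory=list)
    mean_fitness_trace: list[float] = field(default_factory=list)
    diversity_trace: list[DiversityEntry] = field(default_factory=list)

    @property
    def best(self) -> Candidate:
        return min(self.population, key=lambda c: c.fitness)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def initialize_population(
    config: GAConfig, n_genes: int, rng: np.random.Generator
) -> list[Candidate]:
    """population_size genomes with genes i.i.d. uniform on [gene_min, gene_max]."""
    return [
        Candidate(rng.uniform(config.gene_min, config.gene_max, size=n_genes))
        for _ in range(config.population_size)
    ]


def tournament_select(
    population: Sequence[Candidate],
    rng: np.random.Generator,
    tournament_size: int = 2,
    pool_size: int | None = None,
) -> list[Candidate]:
    """Repeated tournaments (sampling without replacement within a
    tournament, with replacement across tournaments); the lower-fitness
    member wins, ties are broken by a seeded coin flip."""
    for c in population:
        if not c.evaluated:
            raise ValueError("tournament requires evaluated candidates")
    n = len(population)
    pool_size = n if pool_size is None else pool_size
    pool: list[Candidate] = []
    for _ in range(pool_size):
        idx = rng.choice(n, size=tournament_size, replace=False)
        fits = np.array([population[i].fitness for i in idx])
        best = np.flatnonzero(fits == fits.min())
        winner = int(best[0]) if best.size == 1 else int(rng.choice(best))
        pool.append(population[idx[winner]])
    return pool


def apply_elitism(
    pool: Sequence[Candidate],
    previous_population: Sequence[Candidate],
    elite_fraction: float,
) -> list[Candidate]:
    """Replace the floor(elite_fraction * size) worst pool members with the
    same number of best previous-generation candidates; pool size and
    ordering are otherwise unchanged."""
    for c in list(pool) + list(previous_population):
        if not c.evaluated:
            raise ValueError("elitism requires evaluated candidates")
    pool = list(pool)
    n_e = math.floor(elite_fraction * len(pool))
    if n_e == 0:
        return pool
    worst = sorted(range(len(pool)), key=lambda i: -pool[i].fitness)[:n_e]
    best_prev = sorted(previous_population, key=lambda c: c.fitness)[:n_e]
    for slot, elite in zip(sorted(worst), best_prev):
        pool[slot] = elite.copy()
    return pool


def crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    rng: np.random.Generator,
    per_gene_beta: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform continuous crossover: c1 = b*p1 + (1-b)*p2 and the mirror
    child, with b ~ U(0,1) drawn per gene (default) or once per mating.
    Children conserve p1 + p2 gene-wise and stay within the gene bounds."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"parent lengths differ: {p1.shape} vs {p2.shape}")
    beta = rng.random(p1.size) if per_gene_beta else rng.random()
    c1 = beta * p1 + (1.0 - beta) * p2
    c2 = beta * p2 + (1.0 - beta) * p1
    return c1, c2


def mutation_rate(
    g_n: int, base: float = 0.01, increment: float = 0.002
) -> float:
    """r_m = base + increment * g_n, capped at 1."""
    if g_n < 0:
        raise ValueError("generation counter must be >= 0")
    return min(1.0, base + increment * g_n)


def mutate(
    genome: np.ndarray,
    g_n: int,
    rng: np.random.Generator,
    base: float = 0.01,
    increment: float = 0.002,
    gene_min: float = GENE_MIN,
    gene_max: float = GENE_MAX,
    per_gene: bool = False,
) -> np.ndarray:
    """With probability r_m(g_n) replace one uniformly chosen gene by a fresh
    uniform draw (the default, matching one mutation draw per child);
    ``per_gene=True`` applies the same probability independently per gene."""
    out = np.asarray(genome, dtype=float).copy()
    r_m = mutation_rate(g_n, base, increment)
    if per_gene:
        hit = rng.random(out.size) <= r_m
        out[hit] = rng.uniform(gene_min, gene_max, size=int(hit.sum()))
        return out
    if rng.random() <= r_m:
        idx = int(rng.integers(out.size))
        out[idx] = rng.uniform(gene_min, gene_max)
    return out


def population_diversity(
    population: Sequence[Candidate] | Sequence[np.ndarray],
    generation: int = 0,
) -> DiversityEntry:
    """Total diversity = sum over genes of (max - min) across the population."""
    if not len(population):
        raise ValueError("empty population")
    genomes = [
        c.genome if isinstance(c, Candidate) else np.asarray(c, dtype=float)
        for c in population
    ]
    arr = np.stack(genomes)
    ranges = arr.max(axis=0) - arr.min(axis=0)
    return DiversityEntry(generation=generation, per_gene_range=ranges, total=float(ranges.sum()))


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _evaluation_seeds(root_seed: int, generation: int, index: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(1, generation, index))
    return [int(s) for s in ss.generate_state(n, dtype=np.uint64)]


def default_evaluator(
    targets: ClinicalTargets,
    injury: abm.InjuryParams,
    sim_config: abm.SimConfig,
    ga_config: GAConfig,
) -> Callable[[np.ndarray, Sequence[int]], Candidate]:
    """The standard simulator-backed evaluation callback, a pure function of
    (genome, seeds)."""

    def evaluate(genome: np.ndarray, seeds: Sequence[int]) -> Candidate:
        return fit.evaluate_candidate(
            genome,
            injury,
            targets,
            sim_config,
            seeds,
            range_mode=ga_config.range_mode,
            nonviable_mode=ga_config.nonviable_mode,
        )

    return evaluate


def evolve(
    targets: ClinicalTargets,
    injury: abm.InjuryParams,
    sim_config: abm.SimConfig,
    ga_config: GAConfig,
    evaluate_fn: Callable[[np.ndarray, Sequence[int]], Candidate] | None = None,
    log_fn: Callable[[str], None] | None = None,
) -> GAState:
    """Run the full calibration loop and return the final state with traces.

    Per generation: evaluate new candidates (replicate seeds derived from
    (root_seed, generation, index)), replace non-viable candidates with
    uniformly chosen viable ones, retain bioplausible candidates in the
    archive, record traces, then tournament selection, elitism, pairing
    without replacement, crossover and mutation.  Elite candidates pass to
    the next generation verbatim (mutation bypassed) with their stored
    fitness, which makes the best-fitness trace monotone non-increasing.
    Stops at fitness 0 or after max_generations.
    """
    cfg = ga_config
    if evaluate_fn is None:
        evaluate_fn = default_evaluator(targets, injury, sim_config, cfg)
    n_genes = sim_config.genome_length
    rng_init = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.root_seed, spawn_key=(0,))
    )
    rng_ops = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.root_seed, spawn_key=(2,))
    )
    state = GAState(config=cfg)
    population = initialize_population(cfg, n_genes, rng_init)

    for g_n in range(cfg.max_generations):
        # evaluate whatever has not been evaluated (elites carry fitness)
        for i, cand in enumerate(population):
            if not cand.evaluated:
                seeds = _evaluation_seeds(
                    cfg.root_seed, g_n, i, cfg.replicates_per_candidate
                )
                population[i] = evaluate_fn(cand.genome, seeds)

        # non-viability criterion
        viable_idx = [i for i, c in enumerate(population) if c.viable]
        if not viable_idx:
            if g_n == 0:
                for attempt in range(cfg.max_redraws):
                    population = initialize_population(cfg, n_genes, rng_init)
                    for i, cand in enumerate(population):
                        seeds = _evaluation_seeds(
                            cfg.root_seed, g_n, i + (attempt + 1) * cfg.population_size,
                            cfg.replicates_per_candidate,
                        )
                        population[i] = evaluate_fn(cand.genome, seeds)
                    viable_idx = [i for i, c in enumerate(population) if c.viable]
                    if viable_idx:
                        break
            if not viable_idx:
                raise RuntimeError(
                    f"no viable candidate in generation {g_n} "
                    f"(every replicate set died before the first clinical time point)"
                )
        def under_ceiling(c: Candidate) -> bool:
            return cfg.fitness_ceiling is None or c.fitness <= cfg.fitness_ceiling

        donor_idx = [i for i in viable_idx if under_ceiling(population[i])]
        if not donor_idx:
            donor_idx = viable_idx
        for i, cand in enumerate(population):
            if not cand.viable or not under_ceiling(cand):
                donor = population[donor_idx[int(rng_ops.integers(len(donor_idx)))]]
                population[i] = donor.copy()

        # ensemble retainment
        for cand in population:
            if cand.bioplausible:
                state.archive.add(cand, g_n)

        # traces
        fits = np.array([c.fitness for c in population])
        state.best_fitness_trace.append(float(fits.min()))
        state.mean_fitness_trace.append(float(fits.mean()))
        state.diversity_trace.append(population_diversity(population, g_n))
        state.generation = g_n
        state.population = population
        if log_fn is not None:
            log_fn(
                f"generation {g_n}: best F = {fits.min():.4f}, "
                f"mean F = {fits.mean():.4f}, "
                f"diversity = {state.diversity_trace[-1].total:.1f}, "
                f"archive = {len(state.archive)}"
            )

        if fits.min() == 0.0 or g_n == cfg.max_generations - 1:
            break

        # breed the next generation
        pool = tournament_select(
            population, rng_ops, tournament_size=cfg.tournament_size
        )
        pool = apply_elitism(pool, population, cfg.elite_fraction)
        n_elite = cfg.elite_count
        elites = [
            c.copy() for c in sorted(population, key=lambda c: c.fitness)[:n_elite]
        ]
        order = rng_ops.permutation(len(pool))
        children: list[np.ndarray] = []
        need = cfg.population_size - n_elite
        k = 0
        while len(children) < need:
            a = pool[order[k % len(pool)]]
            b = pool[order[(k + 1) % len(pool)]]
            k += 2
            c1, c2 = crossover(a.genome, b.genome, rng_ops, cfg.per_gene_beta)
            children.extend([c1, c2])
        children = children[:need]
        population = elites + [
            Candidate(
                mutate(
                    ch,
                    g_n,
                    rng_ops,
                    cfg.mutation_base,
                    cfg.mutation_increment,
                    cfg.gene_min,
                    cfg.gene_max,
                    per_gene=cfg.per_gene_mutation,
                )
            )
            for ch in children
        ]

    return state
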