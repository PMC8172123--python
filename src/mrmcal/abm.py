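"""Reduced stochastic agent-based model of the endothelial-blood interface.

The simulator is a 2-D toroidal lattice of endothelial sites carrying a
damage level and an infection level, over which mobile immune-cell agents
(macrophages, neutrophils, TH0/TH1/TH2 lymphocytes) move by chemotaxis or
random walk.  Every cytokine rule is read from a Model Rule Matrix: each rule
belongs to one cell type, names one output mediator, and fires wherever an
agent of that type stands, producing

    max(0, sum_j matrix[r, j] * input_j) * production_scale

where the inputs are the start-of-step local mediator concentrations plus the
lattice damage and infection signals.  Mediator fields diffuse (4-neighbour
averaging on the torus) and decay each step.  The in-silico patient dies when
the total damage fraction exceeds 0.80, heals when damage and infection both
reach zero, and is censored at the horizon otherwise.

All replicate stochasticity flows from one integer seed per replicate through
a counter-based (Philox) generator, so every trajectory is exactly
reproducible and independent of how replicates are batched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mrm

DAMAGE_THRESHOLD = 0.80  # total damage fraction beyond which the patient dies

ENTITY_DAMAGE = "damage"
ENTITY_INFECTION = "infection"

DEFAULT_MEDIATORS: tuple[str, ...] = (
    "TNFa", "IL10", "IFNg", "IL4", "GCSF", "M1", "M2", "M3",
)

#: (cell type, output mediator) pairs; row order of the rule matrix.
DEFAULT_RULES: tuple[tuple[str, str], ...] = (
    ("macrophage", "TNFa"),
    ("macrophage", "IL10"),
    ("macrophage", "GCSF"),
    ("macrophage", "M1"),
    ("neutrophil", "TNFa"),
    ("neutrophil", "M2"),
    ("TH0", "M3"),
    ("TH1", "IFNg"),
    ("TH2", "IL4"),
    ("TH2", "IL10"),
)

DEFAULT_CELL_COUNTS: Mapping[str, int] = {
    "macrophage": 12,
    "neutrophil": 12,
    "TH0": 6,
    "TH1": 5,
    "TH2": 5,
}

#: Innate cells are recruited up the pro-inflammatory (TNFa) gradient; this
#: aggregation feedback is what lets inflammation stochastically ignite.
DEFAULT_ATTRACTANTS: Mapping[str, str] = {
    "macrophage": "TNFa",
    "neutrophil": "TNFa",
    "TH0": "TNFa",
    "TH1": "TNFa",
    "TH2": "TNFa",
}


@dataclass(frozen=True)
class InjuryParams:
    """The five dimensionless injury/host axes.

    injury_size: fraction of the lattice initially damaged, in [0, 1].
    microbial_invasiveness: infection spread rate per step, >= 0.
    microbial_toxigenesis: damage rate per step from infection, >= 0.
    environmental_toxicity: per-step probability of spontaneous re-exposure.
    host_resilience: per-step recovery rate of damaged tissue, in (0, 1].
    """

    injury_size: float
    microbial_invasiveness: float
    microbial_toxigenesis: float
    environmental_toxicity: float
    host_resilience: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.injury_size <= 1.0:
            raise ValueError(f"injury_size {self.injury_size} outside [0, 1]")
        if self.microbial_invasiveness < 0:
            raise ValueError("microbial_invasiveness must be >= 0")
        if self.microbial_toxigenesis < 0:
            raise ValueError("microbial_toxigenesis must be >= 0")
        if not 0.0 <= self.environmental_toxicity <= 1.0:
            raise ValueError("environmental_toxicity outside [0, 1]")
        if not 0.0 < self.host_resilience <= 1.0:
            raise ValueError("host_resilience outside (0, 1]")

    @classmethod
    def sterile_burn(
        cls,
        injury_size: float = 0.5,
        environmental_toxicity: float = 0.0,
        host_resilience: float = 0.007,
    ) -> "InjuryParams":
        """A caustic, sterile injury: no microbial spread or toxigenesis."""
        return cls(
            injury_size=injury_size,
            microbial_invasiveness=0.0,
            microbial_toxigenesis=0.0,
            environmental_toxicity=environmental_toxicity,
            host_resilience=host_resilience,
        )


@dataclass(frozen=True)
class SimConfig:
    """Structural constants of the reduced simulator.

    All spatial/temporal scales and the rule catalogue live here so that any
    factorization of the rule matrix can be exercised.  Per-step rates
    (decay, repair, toxicity) are expressed per time step.
    """

    grid_width: int = 40
    grid_height: int = 40
    step_minutes: float = 10.0
    mediators: tuple[str, ...] = DEFAULT_MEDIATORS
    diffusion: float = 0.2
    decay: float = 0.1
    production_scale: float = 0.3
    horizon_days: float = 22.0
    rules: tuple[tuple[str, str], ...] = DEFAULT_RULES
    cell_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    attractants: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ATTRACTANTS))
    # collateral endothelial damage per step per unit local mediator concentration
    mediator_toxicity: Mapping[str, float] = field(default_factory=lambda: {"TNFa": 0.008})
    toxicity_inhibitor: str | None = "IL10"
    inhibition_strength: float = 0.1
    phagocyte_types: tuple[str, ...] = ("macrophage", "neutrophil")
    phagocytosis_rate: float = 0.5
    damage_floor: float = 1e-3
    #: per-site mediator saturation (receptor/secretion saturation); keeps
    #: autocatalytic cytokine bursts bounded
    mediator_cap: float = 50.0

    def __post_init__(self) -> None:
        if self.grid_width < 1 or self.grid_height < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 <= self.diffusion <= 1.0:
            raise ValueError("diffusion outside [0, 1]")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay outside [0, 1]")
        if self.step_minutes <= 0:
            raise ValueError("step_minutes must be positive")
        if len(set(self.mediators)) != len(self.mediators):
            raise ValueError("duplicate mediator names")
        for cell, out in self.rules:
            if out not in self.mediators:
                raise ValueError(f"rule output {out!r} not a mediator")
            if cell not in self.cell_counts:
                raise ValueError(f"rule cell type {cell!r} has no cell count")
        for cell, att in self.attractants.items():
            if att not in self.entity_labels:
                raise ValueError(f"attractant {att!r} for {cell!r} is not an entity")
        for med in self.mediator_toxicity:
            if med not in self.mediators:
                raise ValueError(f"toxicity for unknown mediator {med!r}")
        if self.toxicity_inhibitor is not None and self.toxicity_inhibitor not in self.mediators:
            raise ValueError(f"unknown toxicity inhibitor {self.toxicity_inhibitor!r}")

    # -- derived structure --------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.grid_width * self.grid_height

    @property
    def entity_labels(self) -> tuple[str, ...]:
        return self.mediators + (ENTITY_DAMAGE, ENTITY_INFECTION)

    @property
    def rule_labels(self) -> tuple[str, ...]:
        return tuple(f"{cell}->{out}" for cell, out in self.rules)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def n_entities(self) -> int:
        return len(self.entity_labels)

    @property
    def genome_length(self) -> int:
        return self.n_rules * self.n_entities

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.cell_counts)

    @property
    def horizon_hours(self) -> float:
        return self.horizon_days * 24.0

    def steps_for_hours(self, hours: float) -> int:
        return math.ceil(round(hours * 60.0 / self.step_minutes, 9))

    def empty_matrix_labels(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return self.rule_labels, self.entity_labels

    def matrix_from_genome(self, genome: np.ndarray) -> mrm.ModelRuleMatrix:
        return mrm.unflatten(
            genome, rule_labels=self.rule_labels, entity_labels=self.entity_labels
        )


def desk_config(**overrides) -> SimConfig:
    """Small, fast configuration used for desk-scale calibration runs."""
    base = dict(
        grid_width=20,
        grid_height=20,
        step_minutes=30.0,
        horizon_days=2.0,
    )
    base.update(overrides)
    return SimConfig(**base)


DEFAULT_CONFIG = SimConfig()


@dataclass
class SimulationResult:
    """One stochastic trajectory: per-step lattice totals plus outcome."""

    mediators: tuple[str, ...]
    times_hours: np.ndarray          # (T,)
    totals: np.ndarray               # (T, n_mediators), lattice sums
    outcome: str                     # "died" | "healed" | "censored"
    death_time_hours: float | None
    seed: int

    def __post_init__(self) -> None:
        if (self.outcome == "died") != (self.death_time_hours is not None):
            raise ValueError("death_time_hours present iff outcome is 'died'")
        if self.totals.shape != (self.times_hours.size, len(self.mediators)):
            raise ValueError("totals shape does not match times/mediators")

    def series(self, mediator: str) -> np.ndarray:
        return self.totals[:, self.mediators.index(mediator)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.totals, columns=list(self.mediators))
        frame.insert(0, "time_hours", self.times_hours)
        return frame


def mortality_rate(results: Sequence[SimulationResult]) -> float:
    """Replicate mortality estimate R_m = died / n."""
    if not results:
        raise ValueError("no results")
    return sum(r.outcome == "died" for r in results) / len(results)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

class SimState:
    """Batched simulation state.

    Arrays carry a leading replicate axis; a single simulation is a batch of
    one.  Finished replicates are extracted and their rows dropped, so the
    arrays always hold only live replicates.
    """

    def __init__(
        self,
        params: InjuryParams,
        genome: np.ndarray,
        seeds: Sequence[int],
        config: SimConfig,
        horizon_hours: float | None = None,
    ) -> None:
        genome = mrm.validate_genome(genome)
        if genome.size != config.genome_length:
            raise ValueError(
                f"genome length {genome.size} != configured {config.genome_length}"
            )
        seeds = [int(s) for s in seeds]
        if len(set(seeds)) != len(seeds):
            raise ValueError("replicate seeds must be distinct")
        self.params = params
        self.config = config
        self.genome = genome
        self.weights = genome.reshape(config.n_rules, config.n_entities)
        self.seeds = seeds
        self.horizon_hours = (
            config.horizon_hours if horizon_hours is None else float(horizon_hours)
        )
        self.horizon_steps = config.steps_for_hours(self.horizon_hours)

        n = len(seeds)
        S = config.n_sites
        M = len(config.mediators)
        self.fields = np.zeros((n, M, S))
        self.damage = np.zeros((n, S))
        self.infection = np.zeros((n, S))
        self.clock_minutes = 0.0
        self.step_count = 0

        # contiguous injured patch: the first ceil(injury_size * S) row-major
        # sites, damage 1 (contiguous on the torus)
        k = math.ceil(params.injury_size * S)
        if params.injury_size > 0 and k == 0:
            raise ValueError("injury_size yields zero injured sites")
        self.damage[:, :k] = 1.0

        self.rngs = [np.random.Generator(np.random.Philox(key=s)) for s in seeds]
        self.positions: dict[str, np.ndarray] = {}
        for cell in config.cell_types:
            count = config.cell_counts[cell]
            pos = np.empty((n, count), dtype=np.int64)
            for r, rng in enumerate(self.rngs):
                pos[r] = rng.integers(0, S, size=count)
            self.positions[cell] = pos
        self.n_agents = int(sum(config.cell_counts.values()))

        # torus neighbour table (S, 4): up, down, left, right
        H, W = config.grid_height, config.grid_width
        idx = np.arange(S).reshape(H, W)
        self.nbr = np.stack(
            [
                np.roll(idx, 1, axis=0).reshape(-1),
                np.roll(idx, -1, axis=0).reshape(-1),
                np.roll(idx, 1, axis=1).reshape(-1),
                np.roll(idx, -1, axis=1).reshape(-1),
            ],
            axis=1,
        )

        # rule bookkeeping: rules grouped by owning cell type
        self._rules_of = {
            cell: [i for i, (c, _) in enumerate(config.rules) if c == cell]
            for cell in config.cell_types
        }
        self._rule_out = np.array(
            [config.mediators.index(out) for _, out in config.rules], dtype=np.int64
        )
        self._tox = np.zeros(M)
        for med, rate in config.mediator_toxicity.items():
            self._tox[config.mediators.index(med)] = rate
        self._inhibitor_idx = (
            config.mediators.index(config.toxicity_inhibitor)
            if config.toxicity_inhibitor is not None
            else None
        )

        # replicate bookkeeping: original index of each live row
        self.live = np.arange(n)
        self.trajectory = np.zeros((n, self.horizon_steps + 1, M))
        self.trajectory[:, 0, :] = 0.0
        self.results: dict[int, SimulationResult] = {}

    # -- convenience --------------------------------------------------------
    @property
    def n_live(self) -> int:
        return self.live.size

    @property
    def total_damage_fraction(self) -> np.ndarray:
        return self.damage.mean(axis=1)

    @property
    def clock_hours(self) -> float:
        return self.clock_minutes / 60.0

    def total_mediators(self) -> np.ndarray:
        """Lattice totals, shape (n_live, n_mediators)."""
        return self.fields.sum(axis=2)

    # -- outcome handling ----------------------------------------------------
    def _finish(self, local_idx: np.ndarray, outcome: str) -> None:
        for i in sorted(map(int, local_idx), reverse=True):
            orig = int(self.live[i])
            t = self.step_count
            self.results[orig] = SimulationResult(
                mediators=self.config.mediators,
                times_hours=np.arange(t + 1) * self.config.step_minutes / 60.0,
                totals=self.trajectory[orig, : t + 1].copy(),
                outcome=outcome,
                death_time_hours=self.clock_hours if outcome == "died" else None,
                seed=self.seeds[orig],
            )
        keep = np.ones(self.n_live, dtype=bool)
        keep[np.asarray(local_idx, dtype=int)] = False
        self._compact(keep)

    def _compact(self, keep: np.ndarray) -> None:
        self.live = self.live[keep]
        self.fields = self.fields[keep]
        self.damage = self.damage[keep]
        self.infection = self.infection[keep]
        self.rngs = [rng for rng, k in zip(self.rngs, keep) if k]
        for cell in self.positions:
            self.positions[cell] = self.positions[cell][keep]

    def check_outcomes(self) -> None:
        """Extract replicates that died (>80% damage) or healed (no damage,
        no infection).  Death takes precedence."""
        if self.n_live == 0:
            return
        frac = self.total_damage_fraction
        died = frac > DAMAGE_THRESHOLD
        healed = (~died) & (self.damage.sum(axis=1) == 0.0) & (
            self.infection.sum(axis=1) == 0.0
        )
        if died.any():
            self._finish(np.flatnonzero(died), "died")
            healed = healed[~died]
        if healed.any():
            self._finish(np.flatnonzero(healed), "healed")

    def finish_censored(self) -> None:
        if self.n_live:
            self._finish(np.arange(self.n_live), "censored")


# ---------------------------------------------------------------------------
# the step kernel
# ---------------------------------------------------------------------------

def step(state: SimState, matrix: mrm.ModelRuleMatrix | np.ndarray | None = None) -> SimState:
    """Advance every live replicate by one synchronous step.

    Phase order is fixed: (1) mediator diffusion and decay, (2) agent
    movement, (3) rule firing (inputs are start-of-step concentrations),
    (4) infection spread / toxigenesis / mediator-driven collateral damage,
    (5) repair, (6) environmental re-exposure.
    """
    cfg = state.config
    params = state.params
    if matrix is None:
        W = state.weights
    elif isinstance(matrix, mrm.ModelRuleMatrix):
        if matrix.rule_labels != cfg.rule_labels or matrix.entity_labels != cfg.entity_labels:
            raise ValueError("matrix labels do not match the simulator configuration")
        W = matrix.values
    else:
        W = np.asarray(matrix, dtype=float)
        if W.shape != (cfg.n_rules, cfg.n_entities):
            raise ValueError("matrix shape does not match the simulator configuration")

    R = state.n_live
    if R == 0:
        return state
    M = len(cfg.mediators)
    rows = np.arange(R)[:, None]
    rows3 = rows[:, :, None]
    H, Wd = cfg.grid_height, cfg.grid_width
    S = cfg.n_sites
    F0 = state.fields                       # start-of-step concentrations

    # (1) diffusion (4-neighbour averaging on the torus) then decay
    grid = F0.reshape(R, M, H, Wd)
    if cfg.diffusion > 0.0:
        nb_mean = 0.25 * (
            np.roll(grid, 1, axis=2)
            + np.roll(grid, -1, axis=2)
            + np.roll(grid, 1, axis=3)
            + np.roll(grid, -1, axis=3)
        )
        new = grid + cfg.diffusion * (nb_mean - grid)
    else:
        new = grid.copy()
    if cfg.decay > 0.0:
        new *= 1.0 - cfg.decay
    fields_new = new.reshape(R, M, S)

    # per-replicate randoms: one direction draw per agent + two event draws
    draws = np.empty((R, state.n_agents + 2))
    for r, rng in enumerate(state.rngs):
        draws[r] = rng.random(state.n_agents + 2)
    rand_dirs = (draws[:, : state.n_agents] * 4).astype(np.int64)

    # (2) movement: uphill on the attractant if any neighbour beats the
    # current site, else a seeded-random step
    offset = 0
    for cell in cfg.cell_types:
        pos = state.positions[cell]
        n_c = pos.shape[1]
        if n_c == 0:
            offset += n_c
            continue
        att_name = cfg.attractants.get(cell, ENTITY_DAMAGE)
        if att_name == ENTITY_DAMAGE:
            att = state.damage
        elif att_name == ENTITY_INFECTION:
            att = state.infection
        else:
            att = fields_new[:, cfg.mediators.index(att_name), :]
        nb = state.nbr[pos]                                     # (R, n, 4)
        nv = att[rows3, nb]
        cur = att[rows, pos]
        best = nv.argmax(axis=2)
        bestv = nv.max(axis=2)
        chosen = np.where(bestv > cur, best, rand_dirs[:, offset : offset + n_c])
        cols = np.arange(n_c)[None, :]
        state.positions[cell] = nb[rows, cols, chosen]
        offset += n_c

    # (3) rule firing from start-of-step inputs at the agents' new sites
    for cell in cfg.cell_types:
        rule_ids = state._rules_of[cell]
        if not rule_ids:
            continue
        pos = state.positions[cell]
        if pos.shape[1] == 0:
            continue
        med_in = F0[rows, :, pos]                               # (R, n, M)
        dmg_in = state.damage[rows, pos]
        inf_in = state.infection[rows, pos]
        X = np.concatenate(
            [med_in, dmg_in[:, :, None], inf_in[:, :, None]], axis=2
        )                                                       # (R, n, E)
        for rid in rule_ids:
            contrib = np.maximum(X @ W[rid], 0.0) * cfg.production_scale
            np.add.at(
                fields_new,
                (rows, int(state._rule_out[rid]), pos),
                contrib,
            )
    if cfg.mediator_cap > 0.0:
        np.clip(fields_new, 0.0, cfg.mediator_cap, out=fields_new)

    # (4) infection spread, toxigenesis, phagocytosis, collateral damage
    if params.microbial_invasiveness > 0.0:
        inf_grid = state.infection.reshape(R, H, Wd)
        nb_inf = 0.25 * (
            np.roll(inf_grid, 1, axis=1)
            + np.roll(inf_grid, -1, axis=1)
            + np.roll(inf_grid, 1, axis=2)
            + np.roll(inf_grid, -1, axis=2)
        )
        state.infection += params.microbial_invasiveness * nb_inf.reshape(R, S)
        np.clip(state.infection, 0.0, 1.0, out=state.infection)
    if params.microbial_toxigenesis > 0.0:
        state.damage += params.microbial_toxigenesis * np.minimum(state.infection, 1.0)
    if cfg.phagocytosis_rate > 0.0:
        for cell in cfg.phagocyte_types:
            pos = state.positions.get(cell)
            if pos is None or pos.shape[1] == 0:
                continue
            state.infection[rows, pos] = state.infection[rows, pos] * (
                1.0 - cfg.phagocytosis_rate
            )
    if state._tox.any():
        # systemic collateral damage: the lattice-mean pro-inflammatory load
        # injures endothelium everywhere, tempered by the mean
        # anti-inflammatory (inhibitor) level
        mean_conc = fields_new.mean(axis=2)               # (R, M)
        harm = mean_conc @ state._tox                     # (R,)
        if state._inhibitor_idx is not None and cfg.inhibition_strength > 0.0:
            harm = harm / (
                1.0 + cfg.inhibition_strength * mean_conc[:, state._inhibitor_idx]
            )
        state.damage += harm[:, None]
    np.clip(state.damage, 0.0, 1.0, out=state.damage)

    # (5) repair: damaged tissue recovers host_resilience damage units per
    # step (constant-rate healing, so full recovery is reachable)
    if params.host_resilience > 0.0:
        state.damage -= params.host_resilience
        np.clip(state.damage, 0.0, 1.0, out=state.damage)
        state.damage[state.damage < cfg.damage_floor] = 0.0

    # (6) environmental re-exposure: one random site per replicate
    if params.environmental_toxicity > 0.0:
        hits = np.flatnonzero(draws[:, state.n_agents] < params.environmental_toxicity)
        sites = (draws[:, state.n_agents + 1] * S).astype(np.int64)
        for r in hits:
            state.infection[r, sites[r]] = min(state.infection[r, sites[r]] + 1.0, 1.0)

    state.fields = fields_new
    state.step_count += 1
    state.clock_minutes += cfg.step_minutes
    state.trajectory[state.live, state.step_count, :] = fields_new.sum(axis=2)
    return state


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def init_simulation(
    params: InjuryParams,
    genome: np.ndarray,
    seed: int,
    config: SimConfig = DEFAULT_CONFIG,
    horizon_hours: float | None = None,
) -> SimState:
    """A single-replicate state (batch of one), fully determined by the seed."""
    return SimState(params, genome, [seed], config, horizon_hours)


def run_replicates(
    params: InjuryParams,
    genome: np.ndarray,
    seeds: Sequence[int],
    config: SimConfig = DEFAULT_CONFIG,
    horizon_hours: float | None = None,
) -> list[SimulationResult]:
    """Run independent stochastic replicates to completion.

    Each replicate ends at death (>80% damage), healing (zero damage and
    infection) or the horizon (censored); its trajectory holds the per-step
    lattice totals for every mediator up to its end.
    """
    state = SimState(params, genome, seeds, config, horizon_hours)
    state.check_outcomes()
    while state.n_live and state.step_count < state.horizon_steps:
        step(state)
        state.check_outcomes()
    state.finish_censored()
    return [state.results[i] for i in range(len(seeds))]


def run_simulation(
    params: InjuryParams,
    genome: np.ndarray,
    seed: int,
    config: SimConfig = DEFAULT_CONFIG,
    horizon_hours: float | None = None,
) -> SimulationResult:
    """One stochastic trajectory; identical inputs give identical output."""
    return run_replicates(params, genome, [seed], config, horizon_hours)[0]


def replicate_seeds(root_seed: int, n: int) -> list[int]:
    """Derive n distinct replicate seeds from one root seed (documented
    counter scheme: SeedSequence(root).generate_state)."""
    states = np.random.SeedSequence(int(root_seed)).generate_state(n, dtype=np.uint64)
    return [int(s) for s in states]
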