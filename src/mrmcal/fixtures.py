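"""Generated inputs: clinical-like targets, surrogate targets, and the
calibrated reference genome.

No machine-readable clinical cytokine values exist for the burn cohort that
motivates this tool (only figure-level ranges were ever available), so the
generators here reproduce the *shape* of that dataset — 5 cytokines (GCSF,
TNF-a, IL-4, IL-10, IFN-g), 15 sampling times over 22 days starting at 3 h,
a 50% cohort mortality rate, an IL-10 pulse peaking at day 5 — without
asserting any numerical cytokine level as ground truth.

Surrogate targets are built by running the simulator with a known genome and
converting its replicate envelope into a target file; by construction the
generating genome scores fitness 0 against them with matched seeds, which
anchors end-to-end recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from . import abm, fitness as fit, mrm

CLINICAL_CYTOKINES: tuple[str, ...] = ("TNFa", "IL10", "IFNg", "IL4", "GCSF")

#: 15 sampling times (hours) spanning 22 days, first at 3 h post-injury.
DEFAULT_TIME_POINTS_HOURS: tuple[float, ...] = (
    3, 6, 12, 24, 48, 72, 96, 120, 144, 192, 240, 288, 336, 432, 528,
)

#: Held out from fitness evaluation: 48 h and 8 days post-burn.
DEFAULT_HELD_OUT_HOURS: tuple[float, ...] = (48.0, 192.0)

#: IL-10 weight 2: doubling its fitness contribution suffices to recover the
#: day-5 IL-10 pulse that an equally weighted fitness misses.
DEFAULT_WEIGHTS: Mapping[str, float] = {"IL10": 2.0}

_REFERENCE_GENOME_RESOURCE = "reference_genome.json"


@dataclass(frozen=True)
class TargetSpec:
    """Shape parameters of a clinical-like target dataset."""

    cytokines: tuple[str, ...] = CLINICAL_CYTOKINES
    time_points_hours: tuple[float, ...] = DEFAULT_TIME_POINTS_HOURS
    horizon_days: float = 22.0
    first_sample_hours: float = 3.0
    mortality_rate: float = 0.5
    #: per-cytokine pulse peak time (hours); IL-10 peaks at day 5
    peak_hours: Mapping[str, float] = field(
        default_factory=lambda: {
            "TNFa": 12.0, "IL10": 120.0, "IFNg": 24.0, "IL4": 72.0, "GCSF": 48.0,
        }
    )
    peak_log_width: float = 0.9
    #: range width as a fraction of the upper bound (min = max * (1 - f))
    range_width_factor: float = 0.5
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points_hours, dtype=float)
        if np.any(np.diff(tp) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not math.isclose(tp[0], self.first_sample_hours):
            raise ValueError("first time point must equal first_sample_hours")
        if tp[-1] > self.horizon_days * 24.0:
            raise ValueError("last time point beyond the horizon")
        if not 0.0 < self.range_width_factor < 1.0:
            raise ValueError("range_width_factor outside (0, 1)")
        for c in self.cytokines:
            if c not in self.peak_hours:
                raise ValueError(f"no peak time for cytokine {c!r}")


def make_clinical_like_targets(spec: TargetSpec = TargetSpec()) -> fit.ClinicalTargets:
    """Smooth per-cytokine min/max pulses with the clinical dataset's shape.

    Each upper bound is a log-normal-like pulse in time with seeded
    amplitude and per-point jitter; the lower bound is the upper bound
    scaled down by the range-width factor.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    tp = np.asarray(spec.time_points_hours, dtype=float)
    hi = np.zeros((len(spec.cytokines), tp.size))
    lo = np.zeros_like(hi)
    for i, c in enumerate(spec.cytokines):
        tau = spec.peak_hours[c]
        amp = spec.amplitude * math.exp(0.25 * rng.standard_normal())
        pulse = amp * np.exp(-(np.log(tp / tau) ** 2) / (2.0 * spec.peak_log_width**2))
        jitter = 1.0 + 0.05 * rng.standard_normal(tp.size)
        hi[i] = pulse * np.clip(jitter, 0.5, 1.5)
        width = spec.range_width_factor * np.clip(
            0.8 + 0.4 * rng.random(tp.size), 0.0, 1.0
        )
        lo[i] = hi[i] * (1.0 - width)
    weights = np.array([DEFAULT_WEIGHTS.get(c, 1.0) for c in spec.cytokines])
    held_out = tuple(h for h in DEFAULT_HELD_OUT_HOURS if np.isclose(tp, h).any())
    return fit.ClinicalTargets(
        cytokines=spec.cytokines,
        time_points_hours=tp,
        range_min=lo,
        range_max=hi,
        mortality_rate=spec.mortality_rate,
        weights=weights,
        held_out_hours=held_out,
    )


# ---------------------------------------------------------------------------
# surrogate targets from a known genome
# ---------------------------------------------------------------------------

def surrogate_seeds(seed: int, n: int) -> list[int]:
    """Replicate seeds used by :func:`make_surrogate_targets`; pass the same
    seeds to re-score the generating genome at fitness 0."""
    return abm.replicate_seeds(seed, n)


def make_surrogate_targets(
    genome: np.ndarray,
    injury: abm.InjuryParams,
    config: abm.SimConfig,
    time_points_hours: Sequence[float],
    n_replicates: int = 10,
    seed: int = 0,
    cytokines: Sequence[str] | None = None,
    held_out_hours: Sequence[float] = (),
    inflate: float = 1.0,
    mortality_coefficient: float = 10.0,
) -> fit.ClinicalTargets:
    """Targets whose ranges are the replicate envelope of a known genome.

    ``inflate`` scales each range symmetrically about its midpoint (floored
    at zero); at 1.0 the generating genome is bioplausible and scores
    fitness 0 against these targets when evaluated with matched seeds.
    """
    if cytokines is None:
        cytokines = tuple(c for c in CLINICAL_CYTOKINES if c in config.mediators)
    else:
        cytokines = tuple(cytokines)
    tp = np.asarray(time_points_hours, dtype=float)
    seeds = surrogate_seeds(seed, n_replicates)
    results = abm.run_replicates(
        injury, genome, seeds, config, horizon_hours=float(tp[-1])
    )
    if all(r.outcome == "died" and r.death_time_hours < tp[0] for r in results):
        raise ValueError("generating genome is non-viable: all replicates died early")
    sampled = np.stack([fit.sample_totals(r, cytokines, tp) for r in results])
    lo = sampled.min(axis=0)
    hi = sampled.max(axis=0)
    if inflate != 1.0:
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo) * inflate
        lo = np.maximum(mid - half, 0.0)
        hi = mid + half
    return fit.ClinicalTargets(
        cytokines=cytokines,
        time_points_hours=tp,
        range_min=lo,
        range_max=hi,
        mortality_rate=abm.mortality_rate(results),
        weights=np.ones(len(cytokines)),
        mortality_coefficient=mortality_coefficient,
        held_out_hours=tuple(held_out_hours),
    )


# ---------------------------------------------------------------------------
# reference calibrated genome
# ---------------------------------------------------------------------------

def reference_injury() -> abm.InjuryParams:
    """The reference burn scenario: sterile injury over half the surface."""
    return abm.InjuryParams.sterile_burn()


def base_matrix(config: abm.SimConfig = abm.DEFAULT_CONFIG) -> mrm.ModelRuleMatrix:
    """Hand-written, immunologically plausible starting rule matrix.

    Damage and infection drive innate pro-inflammatory output (TNFa, GCSF);
    TNFa is strongly autocrine (local amplification that, combined with
    TNFa-directed recruitment, lets inflammation ignite stochastically);
    TNFa induces IL-10, which suppresses the pro-inflammatory rules; the
    generic intermediates relay innate signals to the T-helper axis (IFNg
    vs IL-4).  Only defined for the default rule catalogue.
    """
    triples = [
        ("macrophage->TNFa", "TNFa", 1.5),
        ("macrophage->TNFa", "damage", 0.4),
        ("macrophage->TNFa", "infection", 1.5),
        ("macrophage->TNFa", "IL10", -0.3),
        ("macrophage->IL10", "TNFa", 0.3),
        ("macrophage->IL10", "damage", 0.2),
        ("macrophage->GCSF", "damage", 0.8),
        ("macrophage->GCSF", "TNFa", 0.3),
        ("macrophage->M1", "damage", 0.5),
        ("neutrophil->TNFa", "TNFa", 1.2),
        ("neutrophil->TNFa", "damage", 0.3),
        ("neutrophil->TNFa", "infection", 1.0),
        ("neutrophil->TNFa", "GCSF", 0.5),
        ("neutrophil->TNFa", "IL10", -0.25),
        ("neutrophil->M2", "TNFa", 0.4),
        ("TH0->M3", "M1", 0.6),
        ("TH0->M3", "TNFa", 0.3),
        ("TH1->IFNg", "M3", 0.7),
        ("TH1->IFNg", "TNFa", 0.3),
        ("TH1->IFNg", "IL4", -0.6),
        ("TH2->IL4", "M3", 0.5),
        ("TH2->IL4", "IL10", 0.3),
        ("TH2->IL10", "IL4", 0.6),
        ("TH2->IL10", "TNFa", 0.2),
    ]
    return mrm.build_matrix(triples, config.rule_labels, config.entity_labels)


def make_reference_calibrated_genome(
    config: abm.SimConfig = abm.DEFAULT_CONFIG,
    injury: abm.InjuryParams | None = None,
    seed: int = 20210519,
    n_replicates: int = 150,
    n_iterations: int = 7,
    scale_bounds: tuple[float, float] = (0.3, 1.33),
    target_mortality: float = 0.5,
    refine_replicates: int = 400,
    refine_span: float = 0.12,
) -> np.ndarray:
    """Deterministically calibrate the base matrix to ~50% mortality.

    Stage 1 bisects a global scale factor on the base matrix (more
    inflammation, more death) against the replicate mortality fraction;
    stage 2 re-estimates mortality at five scales spanning
    ``+-refine_span`` around the bisection result (``refine_replicates``
    replicates each), monotonizes the mortality-vs-scale curve and
    interpolates it locally to the target (the response is monotone but
    visibly convex, so a global linear fit would bias the solution).  The
    wide window absorbs bisection error from noisy late branch decisions.
    Fully reproducible from the seed.
    """
    if injury is None:
        injury = reference_injury()
    base = mrm.flatten(base_matrix(config))

    def mortality_at(scale: float, eval_seed: int, n: int) -> float:
        genome = mrm.clamp(base * scale)
        seeds = abm.replicate_seeds(eval_seed, n)
        return abm.mortality_rate(abm.run_replicates(injury, genome, seeds, config))

    lo, hi = scale_bounds
    best: tuple[float, float] | None = None  # (|mort - target|, scale)
    for it in range(n_iterations):
        mid = 0.5 * (lo + hi)
        mort = mortality_at(mid, seed + it, n_replicates)
        gap = abs(mort - target_mortality)
        if best is None or gap <= best[0]:
            best = (gap, mid)
        if mort > target_mortality:
            hi = mid
        else:
            lo = mid
    assert best is not None
    pick = best[1]
    if refine_replicates > 0:
        scales = np.clip(
            pick + refine_span * np.array([-1.0, -0.5, 0.0, 0.5, 1.0]),
            scale_bounds[0],
            scale_bounds[1],
        )
        morts = np.array(
            [
                mortality_at(float(s), seed + n_iterations + j, refine_replicates)
                for j, s in enumerate(scales)
            ]
        )
        morts_mono = np.maximum.accumulate(morts)
        if morts_mono[0] >= target_mortality:
            pick = float(scales[0])
        elif morts_mono[-1] <= target_mortality:
            pick = float(scales[-1])
        else:
            pick = float(np.interp(target_mortality, morts_mono, scales))
    return mrm.clamp(base * pick)


def load_reference_genome() -> np.ndarray:
    """The packaged calibrated reference genome (regenerable via
    :func:`make_reference_calibrated_genome` with defaults)."""
    text = (
        resources.files("mrmcal").joinpath("data", _REFERENCE_GENOME_RESOURCE).read_text()
    )
    obj = json.loads(text)
    return np.asarray(obj["genes"], dtype=float)
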