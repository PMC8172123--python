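"""Range-envelope fitness against heterogeneous clinical targets.

The clinical dataset is a sequence of per-cytokine [min, max] ranges at
discrete post-injury time points plus a cohort mortality rate.  A candidate
parameterization is scored by running stochastic replicates, collapsing them
into a min/max envelope at the clinical sampling times, and summing the
weighted absolute differences between the clinical and simulated range
maxima, plus a mortality-mismatch term:

    F = sum_{i,t} w_i |max(C^e_{i,t}) - max(C^m_{i,t})| + k |R_e - R_m|

Held-out time points contribute nothing to F.  A parameterization whose
envelope lies entirely inside the clinical ranges cannot be invalidated by
the data and is flagged bioplausible; one that dies before the first clinical
sampling time is non-viable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import abm

_ATOL = 1e-9


@dataclass(frozen=True)
class ClinicalTargets:
    """Per-cytokine, per-timepoint target ranges plus cohort metadata.

    ``range_min``/``range_max`` have shape (n_cytokines, n_time_points).
    ``weights`` multiplies each cytokine's contribution to the fitness;
    ``mortality_coefficient`` is k; ``held_out_hours`` lists sampling times
    excluded from fitness and bioplausibility evaluation.
    """

    cytokines: tuple[str, ...]
    time_points_hours: np.ndarray
    range_min: np.ndarray
    range_max: np.ndarray
    mortality_rate: float
    weights: np.ndarray
    mortality_coefficient: float = 10.0
    held_out_hours: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "cytokines", tuple(self.cytokines))
        tp = np.asarray(self.time_points_hours, dtype=float)
        lo = np.asarray(self.range_min, dtype=float)
        hi = np.asarray(self.range_max, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "time_points_hours", tp)
        object.__setattr__(self, "range_min", lo)
        object.__setattr__(self, "range_max", hi)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "held_out_hours", tuple(float(h) for h in self.held_out_hours))
        C, T = len(self.cytokines), tp.size
        if lo.shape != (C, T) or hi.shape != (C, T):
            raise ValueError("range arrays must have shape (n_cytokines, n_time_points)")
        if w.shape != (C,):
            raise ValueError("one weight per cytokine required")
        if np.any(np.diff(tp) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(lo > hi + _ATOL):
            raise ValueError("range_min exceeds range_max")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ValueError("mortality_rate outside [0, 1]")
        if self.mortality_coefficient < 0:
            raise ValueError("mortality_coefficient must be >= 0")
        for h in self.held_out_hours:
            if not np.isclose(tp, h).any():
                raise ValueError(f"held-out time {h} h is not a sampling time")

    # -- helpers ------------------------------------------------------------
    @property
    def n_time_points(self) -> int:
        return self.time_points_hours.size

    @property
    def evaluated_mask(self) -> np.ndarray:
        """Boolean mask over time points: True where fitness is evaluated."""
        mask = np.ones(self.n_time_points, dtype=bool)
        for h in self.held_out_hours:
            mask &= ~np.isclose(self.time_points_hours, h)
        return mask

    def clinical_max(self) -> np.ndarray:
        """Per-cytokine maximum of the range upper bound over all times."""
        return self.range_max.max(axis=1)

    def normalized(self) -> "ClinicalTargets":
        """Ranges divided per cytokine by the clinical maximum (zero maxima
        left untouched, with a warning)."""
        denom = self.clinical_max().copy()
        zero = denom <= 0
        if zero.any():
            warnings.warn(
                f"cytokines with zero clinical maximum left unscaled: "
                f"{[c for c, z in zip(self.cytokines, zero) if z]}"
            )
            denom[zero] = 1.0
        return replace(
            self,
            range_min=self.range_min / denom[:, None],
            range_max=self.range_max / denom[:, None],
        )

    # -- serialization ------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "cytokines": list(self.cytokines),
            "time_points_hours": self.time_points_hours.tolist(),
            "ranges": {
                c: [[float(lo), float(hi)] for lo, hi in zip(self.range_min[i], self.range_max[i])]
                for i, c in enumerate(self.cytokines)
            },
            "mortality_rate": float(self.mortality_rate),
            "weights": {c: float(w) for c, w in zip(self.cytokines, self.weights)},
            "mortality_coefficient": float(self.mortality_coefficient),
            "held_out_hours": list(self.held_out_hours),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ClinicalTargets":
        cytokines = tuple(obj["cytokines"])
        ranges = obj["ranges"]
        lo = np.array([[pair[0] for pair in ranges[c]] for c in cytokines])
        hi = np.array([[pair[1] for pair in ranges[c]] for c in cytokines])
        weights = obj.get("weights", {})
        w = np.array([float(weights.get(c, 1.0)) for c in cytokines])
        return cls(
            cytokines=cytokines,
            time_points_hours=np.asarray(obj["time_points_hours"], dtype=float),
            range_min=lo,
            range_max=hi,
            mortality_rate=float(obj["mortality_rate"]),
            weights=w,
            mortality_coefficient=float(obj.get("mortality_coefficient", 10.0)),
            held_out_hours=tuple(obj.get("held_out_hours", ())),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_json(), indent=1))
        else:
            rows = []
            for i, c in enumerate(self.cytokines):
                for j, t in enumerate(self.time_points_hours):
                    rows.append((c, t, self.range_min[i, j], self.range_max[i, j]))
            pd.DataFrame(rows, columns=["cytokine", "time_hours", "min", "max"]).to_csv(
                path, index=False
            )
            sidecar = self.to_json()
            del sidecar["ranges"], sidecar["time_points_hours"], sidecar["cytokines"]
            path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClinicalTargets":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_json(json.loads(path.read_text()))
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        cytokines = tuple(dict.fromkeys(frame["cytokine"]))
        tp = np.sort(frame["time_hours"].unique())
        lo = np.zeros((len(cytokines), tp.size))
        hi = np.zeros_like(lo)
        for i, c in enumerate(cytokines):
            sub = frame[frame["cytokine"] == c].sort_values("time_hours")
            lo[i] = sub["min"].to_numpy()
            hi[i] = sub["max"].to_numpy()
        weights = meta.get("weights", {})
        return cls(
            cytokines=cytokines,
            time_points_hours=tp,
            range_min=lo,
            range_max=hi,
            mortality_rate=float(meta["mortality_rate"]),
            weights=np.array([float(weights.get(c, 1.0)) for c in cytokines]),
            mortality_coefficient=float(meta.get("mortality_coefficient", 10.0)),
            held_out_hours=tuple(meta.get("held_out_hours", ())),
        )


@dataclass(frozen=True)
class RangeEnvelope:
    """Min/max of (normalized) model totals over replicates, per (cytokine,
    time point), plus the replicate mortality fraction R_m."""

    cytokines: tuple[str, ...]
    time_points_hours: np.ndarray
    env_min: np.ndarray
    env_max: np.ndarray
    mortality_rate: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("envelope needs at least one replicate")
        if np.any(self.env_min > self.env_max + _ATOL):
            raise ValueError("envelope min exceeds max")


# ---------------------------------------------------------------------------
# trajectory handling
# ---------------------------------------------------------------------------

def sample_totals(
    result: abm.SimulationResult,
    cytokines: Sequence[str],
    times_hours: np.ndarray,
) -> np.ndarray:
    """Raw lattice totals at the requested times, shape (C, T).

    Each clinical time maps to the nearest recorded step; a replicate that
    ended earlier (death/healing) contributes its last observed value,
    carried forward.
    """
    for c in cytokines:
        if c not in result.mediators:
            raise KeyError(f"cytokine {c!r} missing from trajectory")
    times_hours = np.asarray(times_hours, dtype=float)
    rec = result.times_hours
    idx = np.abs(rec[None, :] - times_hours[:, None]).argmin(axis=1)
    cols = [result.mediators.index(c) for c in cytokines]
    return result.totals[np.ix_(idx, cols)].T


def normalize(
    result: abm.SimulationResult, targets: ClinicalTargets
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each target cytokine's full series by its clinical maximum.

    Returns ``(times_hours, series)`` with ``series`` of shape
    (n_cytokines, n_recorded_steps).  A cytokine whose clinical maximum is
    zero is left unscaled (with a warning), so an all-zero series stays zero.
    """
    for c in targets.cytokines:
        if c not in result.mediators:
            raise KeyError(f"cytokine {c!r} missing from trajectory")
    cols = [result.mediators.index(c) for c in targets.cytokines]
    series = result.totals[:, cols].T.copy()
    denom = targets.clinical_max().copy()
    zero = denom <= 0
    if zero.any():
        warnings.warn(
            f"cytokines with zero clinical maximum left unscaled: "
            f"{[c for c, z in zip(targets.cytokines, zero) if z]}"
        )
        denom[zero] = 1.0
    return result.times_hours, series / denom[:, None]


def build_envelope(
    results: Sequence[abm.SimulationResult], targets: ClinicalTargets
) -> RangeEnvelope:
    """Per-(cytokine, time point) min/max of normalized totals over
    replicates; R_m = died / n."""
    if not results:
        raise ValueError("cannot build an envelope from zero replicates")
    denom = targets.clinical_max().copy()
    denom[denom <= 0] = 1.0
    sampled = np.stack(
        [
            sample_totals(r, targets.cytokines, targets.time_points_hours)
            for r in results
        ]
    ) / denom[None, :, None]
    return RangeEnvelope(
        cytokines=targets.cytokines,
        time_points_hours=targets.time_points_hours.copy(),
        env_min=sampled.min(axis=0),
        env_max=sampled.max(axis=0),
        mortality_rate=abm.mortality_rate(results),
        n_replicates=len(results),
    )


def _check_axes(env: RangeEnvelope, targets: ClinicalTargets) -> None:
    if env.cytokines != targets.cytokines:
        raise ValueError(
            f"cytokine axes differ: {env.cytokines} vs {targets.cytokines}"
        )
    if env.time_points_hours.size != targets.n_time_points or not np.allclose(
        env.time_points_hours, targets.time_points_hours
    ):
        raise ValueError("time-point axes differ")


def compute_fitness(
    env: RangeEnvelope,
    targets: ClinicalTargets,
    range_mode: str = "max",
) -> float:
    """The range-difference + mortality fitness (lower is better).

    ``range_mode="max"`` (default) sums weighted |target max - model max|
    over evaluated time points; ``"minmax"`` adds the symmetric min term.
    Values are compared on whatever scale the caller supplies: no
    re-normalization happens here.
    """
    _check_axes(env, targets)
    if range_mode not in ("max", "minmax"):
        raise ValueError(f"unknown range_mode {range_mode!r}")
    mask = targets.evaluated_mask
    diff = np.abs(targets.range_max[:, mask] - env.env_max[:, mask]).sum(axis=1)
    if range_mode == "minmax":
        diff = diff + np.abs(targets.range_min[:, mask] - env.env_min[:, mask]).sum(axis=1)
    F = float(targets.weights @ diff) + targets.mortality_coefficient * abs(
        targets.mortality_rate - env.mortality_rate
    )
    return F


def is_nonviable(
    results: Sequence[abm.SimulationResult],
    first_time_point_hours: float = 3.0,
    mode: str = "any",
) -> bool:
    """True when the parameterization dies before the first clinical sampling
    time: with ``mode="any"`` (default, strictest) one early death suffices;
    ``mode="all"`` requires every replicate to die early."""
    if mode not in ("any", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    early = [
        r.outcome == "died" and r.death_time_hours < first_time_point_hours
        for r in results
    ]
    return any(early) if mode == "any" else bool(early) and all(early)


def is_bioplausible(env: RangeEnvelope, targets: ClinicalTargets) -> bool:
    """True when the envelope lies inside the clinical ranges (boundary
    inclusive) at every cytokine and every evaluated time point — such a
    parameterization cannot be invalidated by the data."""
    _check_axes(env, targets)
    mask = targets.evaluated_mask
    inside_lo = env.env_min[:, mask] >= targets.range_min[:, mask] - _ATOL
    inside_hi = env.env_max[:, mask] <= targets.range_max[:, mask] + _ATOL
    return bool(inside_lo.all() and inside_hi.all())


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    """A genome with its evaluation results (fitness present iff evaluated;
    bioplausible implies viable)."""

    genome: np.ndarray
    fitness: float | None = None
    viable: bool | None = None
    bioplausible: bool | None = None
    envelope: RangeEnvelope | None = None

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None

    def copy(self) -> "Candidate":
        return Candidate(
            genome=self.genome.copy(),
            fitness=self.fitness,
            viable=self.viable,
            bioplausible=self.bioplausible,
            envelope=self.envelope,
        )


def evaluate_candidate(
    genome: np.ndarray,
    params: abm.InjuryParams,
    targets: ClinicalTargets,
    config: abm.SimConfig,
    seeds: Sequence[int],
    range_mode: str = "max",
    nonviable_mode: str = "any",
) -> Candidate:
    """Full evaluation pipeline: replicates -> normalized envelope -> fitness
    against the per-cytokine-normalized targets -> viability/bioplausibility
    flags."""
    horizon = max(float(targets.time_points_hours[-1]), 0.0)
    results = abm.run_replicates(params, genome, seeds, config, horizon_hours=horizon)
    env = build_envelope(results, targets)
    norm_targets = targets.normalized()
    F = compute_fitness(env, norm_targets, range_mode=range_mode)
    viable = not is_nonviable(
        results,
        first_time_point_hours=float(targets.time_points_hours[0]),
        mode=nonviable_mode,
    )
    plausible = viable and is_bioplausible(env, norm_targets)
    return Candidate(
        genome=np.asarray(genome, dtype=float),
        fitness=F,
        viable=viable,
        bioplausible=plausible,
        envelope=env,
    )
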