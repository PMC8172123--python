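"""Configuration loading, run outputs and the run manifest.

Ensemble archives are written as JSON Lines (streamable, append-only, one
genome with metadata per line); traces go to CSV; genomes round-trip at full
float precision.  Every run directory carries a manifest with SHA-256
checksums of its outputs and of the input files it was produced from.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abm, fitness as fit, ga

_SIM_KEYS = {f.name for f in dataclasses.fields(abm.SimConfig)}
_GA_KEYS = {f.name for f in dataclasses.fields(ga.GAConfig)}
_INJURY_KEYS = {f.name for f in dataclasses.fields(abm.InjuryParams)}


def _read_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        obj = yaml.safe_load(text)
    else:
        obj = json.loads(text)
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return obj


def _build(cls, obj: dict, allowed: set[str], what: str):
    unknown = set(obj) - allowed
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    converted = {
        k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(v, list)
        else v
        for k, v in obj.items()
    }
    return cls(**converted)


def load_sim_config(path: str | Path) -> abm.SimConfig:
    """Schema-validated simulator configuration; unknown keys are rejected
    and omitted keys take their documented defaults."""
    return _build(abm.SimConfig, _read_structured(Path(path)), _SIM_KEYS, "simulator config")


def load_ga_config(path: str | Path) -> ga.GAConfig:
    return _build(ga.GAConfig, _read_structured(Path(path)), _GA_KEYS, "GA config")


def load_injury(path: str | Path) -> abm.InjuryParams:
    return _build(abm.InjuryParams, _read_structured(Path(path)), _INJURY_KEYS, "injury")


def load_targets(path: str | Path) -> fit.ClinicalTargets:
    return fit.ClinicalTargets.load(path)


def load_config(path: str | Path, kind: str):
    """Dispatching loader: ``kind`` in {"sim", "ga", "injury", "targets"}."""
    loaders = {
        "sim": load_sim_config,
        "ga": load_ga_config,
        "injury": load_injury,
        "targets": load_targets,
    }
    if kind not in loaders:
        raise ValueError(f"unknown config kind {kind!r}")
    return loaders[kind](path)


def _plain(value):
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    return value


def save_config(config, path: str | Path) -> None:
    """Write a SimConfig / GAConfig / InjuryParams back to YAML or JSON."""
    obj = {k: _plain(v) for k, v in dataclasses.asdict(config).items()}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=1))


# ---------------------------------------------------------------------------
# run outputs
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    root_seed: int
    code_version: str
    created_unix: float
    files: dict[str, str]          # output file name -> sha256
    inputs: dict[str, str]         # input path -> sha256

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_outputs(
    state: ga.GAState,
    outdir: str | Path,
    input_paths: dict[str, str | Path] | None = None,
) -> RunManifest:
    """Write ensemble.jsonl, fitness_trace.csv, diversity.csv,
    best_genome.json and manifest.json into ``outdir``."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ensemble_path = outdir / "ensemble.jsonl"
    with ensemble_path.open("w") as fh:
        for member in state.archive:
            fh.write(
                json.dumps(
                    {
                        "genome": [float(g) for g in member.genome],
                        "fitness": float(member.fitness),
                        "generation": int(member.generation),
                        "mortality_rate": float(member.mortality_rate),
                    }
                )
                + "\n"
            )

    pd.DataFrame(
        {
            "generation": np.arange(len(state.best_fitness_trace)),
            "best_fitness": state.best_fitness_trace,
            "mean_fitness": state.mean_fitness_trace,
        }
    ).to_csv(outdir / "fitness_trace.csv", index=False)

    pd.DataFrame(
        {
            "generation": [d.generation for d in state.diversity_trace],
            "total_diversity": [d.total for d in state.diversity_trace],
        }
    ).to_csv(outdir / "diversity.csv", index=False)

    best = state.best
    (outdir / "best_genome.json").write_text(
        json.dumps(
            {"genes": [float(g) for g in best.genome], "fitness": float(best.fitness)}
        )
    )

    names = ["ensemble.jsonl", "fitness_trace.csv", "diversity.csv", "best_genome.json"]
    manifest = RunManifest(
        root_seed=int(state.config.root_seed),
        code_version=__version__,
        created_unix=time.time(),
        files={n: sha256_file(outdir / n) for n in names},
        inputs={
            str(k): sha256_file(v) for k, v in (input_paths or {}).items()
        },
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_json(), indent=1))
    return manifest


def read_ensemble(path: str | Path) -> list[ga.EnsembleMember]:
    """Read ensemble.jsonl back; genomes are restored exactly."""
    members = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        members.append(
            ga.EnsembleMember(
                genome=np.asarray(obj["genome"], dtype=float),
                fitness=float(obj["fitness"]),
                generation=int(obj["generation"]),
                mortality_rate=float(obj["mortality_rate"]),
            )
        )
    return members
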