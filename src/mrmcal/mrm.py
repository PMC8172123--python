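"""Model Rule Matrix (MRM): the evolvable rule-coefficient matrix.

Rows are rules, columns are the model entities that may contribute to each
rule's decision; element (r, j) is the coefficient with which entity j enters
rule r, and 0 means "no connection".  The matrix flattens row-major into a
one-dimensional genome on which the genetic algorithm operates.  Every
coefficient is a dimensionless value in the closed interval [-2, 2].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENE_MIN: float = -2.0
GENE_MAX: float = 2.0

#: Reference matrix shape: 18 rules x 24 entities = 432 free parameters.
REFERENCE_N_RULES: int = 18
REFERENCE_N_ENTITIES: int = 24


def default_labels(n_rules: int, n_entities: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Generic placeholder labels for a matrix of the given shape."""
    rules = tuple(f"rule_{i:02d}" for i in range(n_rules))
    entities = tuple(f"entity_{j:02d}" for j in range(n_entities))
    return rules, entities


def reference_labels() -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Labels for the reference 18 x 24 (432-parameter) configuration."""
    return default_labels(REFERENCE_N_RULES, REFERENCE_N_ENTITIES)


@dataclass(frozen=True)
class ModelRuleMatrix:
    """A validated rule-coefficient matrix.

    Parameters
    ----------
    values
        Real matrix of shape (n_rules, n_entities); elements in [-2, 2].
    rule_labels
        One name per row, unique.
    entity_labels
        One name per column, unique.
    """

    values: np.ndarray
    rule_labels: tuple[str, ...]
    entity_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "rule_labels", tuple(self.rule_labels))
        object.__setattr__(self, "entity_labels", tuple(self.entity_labels))
        n_rules, n_entities = values.shape
        if len(self.rule_labels) != n_rules:
            raise ValueError(
                f"{len(self.rule_labels)} rule labels for {n_rules} rows"
            )
        if len(self.entity_labels) != n_entities:
            raise ValueError(
                f"{len(self.entity_labels)} entity labels for {n_entities} columns"
            )
        for labels, what in ((self.rule_labels, "rule"), (self.entity_labels, "entity")):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {what} labels")
        bad = np.argwhere((values < GENE_MIN) | (values > GENE_MAX) | ~np.isfinite(values))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"element ({self.rule_labels[r]!r}, {self.entity_labels[c]!r}) = "
                f"{values[r, c]} outside [{GENE_MIN}, {GENE_MAX}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rules(self) -> int:
        return self.values.shape[0]

    @property
    def n_entities(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelRuleMatrix):
            return NotImplemented
        return (
            self.rule_labels == other.rule_labels
            and self.entity_labels == other.entity_labels
            and np.array_equal(self.values, other.values)
        )


def build_matrix(
    coefficients: Iterable[tuple[str, str, float]],
    rule_labels: Sequence[str],
    entity_labels: Sequence[str],
) -> ModelRuleMatrix:
    """Assemble a matrix from (rule, entity, value) triples.

    Cells not named by any triple are 0 ("no connection").  Out-of-bounds
    values and duplicate triples are rejected.
    """
    rule_labels = tuple(rule_labels)
    entity_labels = tuple(entity_labels)
    r_index = {name: i for i, name in enumerate(rule_labels)}
    e_index = {name: j for j, name in enumerate(entity_labels)}
    values = np.zeros((len(rule_labels), len(entity_labels)))
    seen: set[tuple[str, str]] = set()
    for rule, entity, value in coefficients:
        if rule not in r_index:
            raise ValueError(f"unknown rule label {rule!r}")
        if entity not in e_index:
            raise ValueError(f"unknown entity label {entity!r}")
        if (rule, entity) in seen:
            raise ValueError(f"duplicate triple for cell ({rule!r}, {entity!r})")
        seen.add((rule, entity))
        if not (GENE_MIN <= value <= GENE_MAX):
            raise ValueError(
                f"value {value} for cell ({rule!r}, {entity!r}) outside "
                f"[{GENE_MIN}, {GENE_MAX}]"
            )
        values[r_index[rule], e_index[entity]] = value
    return ModelRuleMatrix(values, rule_labels, entity_labels)


def flatten(m: ModelRuleMatrix) -> np.ndarray:
    """Row-major flattening of the matrix into a genome vector."""
    return m.values.reshape(-1).copy()


def unflatten(
    genes: np.ndarray,
    n_rules: int | None = None,
    n_entities: int | None = None,
    rule_labels: Sequence[str] | None = None,
    entity_labels: Sequence[str] | None = None,
) -> ModelRuleMatrix:
    """Inverse of :func:`flatten`.

    The shape may be given either explicitly or through the label lists;
    omitting both falls back to the reference 18 x 24 configuration.
    """
    genes = validate_genome(genes)
    if rule_labels is not None and n_rules is None:
        n_rules = len(rule_labels)
    if entity_labels is not None and n_entities is None:
        n_entities = len(entity_labels)
    if n_rules is None and n_entities is None:
        n_rules, n_entities = REFERENCE_N_RULES, REFERENCE_N_ENTITIES
    if n_rules is None or n_entities is None:
        raise ValueError("both dimensions (or both label lists) are required")
    if genes.size != n_rules * n_entities:
        raise ValueError(
            f"genome length {genes.size} != {n_rules} x {n_entities}"
        )
    if rule_labels is None:
        rule_labels = default_labels(n_rules, n_entities)[0]
    if entity_labels is None:
        entity_labels = default_labels(n_rules, n_entities)[1]
    return ModelRuleMatrix(
        genes.reshape(n_rules, n_entities), tuple(rule_labels), tuple(entity_labels)
    )


def clamp(genes: np.ndarray) -> np.ndarray:
    """Clip every gene into [-2, 2]; idempotent."""
    return np.clip(np.asarray(genes, dtype=float), GENE_MIN, GENE_MAX)


def validate_genome(genes: np.ndarray) -> np.ndarray:
    """Return the genome as a float vector, rejecting out-of-bounds genes."""
    genes = np.asarray(genes, dtype=float)
    if genes.ndim != 1:
        raise ValueError(f"genome must be 1-D, got ndim={genes.ndim}")
    if genes.size and (not np.isfinite(genes).all() or genes.min() < GENE_MIN or genes.max() > GENE_MAX):
        raise ValueError(f"genes outside [{GENE_MIN}, {GENE_MAX}]")
    return genes


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def matrix_to_json(m: ModelRuleMatrix) -> dict:
    return {
        "rule_labels": list(m.rule_labels),
        "entity_labels": list(m.entity_labels),
        "values": m.values.tolist(),
    }


def matrix_from_json(obj: dict) -> ModelRuleMatrix:
    return ModelRuleMatrix(
        np.asarray(obj["values"], dtype=float),
        tuple(obj["rule_labels"]),
        tuple(obj["entity_labels"]),
    )


def save_matrix(m: ModelRuleMatrix, path: str | Path) -> None:
    """Write a matrix as JSON (``.json``) or labelled CSV (anything else)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(matrix_to_json(m), indent=1))
    else:
        frame = pd.DataFrame(
            m.values, index=list(m.rule_labels), columns=list(m.entity_labels)
        )
        frame.to_csv(path)


def load_matrix(path: str | Path) -> ModelRuleMatrix:
    path = Path(path)
    if path.suffix == ".json":
        return matrix_from_json(json.loads(path.read_text()))
    frame = pd.read_csv(path, index_col=0)
    return ModelRuleMatrix(
        frame.to_numpy(dtype=float),
        tuple(str(r) for r in frame.index),
        tuple(str(c) for c in frame.columns),
    )


def save_genome(genes: np.ndarray, path: str | Path) -> None:
    """Flat JSON array; full float precision survives the round trip."""
    Path(path).write_text(json.dumps(list(map(float, np.asarray(genes, dtype=float)))))


def load_genome(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text()), dtype=float)
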