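"""Encode a patient's lab panel as a matrix of relation vectors.

Following the translational idea l_h + l_r ≈ l_t, the relation between an
indicator and the value measured for a patient is represented by the
embedding difference

    e_r = e_value − e_indicator

(e.g. e_{7.1mmol/L} − e_{fasting blood glucose}).  Stacking the relation
vector of every indicator in a declared order yields the k × m relation
matrix that the downstream attention/CNN classifier consumes, where k is
the embedding dimension and m the number of indicators.

A continuous measurement is matched to the discrete value-entity grid by
nearest value (round-half-up at exact midpoints); measurements beyond the
grid collapse to the <HIGHEST>/<LOWEST> sentinels and missing cells to
<UNK>.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embed import TransParams
from .kg import HIGHEST, LOWEST, UNK, EntityCatalog

__all__ = [
    "PatientRecord",
    "RelationMatrix",
    "match_entity",
    "relation_vector",
    "encode",
    "encode_dataset",
    "encode_learned",
    "read_patients",
]


@dataclass
class PatientRecord:
    """One patient's measured values (indicator -> value, None = missing)
    and an optional binary disease label (1 = diseased)."""

    values: dict[str, float | None]
    label: int | None = None


@dataclass
class RelationMatrix:
    """k x m matrix whose column j is e_value(j) − e_indicator(j)."""

    matrix: np.ndarray
    column_order: list[str]


def match_entity(
    indicator: str, value: float | None, catalog: EntityCatalog
) -> int:
    """Map a measurement to its value entity id.

    Missing -> <UNK>; above the indicator's grid maximum -> <HIGHEST>;
    below its minimum -> <LOWEST>; otherwise the nearest grid value, with
    ties at exact midpoints resolved upward (round-half-up).
    """
    if indicator not in catalog.value_entities:
        raise KeyError(f"unknown indicator {indicator!r}")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return catalog.special_id(UNK)
    grid = catalog.value_entities[indicator]
    values = np.array([v for v, _ in grid])
    if value > values[-1]:
        return catalog.special_id(HIGHEST)
    if value < values[0]:
        return catalog.special_id(LOWEST)
    pos = int(np.searchsorted(values, value))
    if pos == 0:
        best = 0
    else:
        below, above = values[pos - 1], values[pos] if pos < len(values) else values[-1]
        # round-half-up: midpoint goes to the larger grid value
        best = pos - 1 if value - below < above - value else min(pos, len(values) - 1)
    return catalog.entity_to_int[grid[best][1]]


def relation_vector(e_v: np.ndarray, e_c: np.ndarray) -> np.ndarray:
    """Relation vector e_r = e_v − e_c (value minus indicator embedding)."""
    if e_v.shape != e_c.shape:
        raise ValueError(f"shape mismatch: {e_v.shape} vs {e_c.shape}")
    return e_v - e_c


def encode(
    record: PatientRecord,
    catalog: EntityCatalog,
    params: TransParams,
    order: list[str],
) -> RelationMatrix:
    """Relation matrix of one patient: columns follow ``order``."""
    if len(set(order)) != len(order):
        raise ValueError("duplicate indicators in order")
    unknown = [o for o in order if o not in catalog.value_entities]
    if unknown:
        raise KeyError(f"indicators not in catalog: {unknown}")
    E = params.entity_vectors
    cols = []
    for ind in order:
        vid = match_entity(ind, record.values.get(ind), catalog)
        cid = catalog.entity_to_int[ind]
        cols.append(relation_vector(E[vid], E[cid]))
    return RelationMatrix(matrix=np.stack(cols, axis=1), column_order=list(order))


def encode_dataset(
    records: list[PatientRecord],
    catalog: EntityCatalog,
    params: TransParams,
    order: list[str],
) -> np.ndarray:
    """Stack per-patient relation matrices into an (n, k, m) tensor."""
    return np.stack([encode(r, catalog, params, order).matrix for r in records])


def matched_entity_ids(
    records: list[PatientRecord], catalog: EntityCatalog, order: list[str]
) -> np.ndarray:
    """(n, m) integer matrix of matched value-entity ids, for the
    learned-embedding ablation."""
    return np.array(
        [[match_entity(ind, r.values.get(ind), catalog) for ind in order] for r in records]
    )


def encode_learned(
    record: PatientRecord,
    catalog: EntityCatalog,
    embedding_table: np.ndarray,
    order: list[str],
) -> RelationMatrix:
    """Ablation encoder without graph knowledge.

    Column j is simply row ``entity_id`` of ``embedding_table`` for the
    matched value entity — equivalent to one-hot encoding the entity and
    multiplying by the table.  Same downstream interface as :func:`encode`;
    the table is meant to be trained jointly with the classifier.
    """
    if len(set(order)) != len(order):
        raise ValueError("duplicate indicators in order")
    cols = []
    for ind in order:
        vid = match_entity(ind, record.values.get(ind), catalog)
        cols.append(embedding_table[vid])
    return RelationMatrix(matrix=np.stack(cols, axis=1), column_order=list(order))


def read_patients(path: str, indicators: list[str] | None = None) -> list[PatientRecord]:
    """Read patients.csv: one row per patient, one column per indicator,
    empty cell = missing, optional 'label' column."""
    df = pd.read_csv(path)
    has_label = "label" in df.columns
    cols = indicators if indicators is not None else [c for c in df.columns if c != "label"]
    records = []
    for _, row in df.iterrows():
        vals = {
            c: (None if pd.isna(row[c]) else float(row[c])) for c in cols
        }
        label = int(row["label"]) if has_label and pd.notna(row["label"]) else None
        records.append(PatientRecord(values=vals, label=label))
    return records
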