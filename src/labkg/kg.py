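"""Severity-band knowledge graph of indicator–value relations.

Clinical laboratories publish a *reference range* for each analyte: the
interval a healthy measurement is expected to fall in (e.g. triglycerides
0.45–1.81 mmol/L).  This module discretizes each indicator's plausible
measurement axis into a grid of value entities and connects the indicator
entity to every grid value through one of seven ordered severity relations
(severely low, generally low, slightly low, normal, slightly high,
generally high, severely high), producing facts such as

    (triglycerides, normal, "0.45mmol/L")

which form the training data for the translational embedding models in
:mod:`labkg.embed`.

The non-normal band boundaries are parametric: with ``W = high - low``,
``alpha1`` and ``alpha2`` are the fractions of ``W`` that delimit the
slight / general / severe deviations on either side of the range.  The
normal interval is closed on both ends; the outer bands are half-open so
every value belongs to exactly one band.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "BANDS",
    "BandParams",
    "ReferenceRange",
    "EntityCatalog",
    "KnowledgeTriple",
    "UNK",
    "HIGHEST",
    "LOWEST",
    "band_of",
    "value_grid",
    "build_graph",
    "write_graph",
    "read_graph",
    "read_ranges",
    "write_ranges",
]

#: The seven severity relations, ordered from lowest to highest.
BANDS = (
    "severely_low",
    "generally_low",
    "slightly_low",
    "normal",
    "slightly_high",
    "generally_high",
    "severely_high",
)

UNK = "<UNK>"
HIGHEST = "<HIGHEST>"
LOWEST = "<LOWEST>"
SPECIALS = (UNK, HIGHEST, LOWEST)


class GraphFormatError(ValueError):
    """Raised when a serialized graph file violates the format contract."""


@dataclass(frozen=True)
class BandParams:
    """Fractions of the range width delimiting the deviation bands.

    ``alpha1`` ends the *slight* deviation and ``alpha2`` the *general*
    one; beyond ``alpha2`` range-widths a value is *severe*.
    """

    alpha1: float = 0.25
    alpha2: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < self.alpha2):
            raise ValueError(
                f"require 0 < alpha1 < alpha2, got alpha1={self.alpha1}, alpha2={self.alpha2}"
            )


@dataclass(frozen=True)
class ReferenceRange:
    """One indicator's normal interval plus its value-grid policy.

    ``grid_step`` is the spacing of the discretized measurement axis;
    ``span_factor`` is how many range-widths the grid extends beyond
    ``[low, high]`` on each side.  ``nonnegative`` clamps the grid at zero,
    appropriate for concentration-like analytes.
    """

    indicator: str
    low: float
    high: float
    units: str = ""
    grid_step: float | None = None
    span_factor: float = 1.0
    nonnegative: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"{self.indicator}: non-finite bounds")
        if self.low >= self.high:
            raise ValueError(
                f"{self.indicator}: low ({self.low}) must be < high ({self.high})"
            )
        if self.grid_step is not None and self.grid_step <= 0:
            raise ValueError(f"{self.indicator}: grid_step must be positive")
        if self.span_factor <= 0:
            raise ValueError(f"{self.indicator}: span_factor must be positive")

    @property
    def width(self) -> float:
        return self.high - self.low

    def step(self) -> float:
        """Effective grid step: explicit, or width/100 rounded to the
        decimal precision the bounds are printed at."""
        if self.grid_step is not None:
            return self.grid_step
        raw = self.width / 100.0
        # Keep one decimal more than the bounds' printed precision, floor 1e-6.
        decimals = max(_decimals(self.low), _decimals(self.high)) + 1
        step = round(raw, decimals)
        return step if step > 0 else raw


def _decimals(x: float) -> int:
    s = f"{x:g}"
    return len(s.split(".")[1]) if "." in s else 0


def band_of(value: float, rng: ReferenceRange, bands: BandParams = BandParams()) -> str:
    """Locate ``value`` in one of the seven severity bands of ``rng``.

    ``[low, high]`` is normal (both endpoints included); outside it, the
    band is decided by how many ``alpha``-fractions of the range width the
    value deviates.  Total and monotone in ``value``.
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r}")
    w = rng.width
    a1, a2 = bands.alpha1 * w, bands.alpha2 * w
    if value < rng.low - a2:
        return "severely_low"
    if value < rng.low - a1:
        return "generally_low"
    if value < rng.low:
        return "slightly_low"
    if value <= rng.high:
        return "normal"
    if value <= rng.high + a1:
        return "slightly_high"
    if value <= rng.high + a2:
        return "generally_high"
    return "severely_high"


def value_entity_id(rng: ReferenceRange, value: float) -> str:
    """Entity id of a grid value, namespaced by indicator to avoid
    collisions between indicators sharing units."""
    return f"{rng.indicator}:{value:g}{rng.units}"


def value_grid(rng: ReferenceRange) -> list[tuple[float, str]]:
    """Discretize the indicator's measurement axis.

    Values run from ``low - span_factor*W`` (clamped at 0 for nonnegative
    analytes) to ``high + span_factor*W`` in steps of ``grid_step``,
    rounded to the step's decimal precision; strictly increasing, no
    duplicates.
    """
    step = rng.step()
    decimals = max(_decimals(step), 0)
    lo = rng.low - rng.span_factor * rng.width
    if rng.nonnegative and lo < 0.0:
        lo = 0.0
    hi = rng.high + rng.span_factor * rng.width
    values: list[float] = []
    k = 0
    while True:
        v = round(lo + k * step, decimals)
        if v > hi + 1e-12:
            break
        if not values or v > values[-1]:
            values.append(v + 0.0)  # normalize -0.0
        k += 1
    return [(v, value_entity_id(rng, v)) for v in values]


@dataclass
class EntityCatalog:
    """Id maps for the graph: indicator entities, per-indicator value
    entities, the three special entities, and the seven relations."""

    indicator_entities: list[str]
    value_entities: dict[str, list[tuple[float, str]]]
    entity_to_int: dict[str, int] = field(default_factory=dict)
    relation_to_int: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entity_to_int:
            ids = list(self.indicator_entities)
            for ind in self.indicator_entities:
                ids.extend(eid for _, eid in self.value_entities[ind])
            ids.extend(SPECIALS)
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate entity ids")
            self.entity_to_int = {e: i for i, e in enumerate(ids)}
        if not self.relation_to_int:
            self.relation_to_int = {b: i for i, b in enumerate(BANDS)}
        if len(self.relation_to_int) != 7:
            raise ValueError("catalog must register exactly 7 relations")

    # -- convenience lookups -------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self.entity_to_int)

    @property
    def int_to_entity(self) -> dict[int, str]:
        return {i: e for e, i in self.entity_to_int.items()}

    def indicator_ids(self) -> list[int]:
        return [self.entity_to_int[e] for e in self.indicator_entities]

    def value_ids(self) -> list[int]:
        out: list[int] = []
        for ind in self.indicator_entities:
            out.extend(self.entity_to_int[eid] for _, eid in self.value_entities[ind])
        return out

    def special_id(self, name: str) -> int:
        if name not in SPECIALS:
            raise KeyError(name)
        return self.entity_to_int[name]


@dataclass(frozen=True)
class KnowledgeTriple:
    """A (head indicator, severity relation, tail value) fact, as ints."""

    head: int
    relation: int
    tail: int


def build_graph(
    ranges: list[ReferenceRange], bands: BandParams = BandParams()
) -> tuple[EntityCatalog, list[KnowledgeTriple]]:
    """Build the full severity-band graph: one triple per (indicator, grid
    value) pair, with the relation given by :func:`band_of`."""
    if not ranges:
        raise ValueError("need at least one reference range")
    names = [r.indicator for r in ranges]
    if len(set(names)) != len(names):
        raise ValueError("duplicate indicator names")
    grids = {r.indicator: value_grid(r) for r in ranges}
    catalog = EntityCatalog(indicator_entities=names, value_entities=grids)
    triples = [
        KnowledgeTriple(
            head=catalog.entity_to_int[r.indicator],
            relation=catalog.relation_to_int[band_of(v, r, bands)],
            tail=catalog.entity_to_int[eid],
        )
        for r in ranges
        for v, eid in grids[r.indicator]
    ]
    return catalog, triples


# ---------------------------------------------------------------------------
# Plain-text serialization (entity2id.tsv / relation2id.tsv / triples.tsv)
# ---------------------------------------------------------------------------

_VALUE_MARK = "\t"  # column separator in all three files


def write_graph(catalog: EntityCatalog, triples: list[KnowledgeTriple], outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "entity2id.tsv"), "w", encoding="utf-8", newline="\n") as f:
        for e, i in catalog.entity_to_int.items():
            f.write(f"{e}\t{i}\n")
    with open(os.path.join(outdir, "relation2id.tsv"), "w", encoding="utf-8", newline="\n") as f:
        for r, i in catalog.relation_to_int.items():
            f.write(f"{r}\t{i}\n")
    with open(os.path.join(outdir, "triples.tsv"), "w", encoding="utf-8", newline="\n") as f:
        for t in triples:
            f.write(f"{t.head}\t{t.relation}\t{t.tail}\n")
    # Sidecar with catalog structure so read_graph can rebuild it exactly.
    with open(os.path.join(outdir, "catalog.tsv"), "w", encoding="utf-8", newline="\n") as f:
        for ind in catalog.indicator_entities:
            f.write(f"I\t{ind}\n")
            for v, eid in catalog.value_entities[ind]:
                f.write(f"V\t{ind}\t{v:g}\t{eid}\n")


def read_graph(indir: str) -> tuple[EntityCatalog, list[KnowledgeTriple]]:
    """Read the TSV files written by :func:`write_graph`; inverse of it."""
    entity_to_int: dict[str, int] = {}
    with open(os.path.join(indir, "entity2id.tsv"), encoding="utf-8") as f:
        for ln, line in enumerate(f, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise GraphFormatError(f"entity2id.tsv line {ln}: expected 2 fields")
            entity_to_int[parts[0]] = int(parts[1])
    relation_to_int: dict[str, int] = {}
    with open(os.path.join(indir, "relation2id.tsv"), encoding="utf-8") as f:
        for ln, line in enumerate(f, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise GraphFormatError(f"relation2id.tsv line {ln}: expected 2 fields")
            relation_to_int[parts[0]] = int(parts[1])
    indicator_entities: list[str] = []
    value_entities: dict[str, list[tuple[float, str]]] = {}
    with open(os.path.join(indir, "catalog.tsv"), encoding="utf-8") as f:
        for ln, line in enumerate(f, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "I" and len(parts) == 2:
                indicator_entities.append(parts[1])
                value_entities[parts[1]] = []
            elif parts[0] == "V" and len(parts) == 4:
                value_entities[parts[1]].append((float(parts[2]), parts[3]))
            else:
                raise GraphFormatError(f"catalog.tsv line {ln}: malformed record")
    catalog = EntityCatalog(
        indicator_entities=indicator_entities,
        value_entities=value_entities,
        entity_to_int=entity_to_int,
        relation_to_int=relation_to_int,
    )
    triples: list[KnowledgeTriple] = []
    n_rel = len(relation_to_int)
    with open(os.path.join(indir, "triples.tsv"), encoding="utf-8") as f:
        for ln, line in enumerate(f, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise GraphFormatError(f"triples.tsv line {ln}: expected 3 fields")
            h, r, t = (int(p) for p in parts)
            if r >= n_rel or r < 0:
                raise GraphFormatError(f"triples.tsv line {ln}: relation id {r} out of range")
            if h >= len(entity_to_int) or t >= len(entity_to_int):
                raise GraphFormatError(f"triples.tsv line {ln}: entity id out of range")
            triples.append(KnowledgeTriple(h, r, t))
    return catalog, triples


# ---------------------------------------------------------------------------
# ranges.csv
# ---------------------------------------------------------------------------

def read_ranges(path: str) -> list[ReferenceRange]:
    """Read a ranges.csv with header indicator,low,high,units[,grid_step,span_factor]."""
    df = pd.read_csv(path)
    required = {"indicator", "low", "high", "units"}
    missing = required - set(df.columns)
    if missing:
        raise GraphFormatError(f"ranges file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        step = row.get("grid_step")
        span = row.get("span_factor")
        out.append(
            ReferenceRange(
                indicator=str(row["indicator"]),
                low=float(row["low"]),
                high=float(row["high"]),
                units=str(row["units"]) if pd.notna(row["units"]) else "",
                grid_step=float(step) if step is not None and pd.notna(step) else None,
                span_factor=float(span) if span is not None and pd.notna(span) else 1.0,
            )
        )
    return out


def write_ranges(ranges: list[ReferenceRange], path: str) -> None:
    pd.DataFrame(
        {
            "indicator": [r.indicator for r in ranges],
            "low": [r.low for r in ranges],
            "high": [r.high for r in ranges],
            "units": [r.units for r in ranges],
            "grid_step": [r.grid_step for r in ranges],
            "span_factor": [r.span_factor for r in ranges],
        }
    ).to_csv(path, index=False)
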