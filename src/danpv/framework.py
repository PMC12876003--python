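"""Evaluation framework: dimensions, criteria and the block partition.

Every downstream stage (DEMATEL matrices, DANP supermatrices, VIKOR
tables) indexes the criteria space in *framework order*: criteria are
listed dimension-major, so each dimension owns a contiguous block of
indices.  The :class:`CriteriaFramework` records that partition once and
all matrix block arithmetic derives from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Dimension",
    "Criterion",
    "CriteriaFramework",
    "FrameworkError",
    "DuplicateCodeError",
    "OrphanCriterionError",
    "EmptyDimensionError",
    "load_framework",
    "write_framework",
    "case_framework",
    "make_framework",
]


class FrameworkError(ValueError):
    """Base class for framework validation failures."""


class DuplicateCodeError(FrameworkError):
    """A dimension or criterion code occurs more than once."""


class OrphanCriterionError(FrameworkError):
    """A criterion references a dimension that does not exist."""


class EmptyDimensionError(FrameworkError):
    """A dimension has no criteria."""


@dataclass(frozen=True)
class Dimension:
    """One evaluation dimension (e.g. ``D5`` "Daily tasks")."""

    code: str
    name: str
    order: int


@dataclass(frozen=True)
class Criterion:
    """One evaluation criterion, owned by exactly one dimension."""

    code: str
    name: str
    dimension_code: str
    description: str = ""


@dataclass(frozen=True)
class CriteriaFramework:
    """Ordered dimensions and criteria with the dimension-major block map.

    ``blocks`` maps each dimension code to a ``range`` of row/column
    indices over the criteria ordering; the ranges partition ``0..n``.
    """

    dimensions: tuple[Dimension, ...]
    criteria: tuple[Criterion, ...]
    blocks: Mapping[str, range] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = tuple(self.dimensions)
        crits = _sorted_dimension_major(dims, tuple(self.criteria))
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(self, "criteria", crits)
        _validate(dims, crits)
        object.__setattr__(self, "blocks", _compute_blocks(dims, crits))

    # -- convenience accessors -------------------------------------------------

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def criterion_codes(self) -> list[str]:
        return [c.code for c in self.criteria]

    @property
    def dimension_codes(self) -> list[str]:
        return [d.code for d in self.dimensions]

    def criteria_of(self, dimension_code: str) -> list[Criterion]:
        block = self.blocks[dimension_code]
        return [self.criteria[i] for i in block]

    def dimension_of(self, criterion_code: str) -> str:
        for c in self.criteria:
            if c.code == criterion_code:
                return c.dimension_code
        raise KeyError(criterion_code)

    def criterion_index(self, code: str) -> int:
        return self.criterion_codes.index(code)


def _sorted_dimension_major(
    dims: tuple[Dimension, ...], crits: tuple[Criterion, ...]
) -> tuple[Criterion, ...]:
    dim_pos = {d.code: i for i, d in enumerate(dims)}
    # stable: preserves within-dimension input order
    return tuple(
        sorted(crits, key=lambda c: dim_pos.get(c.dimension_code, len(dim_pos)))
    )


def _validate(dims: tuple[Dimension, ...], crits: tuple[Criterion, ...]) -> None:
    dim_codes = [d.code for d in dims]
    if len(set(dim_codes)) != len(dim_codes):
        raise DuplicateCodeError(f"duplicate dimension codes in {dim_codes}")
    crit_codes = [c.code for c in crits]
    if len(set(crit_codes)) != len(crit_codes):
        dupes = sorted({c for c in crit_codes if crit_codes.count(c) > 1})
        raise DuplicateCodeError(f"duplicate criterion codes: {dupes}")
    if set(crit_codes) & set(dim_codes):
        raise DuplicateCodeError("criterion code collides with a dimension code")
    known = set(dim_codes)
    for c in crits:
        if c.dimension_code not in known:
            raise OrphanCriterionError(
                f"criterion {c.code!r} references missing dimension "
                f"{c.dimension_code!r}"
            )
    populated = {c.dimension_code for c in crits}
    empty = [d for d in dim_codes if d not in populated]
    if empty:
        raise EmptyDimensionError(f"dimensions with no criteria: {empty}")
    orders = sorted(d.order for d in dims)
    if orders != list(range(1, len(dims) + 1)):
        raise FrameworkError(
            f"dimension orders {orders} are not a permutation of 1..{len(dims)}"
        )


def _compute_blocks(
    dims: tuple[Dimension, ...], crits: tuple[Criterion, ...]
) -> dict[str, range]:
    blocks: dict[str, range] = {}
    start = 0
    for d in dims:
        size = sum(1 for c in crits if c.dimension_code == d.code)
        blocks[d.code] = range(start, start + size)
        start += size
    return blocks


def load_framework(source: str | Path | pd.DataFrame) -> CriteriaFramework:
    """Read a framework from a CSV document (or pre-parsed table).

    The document has columns ``record`` (``dimension``/``criterion``),
    ``code``, ``name`` and ``parent`` (empty for dimensions).  Dimension
    order follows file order.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = {"record", "code", "name", "parent"}
    missing = required - set(table.columns)
    if missing:
        raise FrameworkError(f"framework document missing columns {sorted(missing)}")
    dims: list[Dimension] = []
    crits: list[Criterion] = []
    for _, row in table.iterrows():
        kind = row["record"].strip().lower()
        if kind == "dimension":
            dims.append(Dimension(row["code"], row["name"], order=len(dims) + 1))
        elif kind == "criterion":
            desc = str(row["description"]) if "description" in table.columns else ""
            crits.append(Criterion(row["code"], row["name"], row["parent"], desc))
        else:
            raise FrameworkError(f"unknown record type {row['record']!r}")
    return CriteriaFramework(tuple(dims), tuple(crits))


def write_framework(framework: CriteriaFramework, path: str | Path) -> None:
    """Write a framework document readable by :func:`load_framework`."""
    rows: list[dict[str, str]] = []
    for d in framework.dimensions:
        rows.append({"record": "dimension", "code": d.code, "name": d.name,
                     "parent": "", "description": ""})
    for c in framework.criteria:
        rows.append({"record": "criterion", "code": c.code, "name": c.name,
                     "parent": c.dimension_code, "description": c.description})
    pd.DataFrame(rows).to_csv(path, index=False)


def case_framework() -> CriteriaFramework:
    """The bundled Qianshan community framework: 6 dimensions, 16 criteria."""
    ref = resources.files("danpv.data").joinpath("qianshan_framework.csv")
    with resources.as_file(ref) as path:
        return load_framework(path)


def make_framework(spec: Mapping[str, Iterable[str]]) -> CriteriaFramework:
    """Build a framework from ``{dimension_code: [criterion codes]}``.

    Handy for synthetic and property tests; labels default to the codes.
    """
    dims = tuple(
        Dimension(code, code, order=i + 1) for i, code in enumerate(spec)
    )
    crits = tuple(
        Criterion(c, c, d) for d, members in spec.items() for c in members
    )
    return CriteriaFramework(dims, crits)
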