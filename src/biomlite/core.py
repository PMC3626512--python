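"""In-memory sample-by-observation contingency tables.

The central data structure of comparative omics: a matrix of abundances of
observations (OTUs, genes, pathways, metabolites, ...) per sample.  Rows are
observations and columns are samples, indices are 0-based.  Tables carry
per-axis metadata (e.g. a taxonomy lineage per OTU) plus provenance fields,
and are backed either by a sparse coordinate list -- only non-zero cells are
stored, as (row, column, value) triples -- or a dense row-major grid.

The fraction of cells with a non-zero value is the table's *density*; real
marker-gene survey tables are frequently <10% dense, which is why the sparse
backing exists.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "AxisEntry",
    "SparsePayload",
    "DensePayload",
    "Table",
    "EmptyTableError",
    "UnknownIdError",
    "NonNumericError",
    "density",
    "get_value",
    "to_sparse",
    "to_dense",
    "sample_sums",
    "observation_sums",
    "as_array",
    "cells_equal",
    "ELEMENT_TYPES",
]

#: Legal values of a table's matrix_element_type.
ELEMENT_TYPES = ("int", "float", "unicode")


def _is_zero(v) -> bool:
    # the implicit value of an absent sparse cell: numeric 0, or "" for
    # unicode tables
    return v == 0 or v == ""


class EmptyTableError(ValueError):
    """An operation that is undefined on a zero-cell table was requested."""


class UnknownIdError(KeyError):
    """A lookup used an id that does not exist on the named axis."""

    def __init__(self, axis: str, id_: str):
        super().__init__(f"unknown {axis} id: {id_!r}")
        self.axis = axis
        self.id = id_


class NonNumericError(TypeError):
    """Arithmetic was requested on a table with unicode element type."""


@dataclass(frozen=True)
class AxisEntry:
    """One row or column of the table: an id plus optional metadata.

    Metadata is an opaque mapping of text keys to text, numbers, or lists of
    text (e.g. ``{"taxonomy": ["k__Bacteria", "p__Firmicutes"]}``).  Absence
    is represented as ``None`` and serialized as JSON null.
    """

    id: str
    metadata: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.id, str) or not self.id:
            raise ValueError("axis entry id must be non-empty text")


def _as_axis_entries(entries: Iterable, axis: str) -> list[AxisEntry]:
    out = []
    for e in entries:
        if isinstance(e, AxisEntry):
            out.append(e)
        elif isinstance(e, str):
            out.append(AxisEntry(e))
        else:
            raise TypeError(f"{axis} entries must be AxisEntry or str, got {type(e)!r}")
    seen: set[str] = set()
    for e in out:
        if e.id in seen:
            raise ValueError(f"duplicate {axis} id: {e.id!r}")
        seen.add(e.id)
    return out


class SparsePayload:
    """Coordinate-list backing: only non-zero cells, as (row, col, value).

    Invariants enforced at construction: indices in range, no duplicate
    coordinates, no stored zeros (explicit zeros handed to the constructor
    are dropped silently; duplicates are an error).  Triples are kept sorted
    row-major so serialization is deterministic.
    """

    kind = "sparse"
    __slots__ = ("shape", "triples", "_index")

    def __init__(self, shape: Sequence[int], triples: Iterable[Sequence]):
        n_obs, n_samp = int(shape[0]), int(shape[1])
        if n_obs < 0 or n_samp < 0:
            raise ValueError(f"negative shape: {shape!r}")
        self.shape = (n_obs, n_samp)
        seen: set[tuple[int, int]] = set()
        kept: list[tuple[int, int, Any]] = []
        for r, c, v in triples:
            r, c = int(r), int(c)
            if not (0 <= r < n_obs and 0 <= c < n_samp):
                raise ValueError(
                    f"sparse index ({r}, {c}) out of range for shape {self.shape}"
                )
            if _is_zero(v):
                continue  # zeros are implicit in the sparse backing
            if (r, c) in seen:
                raise ValueError(f"duplicate sparse coordinate ({r}, {c})")
            seen.add((r, c))
            kept.append((r, c, v))
        kept.sort(key=lambda t: (t[0], t[1]))
        self.triples = kept
        self._index: dict[tuple[int, int], Any] | None = None

    @classmethod
    def _from_checked(cls, shape, sorted_triples) -> "SparsePayload":
        # Fast path for internal callers that guarantee the invariants
        # (synthetic generation, dense->sparse conversion).
        p = cls.__new__(cls)
        p.shape = (int(shape[0]), int(shape[1]))
        p.triples = sorted_triples
        p._index = None
        return p

    def count_nonzero(self) -> int:
        return len(self.triples)

    def value_at(self, r: int, c: int, zero):
        if self._index is None:
            self._index = {(tr, tc): v for tr, tc, v in self.triples}
        return self._index.get((r, c), zero)

    def values(self):
        return (v for _, _, v in self.triples)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SparsePayload)
            and self.shape == other.shape
            and self.triples == other.triples
        )

    def __repr__(self) -> str:
        return f"SparsePayload(shape={self.shape}, nnz={len(self.triples)})"


class DensePayload:
    """Full-grid backing: every cell stored, zeros included, row-major."""

    kind = "dense"
    __slots__ = ("shape", "grid")

    def __init__(self, shape: Sequence[int], grid: Iterable[Sequence]):
        n_obs, n_samp = int(shape[0]), int(shape[1])
        if n_obs < 0 or n_samp < 0:
            raise ValueError(f"negative shape: {shape!r}")
        self.shape = (n_obs, n_samp)
        rows = [list(row) for row in grid]
        if len(rows) != n_obs:
            raise ValueError(f"grid has {len(rows)} rows, expected {n_obs}")
        for i, row in enumerate(rows):
            if len(row) != n_samp:
                raise ValueError(f"grid row {i} has {len(row)} entries, expected {n_samp}")
        self.grid = rows

    def count_nonzero(self) -> int:
        return sum(1 for row in self.grid for v in row if not _is_zero(v))

    def value_at(self, r: int, c: int, zero):
        return self.grid[r][c]

    def values(self):
        return (v for row in self.grid for v in row)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DensePayload)
            and self.shape == other.shape
            and self.grid == other.grid
        )

    def __repr__(self) -> str:
        return f"DensePayload(shape={self.shape})"


Payload = Union[SparsePayload, DensePayload]

_COERCE: dict[str, Callable] = {}


def _coerce_int(v):
    if type(v) is int:
        return v
    if isinstance(v, (bool,)):
        raise TypeError("bool is not a valid int cell value")
    if isinstance(v, (int, np.integer)):
        return int(v)
    if isinstance(v, float) and v.is_integer():
        return int(v)
    raise TypeError(f"value {v!r} is not consistent with element type 'int'")


def _coerce_float(v):
    if type(v) is float:
        return v
    if isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool):
        return float(v)
    raise TypeError(f"value {v!r} is not consistent with element type 'float'")


def _coerce_str(v):
    if isinstance(v, str):
        return v
    raise TypeError(f"value {v!r} is not consistent with element type 'unicode'")


_COERCE.update({"int": _coerce_int, "float": _coerce_float, "unicode": _coerce_str})


def _coerce_payload(payload: Payload, element_type: str) -> Payload:
    coerce = _COERCE[element_type]
    if payload.kind == "sparse":
        if element_type == "int" and all(type(v) is int for _, _, v in payload.triples):
            return payload
        triples = [(r, c, coerce(v)) for r, c, v in payload.triples]
        return SparsePayload._from_checked(payload.shape, triples)
    if element_type == "int" and all(
        type(v) is int for row in payload.grid for v in row
    ):
        return payload
    grid = [[coerce(v) for v in row] for row in payload.grid]
    return DensePayload(payload.shape, grid)


@dataclass
class Table:
    """A sample-by-observation contingency table with metadata.

    ``element_type`` is one of :data:`ELEMENT_TYPES`; unicode tables support
    structural operations (filtering, conversion, validation) but reject
    arithmetic (sums, rarefaction, collapsing).
    """

    observations: list[AxisEntry]
    samples: list[AxisEntry]
    payload: Payload
    table_type: str = "OTU table"
    element_type: str = "int"
    generated_by: str = "biomlite"
    creation_date: str = "1970-01-01T00:00:00"
    table_id: str | None = None
    #: Unknown top-level keys preserved from a parsed document (best effort);
    #: never serialized, never compared.
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.observations = _as_axis_entries(self.observations, "observation")
        self.samples = _as_axis_entries(self.samples, "sample")
        n_obs, n_samp = self.payload.shape
        if len(self.observations) != n_obs:
            raise ValueError(
                f"{len(self.observations)} observations but payload shape {self.payload.shape}"
            )
        if len(self.samples) != n_samp:
            raise ValueError(
                f"{len(self.samples)} samples but payload shape {self.payload.shape}"
            )
        if self.element_type not in ELEMENT_TYPES:
            raise ValueError(f"element_type must be one of {ELEMENT_TYPES}")
        self.payload = _coerce_payload(self.payload, self.element_type)
        self._obs_index: dict[str, int] | None = None
        self._sample_index: dict[str, int] | None = None

    # -- lookups ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.payload.shape

    def observation_index(self, obs_id: str) -> int:
        if self._obs_index is None:
            self._obs_index = {e.id: i for i, e in enumerate(self.observations)}
        try:
            return self._obs_index[obs_id]
        except KeyError:
            raise UnknownIdError("observation", obs_id) from None

    def sample_index(self, sample_id: str) -> int:
        if self._sample_index is None:
            self._sample_index = {e.id: i for i, e in enumerate(self.samples)}
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise UnknownIdError("sample", sample_id) from None

    def zero(self):
        """The zero value of this table's element type."""
        if self.element_type == "int":
            return 0
        if self.element_type == "float":
            return 0.0
        raise NonNumericError("unicode tables have no zero value")

    def is_numeric(self) -> bool:
        return self.element_type in ("int", "float")


# -- operations ------------------------------------------------------------

def density(table: Table) -> float:
    """Fraction of table cells holding a non-zero value.

    Identical for sparse and dense backings of the same data.  Undefined
    (raises :class:`EmptyTableError`) when either dimension is 0.
    """
    n_obs, n_samp = table.shape
    cells = n_obs * n_samp
    if cells == 0:
        raise EmptyTableError("density is undefined for a zero-cell table")
    return table.payload.count_nonzero() / cells


def get_value(table: Table, obs_id: str, sample_id: str):
    """Value stored at (observation, sample); implicit sparse zeros included."""
    r = table.observation_index(obs_id)
    c = table.sample_index(sample_id)
    zero = table.zero() if table.is_numeric() else ""
    return table.payload.value_at(r, c, zero)


def to_sparse(table: Table) -> Table:
    """Return the table on a sparse backing (identity if already sparse)."""
    if table.payload.kind == "sparse":
        return table
    triples = [
        (r, c, v)
        for r, row in enumerate(table.payload.grid)
        for c, v in enumerate(row)
        if not _is_zero(v)
    ]
    payload = SparsePayload._from_checked(table.shape, triples)
    return replace(table, payload=payload)


def to_dense(table: Table) -> Table:
    """Return the table on a dense backing (identity if already dense)."""
    if table.payload.kind == "dense":
        return table
    zero = table.zero() if table.is_numeric() else ""
    n_obs, n_samp = table.shape
    grid = [[zero] * n_samp for _ in range(n_obs)]
    for r, c, v in table.payload.triples:
        grid[r][c] = v
    return replace(table, payload=DensePayload(table.shape, grid))


def _require_numeric(table: Table, op: str) -> None:
    if not table.is_numeric():
        raise NonNumericError(f"{op} requires a numeric element type, got 'unicode'")


def as_array(table: Table) -> np.ndarray:
    """Dense numpy view of a numeric table (int64 or float64, obs x samples)."""
    _require_numeric(table, "as_array")
    dtype = np.int64 if table.element_type == "int" else np.float64
    n_obs, n_samp = table.shape
    arr = np.zeros((n_obs, n_samp), dtype=dtype)
    if table.payload.kind == "sparse":
        if table.payload.triples:
            rows, cols, vals = zip(*table.payload.triples)
            arr[np.asarray(rows), np.asarray(cols)] = np.asarray(vals, dtype=dtype)
    else:
        if n_obs and n_samp:
            arr[:] = np.asarray(table.payload.grid, dtype=dtype)
    return arr


def sample_sums(table: Table) -> np.ndarray:
    """Per-sample (column) totals, ordered as the sample axis."""
    _require_numeric(table, "sample_sums")
    dtype = np.int64 if table.element_type == "int" else np.float64
    n_obs, n_samp = table.shape
    if table.payload.kind == "sparse":
        out = np.zeros(n_samp, dtype=dtype)
        if table.payload.triples:
            _, cols, vals = zip(*table.payload.triples)
            np.add.at(out, np.asarray(cols), np.asarray(vals, dtype=dtype))
        return out
    if n_obs == 0:
        return np.zeros(n_samp, dtype=dtype)
    return np.asarray(table.payload.grid, dtype=dtype).sum(axis=0)


def observation_sums(table: Table) -> np.ndarray:
    """Per-observation (row) totals, ordered as the observation axis."""
    _require_numeric(table, "observation_sums")
    dtype = np.int64 if table.element_type == "int" else np.float64
    n_obs, n_samp = table.shape
    if table.payload.kind == "sparse":
        out = np.zeros(n_obs, dtype=dtype)
        if table.payload.triples:
            rows, _, vals = zip(*table.payload.triples)
            np.add.at(out, np.asarray(rows), np.asarray(vals, dtype=dtype))
        return out
    if n_samp == 0:
        return np.zeros(n_obs, dtype=dtype)
    return np.asarray(table.payload.grid, dtype=dtype).sum(axis=1)


def cells_equal(a: Table, b: Table) -> bool:
    """True when two tables hold the same values cell-for-cell (any backing)."""
    if a.shape != b.shape:
        return False
    sa, sb = to_sparse(a), to_sparse(b)
    return [(r, c, v) for r, c, v in sa.payload.triples] == [
        (r, c, v) for r, c, v in sb.payload.triples
    ]
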