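"""Structural table operations: axis filtering and metadata-driven collapsing.

Collapsing merges observations that share the leading portion of a
list-valued metadata entry (typically a taxonomy lineage truncated at some
rank), summing their counts per sample.  It is the workhorse behind
"summarize at phylum level"-style analyses and conserves the grand total and
every per-sample total under the strict missing-metadata policy.
"""
from __future__ import annotations

import logging
from dataclasses import replace
from typing import Callable

from .core import (
    AxisEntry,
    DensePayload,
    EmptyTableError,
    SparsePayload,
    Table,
    _require_numeric,
    sample_sums,
    observation_sums,
)

__all__ = ["filter_samples", "filter_observations", "collapse_observations", "CollapseError"]

logger = logging.getLogger("biomlite.ops")

#: predicate signature: (id, metadata-or-None, axis total-or-None) -> bool
Predicate = Callable[[str, dict | None, object], bool]


class CollapseError(ValueError):
    """An observation could not be collapsed under the strict policy."""


def _subset_payload(table: Table, keep_rows: list[int], keep_cols: list[int]):
    row_map = {old: new for new, old in enumerate(keep_rows)}
    col_map = {old: new for new, old in enumerate(keep_cols)}
    shape = (len(keep_rows), len(keep_cols))
    if table.payload.kind == "sparse":
        triples = [
            (row_map[r], col_map[c], v)
            for r, c, v in table.payload.triples
            if r in row_map and c in col_map
        ]
        triples.sort(key=lambda t: (t[0], t[1]))
        return SparsePayload._from_checked(shape, triples)
    grid = [[table.payload.grid[r][c] for c in keep_cols] for r in keep_rows]
    return DensePayload(shape, grid)


def _filter(table: Table, predicate: Predicate, axis: str) -> Table:
    entries = table.samples if axis == "sample" else table.observations
    if table.is_numeric():
        totals = sample_sums(table) if axis == "sample" else observation_sums(table)
        totals = totals.tolist()
    else:
        totals = [None] * len(entries)
    keep = [
        i
        for i, (e, t) in enumerate(zip(entries, totals))
        if predicate(e.id, dict(e.metadata) if e.metadata is not None else None, t)
    ]
    if axis == "sample":
        keep_rows, keep_cols = list(range(table.shape[0])), keep
        new_obs, new_samp = table.observations, [entries[i] for i in keep]
    else:
        keep_rows, keep_cols = keep, list(range(table.shape[1]))
        new_obs, new_samp = [entries[i] for i in keep], table.samples
    if not new_obs and not new_samp:
        raise EmptyTableError("filtering left a 0x0 table")
    return replace(
        table,
        observations=list(new_obs),
        samples=list(new_samp),
        payload=_subset_payload(table, keep_rows, keep_cols),
    )


def filter_samples(table: Table, predicate: Predicate) -> Table:
    """Keep samples for which ``predicate(id, metadata, total)`` is true.

    Retained samples keep their relative order; the input is not mutated.
    For unicode tables the total passed to the predicate is None.
    """
    return _filter(table, predicate, "sample")


def filter_observations(table: Table, predicate: Predicate) -> Table:
    """Keep observations for which ``predicate(id, metadata, total)`` is true."""
    return _filter(table, predicate, "observation")


def collapse_observations(
    table: Table,
    metadata_key: str,
    level: int,
    on_missing: str = "error",
) -> Table:
    """Merge observations sharing the first ``level`` elements of a lineage.

    ``metadata_key`` names a per-observation metadata entry holding a list
    (a bare string is treated as a 1-element lineage).  Observations whose
    truncated lineages coincide are summed cell-wise; the merged observation
    id is the "; "-join of the truncated lineage, output order is first
    appearance.  ``on_missing`` is "error" (default: raise
    :class:`CollapseError` naming the offending observation) or "drop"
    (exclude it, logging how many were dropped).
    """
    _require_numeric(table, "collapse_observations")
    if level < 1:
        raise ValueError("level must be a positive integer")
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")

    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    n_dropped = 0
    for i, entry in enumerate(table.observations):
        md = entry.metadata or {}
        lineage = md.get(metadata_key)
        if isinstance(lineage, str):
            lineage = [lineage]
        if lineage is None or len(lineage) < level:
            if on_missing == "error":
                what = "missing" if lineage is None else f"shorter than level {level}"
                raise CollapseError(
                    f"observation {entry.id!r}: metadata key {metadata_key!r} is {what}"
                )
            n_dropped += 1
            continue
        key = tuple(lineage[:level])
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    if n_dropped:
        logger.warning("collapse dropped %d observation(s) lacking %r", n_dropped, metadata_key)

    zero = table.zero()
    n_samp = table.shape[1]
    # accumulate per-group rows; sparse accumulation keeps big tables cheap
    acc = {key: dict() for key in order}
    if table.payload.kind == "sparse":
        row_group: dict[int, tuple] = {
            i: key for key in order for i in groups[key]
        }
        for r, c, v in table.payload.triples:
            key = row_group.get(r)
            if key is None:
                continue
            acc[key][c] = acc[key].get(c, zero) + v
    else:
        for key in order:
            for i in groups[key]:
                row = table.payload.grid[i]
                bucket = acc[key]
                for c, v in enumerate(row):
                    if v != 0:
                        bucket[c] = bucket.get(c, zero) + v

    new_obs = [
        AxisEntry("; ".join(key), {metadata_key: list(key)}) for key in order
    ]
    triples = [
        (r, c, v)
        for r, key in enumerate(order)
        for c, v in sorted(acc[key].items())
        if v != 0
    ]
    payload = SparsePayload._from_checked((len(order), n_samp), triples)
    result = replace(table, observations=new_obs, payload=payload)
    if table.payload.kind == "dense":
        from .core import to_dense

        result = to_dense(result)
    return result
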