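"""Classic QIIME OTU table I/O (tab-separated text).

The legacy format: a header line ``#OTU ID<TAB>sample ids...`` optionally
ending in ``Consensus Lineage``, then one line per OTU with its counts and,
when present, a taxonomy lineage joined with "; ".  Leading lines starting
with ``#`` before the header are comments.

Conversion is lossy by construction: the classic format has one metadata
column, so only the ``taxonomy`` observation-metadata key survives a write;
every other observation-metadata key, and all sample metadata, is dropped
with a logged warning.
"""
from __future__ import annotations

import logging

from .core import AxisEntry, SparsePayload, Table, as_array, _require_numeric

__all__ = ["parse_classic", "write_classic", "ClassicParseError"]

logger = logging.getLogger("biomlite.classic")

_HEADER_PREFIX = "#OTU ID"
_LINEAGE_HEADER = "Consensus Lineage"


class ClassicParseError(ValueError):
    """A classic OTU table could not be parsed; the message names the line."""


def parse_classic(text: str) -> Table:
    """Parse classic QIIME OTU table text into a sparse-backed Table.

    Counts are parsed as int when every value is integral ("1.0" counts as
    integral), float otherwise.  A trailing "Consensus Lineage" column
    becomes per-observation metadata ``{"taxonomy": [...]}``, split on ";"
    with surrounding whitespace stripped; an empty lineage cell leaves the
    observation without metadata.
    """
    lines = text.replace("\r\n", "\n").split("\n")
    header = None
    header_lineno = 0
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith(_HEADER_PREFIX):
            header = line
            header_lineno = i
            break
        if line.startswith("#"):
            continue  # leading comment
        raise ClassicParseError(
            f"line {i + 1}: expected a comment or a header starting {_HEADER_PREFIX!r}"
        )
    if header is None:
        raise ClassicParseError(f"no header line starting {_HEADER_PREFIX!r} found")

    fields = header.rstrip("\n").split("\t")
    has_taxonomy = len(fields) > 1 and fields[-1].strip() == _LINEAGE_HEADER
    sample_ids = fields[1:-1] if has_taxonomy else fields[1:]
    n_fields = 1 + len(sample_ids) + (1 if has_taxonomy else 0)

    obs_entries: list[AxisEntry] = []
    seen_ids: set[str] = set()
    raw_rows: list[list[float | int]] = []
    all_integral = True
    for offset, line in enumerate(lines[header_lineno + 1 :]):
        lineno = header_lineno + 2 + offset
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n_fields:
            raise ClassicParseError(
                f"line {lineno}: expected {n_fields} tab-separated fields, got {len(parts)}"
            )
        obs_id = parts[0]
        if obs_id in seen_ids:
            raise ClassicParseError(f"line {lineno}: duplicate OTU id {obs_id!r}")
        seen_ids.add(obs_id)
        count_tokens = parts[1 : 1 + len(sample_ids)]
        row: list[float | int] = []
        for tok in count_tokens:
            try:
                val = int(tok)
            except ValueError:
                try:
                    val = float(tok)
                except ValueError:
                    raise ClassicParseError(
                        f"line {lineno}: non-numeric count {tok!r}"
                    ) from None
                if val.is_integer():
                    val = int(val)
                else:
                    all_integral = False
            row.append(val)
        raw_rows.append(row)
        metadata = None
        if has_taxonomy:
            lineage_text = parts[-1].strip()
            if lineage_text:
                lineage = [seg.strip() for seg in lineage_text.split(";")]
                metadata = {"taxonomy": lineage}
        obs_entries.append(AxisEntry(obs_id, metadata))

    element_type = "int" if all_integral else "float"
    if element_type == "float":
        raw_rows = [[float(v) for v in row] for row in raw_rows]
    triples = [
        (r, c, v) for r, row in enumerate(raw_rows) for c, v in enumerate(row) if v != 0
    ]
    payload = SparsePayload((len(obs_entries), len(sample_ids)), triples)
    return Table(
        observations=obs_entries,
        samples=[AxisEntry(s) for s in sample_ids],
        payload=payload,
        table_type="OTU table",
        element_type=element_type,
    )


def write_classic(table: Table) -> str:
    """Serialize a numeric table as classic QIIME OTU table text.

    Integer tables render counts with no decimal point.  The "Consensus
    Lineage" column is emitted only when at least one observation carries a
    ``taxonomy`` metadata entry; observations without one get an empty cell.
    Unix newlines; trailing newline included.
    """
    _require_numeric(table, "write_classic")
    dropped_obs_keys = {
        k
        for e in table.observations
        if e.metadata
        for k in e.metadata
        if k != "taxonomy"
    }
    if dropped_obs_keys:
        logger.warning(
            "classic format carries only 'taxonomy' observation metadata; dropping keys: %s",
            ", ".join(sorted(dropped_obs_keys)),
        )
    if any(e.metadata for e in table.samples):
        logger.warning("classic format has no sample metadata; dropping it")

    has_taxonomy = any(e.metadata and "taxonomy" in e.metadata for e in table.observations)
    header = [_HEADER_PREFIX] + [e.id for e in table.samples]
    if has_taxonomy:
        header.append(_LINEAGE_HEADER)
    out = ["\t".join(header)]

    arr = as_array(table)
    is_int = table.element_type == "int"
    for i, entry in enumerate(table.observations):
        row = arr[i].tolist()
        cells = [entry.id]
        cells.extend(map(str, row) if is_int else (repr(v) for v in row))
        if has_taxonomy:
            lineage = (entry.metadata or {}).get("taxonomy")
            if lineage is None:
                cells.append("")
            elif isinstance(lineage, str):
                cells.append(lineage)
            else:
                cells.append("; ".join(lineage))
        out.append("\t".join(cells))
    return "\n".join(out) + "\n"
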