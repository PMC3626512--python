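"""BIOM v1.0.0 JSON serialization: parser, writer, and format validator.

A BIOM document is a single JSON object with twelve required top-level keys
(id, format, format_url, type, generated_by, date, rows, columns,
matrix_type, matrix_element_type, shape, data).  The matrix is stored either
*sparse* -- ``data`` is a list of ``[row, column, value]`` triples, zeros
implicit -- or *dense* -- ``data`` is a full grid of shape[0] rows of
shape[1] values.

The writer emits a canonical compact rendering: no insignificant whitespace,
fixed key order, integers without a decimal point, floats in their shortest
round-trip decimal form.  Byte counts of the output are therefore
deterministic, which the file-size benchmarks rely on.

The validator never raises on bad input; every problem becomes an entry in a
:class:`ValidationReport` (severity ``error`` or ``warning``).  A document
is loadable into a :class:`~biomlite.core.Table` exactly when its report has
no error-severity entries.
"""
from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from typing import Any

from .core import AxisEntry, DensePayload, SparsePayload, Table, _is_zero

__all__ = [
    "REQUIRED_KEYS",
    "FORMAT_STRING",
    "FORMAT_URL",
    "KNOWN_TABLE_TYPES",
    "Violation",
    "ValidationReport",
    "BiomFormatError",
    "validate",
    "parse_biom",
    "write_biom",
]

#: Required top-level keys, in canonical writer order.
REQUIRED_KEYS = (
    "id",
    "format",
    "format_url",
    "type",
    "generated_by",
    "date",
    "rows",
    "columns",
    "matrix_type",
    "matrix_element_type",
    "shape",
    "data",
)

FORMAT_STRING = "Biological Observation Matrix 1.0.0"
FORMAT_URL = "http://biom-format.org"

#: Conventional table types.  Values outside this set only warn: the format
#: itself does not change with the data type carried.
KNOWN_TABLE_TYPES = frozenset(
    {
        "OTU table",
        "Pathway table",
        "Function table",
        "Ortholog table",
        "Gene table",
        "Metabolite table",
        "Taxon table",
    }
)

_MATRIX_TYPES = ("sparse", "dense")
_ELEMENT_TYPES = ("int", "float", "unicode")


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    code: str
    message: str
    path: str

    def render(self) -> str:
        return f"{self.severity.upper()} [{self.code}] at {self.path}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warning"]

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def render(self) -> str:
        if not self.violations:
            return "valid BIOM document (no violations)"
        lines = [v.render() for v in self.violations]
        if self.is_valid:
            lines.append("valid BIOM document (warnings only)")
        return "\n".join(lines)


class BiomFormatError(ValueError):
    """Raised by the parser when a document fails validation."""

    def __init__(self, report: ValidationReport):
        super().__init__(report.render())
        self.report = report


def _err(v, code, message, path):
    v.append(Violation("error", code, message, path))


def _warn(v, code, message, path):
    v.append(Violation("warning", code, message, path))


def _check_axis(v, entries, name, expected_len):
    ok = True
    if not isinstance(entries, list):
        _err(v, f"{name}-not-list", f"'{name}' must be a JSON array", f"/{name}")
        return False
    if expected_len is not None and len(entries) != expected_len:
        _err(
            v,
            f"shape/{name}-length-mismatch",
            f"shape declares {expected_len} {name} but {len(entries)} present",
            f"/{name}",
        )
        ok = False
    seen: set[str] = set()
    for i, e in enumerate(entries):
        path = f"/{name}/{i}"
        if not isinstance(e, dict) or "id" not in e:
            _err(v, f"{name}-entry-malformed", "axis entry must be an object with an 'id'", path)
            ok = False
            continue
        if not isinstance(e["id"], str) or not e["id"]:
            _err(v, f"{name}-id-malformed", "axis id must be non-empty text", path)
            ok = False
            continue
        if e["id"] in seen:
            _err(v, f"duplicate-{name[:-1]}-id", f"duplicate id {e['id']!r}", path)
            ok = False
        seen.add(e["id"])
        md = e.get("metadata")
        if md is not None and not isinstance(md, dict):
            _err(v, f"{name}-metadata-malformed", "metadata must be an object or null", path)
            ok = False
    return ok


def _validate_doc(doc: Any) -> list[Violation]:
    v: list[Violation] = []
    if not isinstance(doc, dict):
        _err(v, "not-an-object", "top-level JSON value must be an object", "/")
        return v

    for key in REQUIRED_KEYS:
        if key not in doc:
            _err(v, "missing-key", f"required key {key!r} is absent", f"/{key}")

    if "format" in doc and doc["format"] != FORMAT_STRING:
        _warn(v, "format-mismatch", f"expected {FORMAT_STRING!r}, got {doc['format']!r}", "/format")
    if "format_url" in doc and doc["format_url"] != FORMAT_URL:
        _warn(v, "format-url-mismatch", f"expected {FORMAT_URL!r}", "/format_url")
    if "type" in doc:
        if not isinstance(doc["type"], str):
            _err(v, "type-malformed", "'type' must be text", "/type")
        elif doc["type"] not in KNOWN_TABLE_TYPES:
            _warn(v, "unknown-table-type", f"unconventional table type {doc['type']!r}", "/type")
    if "date" in doc:
        try:
            datetime.datetime.fromisoformat(str(doc["date"]))
        except (TypeError, ValueError):
            _warn(v, "date-not-iso8601", f"date {doc['date']!r} is not ISO-8601", "/date")

    shape_ok = False
    n_obs = n_samp = None
    if "shape" in doc:
        shape = doc["shape"]
        if (
            isinstance(shape, list)
            and len(shape) == 2
            and all(isinstance(x, int) and not isinstance(x, bool) and x >= 0 for x in shape)
        ):
            shape_ok = True
            n_obs, n_samp = shape
        else:
            _err(v, "shape-malformed", "shape must be a 2-list of non-negative integers", "/shape")

    if "rows" in doc:
        _check_axis(v, doc["rows"], "rows", n_obs if shape_ok else None)
    if "columns" in doc:
        _check_axis(v, doc["columns"], "columns", n_samp if shape_ok else None)

    matrix_type = doc.get("matrix_type")
    if "matrix_type" in doc and matrix_type not in _MATRIX_TYPES:
        _err(v, "matrix-type-malformed", f"matrix_type must be one of {_MATRIX_TYPES}", "/matrix_type")
    element_type = doc.get("matrix_element_type")
    if "matrix_element_type" in doc and element_type not in _ELEMENT_TYPES:
        _err(
            v,
            "element-type-malformed",
            f"matrix_element_type must be one of {_ELEMENT_TYPES}",
            "/matrix_element_type",
        )

    def _value_ok(x):
        if element_type == "unicode":
            return isinstance(x, str)
        return isinstance(x, (int, float)) and not isinstance(x, bool)

    data = doc.get("data")
    if "data" in doc and shape_ok and matrix_type in _MATRIX_TYPES:
        if not isinstance(data, list):
            _err(v, "data-malformed", "'data' must be a JSON array", "/data")
        elif matrix_type == "sparse":
            seen: set[tuple[int, int]] = set()
            for i, entry in enumerate(data):
                path = f"/data/{i}"
                if not (isinstance(entry, list) and len(entry) == 3):
                    _err(v, "sparse-entry-malformed", "sparse entry must be a 3-list", path)
                    continue
                r, c, val = entry
                if not all(isinstance(x, int) and not isinstance(x, bool) for x in (r, c)):
                    _err(v, "sparse-index-malformed", "row/column indices must be integers", path)
                    continue
                if not (0 <= r < n_obs and 0 <= c < n_samp):
                    _err(
                        v,
                        "index-out-of-range",
                        f"index ({r}, {c}) out of range for shape [{n_obs}, {n_samp}]",
                        path,
                    )
                    continue
                if (r, c) in seen:
                    _err(v, "duplicate-coordinate", f"coordinate ({r}, {c}) repeated", path)
                seen.add((r, c))
                if not _value_ok(val):
                    _err(v, "value-type-mismatch", f"value {val!r} inconsistent with element type", path)
                elif val == 0:
                    _warn(v, "explicit-zero", f"explicit zero at ({r}, {c})", path)
        else:  # dense
            if len(data) != n_obs:
                _err(v, "dense-row-count-mismatch", f"{len(data)} data rows, shape declares {n_obs}", "/data")
            for i, row in enumerate(data):
                path = f"/data/{i}"
                if not isinstance(row, list) or len(row) != n_samp:
                    _err(v, "dense-row-length-mismatch", f"dense row must have {n_samp} entries", path)
                    continue
                for j, val in enumerate(row):
                    if not _value_ok(val):
                        _err(v, "value-type-mismatch", f"value {val!r} inconsistent with element type", f"{path}/{j}")
                        break
    return v


def validate(text: str | bytes) -> ValidationReport:
    """Check arbitrary bytes/text against the BIOM v1.0.0 format rules."""
    try:
        doc = json.loads(text)
    except (ValueError, TypeError) as exc:
        return ValidationReport([Violation("error", "json-malformed", str(exc), "/")])
    return ValidationReport(_validate_doc(doc))


def parse_biom(text: str | bytes) -> Table:
    """Load a BIOM v1.0.0 JSON document into a :class:`Table`.

    Raises :class:`json.JSONDecodeError` on malformed JSON and
    :class:`BiomFormatError` (carrying the full report) on any
    error-severity format violation.
    """
    doc = json.loads(text)
    report = ValidationReport(_validate_doc(doc))
    if not report.is_valid:
        raise BiomFormatError(report)

    def axis(entries):
        return [AxisEntry(e["id"], e.get("metadata")) for e in entries]

    shape = tuple(doc["shape"])
    if doc["matrix_type"] == "sparse":
        payload = SparsePayload(shape, doc["data"])
    else:
        payload = DensePayload(shape, doc["data"])
    extra = {k: doc[k] for k in doc if k not in REQUIRED_KEYS}
    return Table(
        observations=axis(doc["rows"]),
        samples=axis(doc["columns"]),
        payload=payload,
        table_type=doc["type"],
        element_type=doc["matrix_element_type"],
        generated_by=doc["generated_by"],
        creation_date=doc["date"],
        table_id=doc["id"],
        extra=extra,
    )


def write_biom(table: Table, matrix_type: str = "sparse") -> str:
    """Serialize a table as canonical compact BIOM v1.0.0 JSON text.

    ``matrix_type`` selects the on-disk representation independently of the
    table's in-memory backing.  Output is deterministic: same table, same
    bytes.  Unknown keys preserved on ``table.extra`` are not written.
    """
    if matrix_type not in _MATRIX_TYPES:
        raise ValueError(f"matrix_type must be one of {_MATRIX_TYPES}")
    n_obs, n_samp = table.shape
    if matrix_type == "sparse":
        if table.payload.kind == "sparse":
            data = [[r, c, v] for r, c, v in table.payload.triples]
        else:
            data = [
                [r, c, v]
                for r, row in enumerate(table.payload.grid)
                for c, v in enumerate(row)
                if not _is_zero(v)
            ]
    else:
        if table.payload.kind == "dense":
            data = [list(row) for row in table.payload.grid]
        else:
            zero = table.zero() if table.is_numeric() else ""
            data = [[zero] * n_samp for _ in range(n_obs)]
            for r, c, v in table.payload.triples:
                data[r][c] = v
    doc = {
        "id": table.table_id,
        "format": FORMAT_STRING,
        "format_url": FORMAT_URL,
        "type": table.table_type,
        "generated_by": table.generated_by,
        "date": table.creation_date,
        "rows": [
            {"id": e.id, "metadata": dict(e.metadata) if e.metadata is not None else None}
            for e in table.observations
        ],
        "columns": [
            {"id": e.id, "metadata": dict(e.metadata) if e.metadata is not None else None}
            for e in table.samples
        ],
        "matrix_type": matrix_type,
        "matrix_element_type": table.element_type,
        "shape": [n_obs, n_samp],
        "data": data,
    }
    return json.dumps(doc, separators=(",", ":"), ensure_ascii=False)
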