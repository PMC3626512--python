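"""Synthetic tables and the sparse/dense file-size analyses.

The file compression ratio -- classic tab-separated size divided by sparse
BIOM size -- is a function of table density: tab-separated text stores one
value per cell with positions implied, while a sparse coordinate list must
spell out *row, column, value* for each non-zero cell but skips zeros
entirely.  At ~1% density a table has 100-fold fewer stored counts in sparse
form, yet the file is only ~10-fold smaller because of that positional
overhead.  As density rises the overhead dominates and, at roughly 15%
density, the dense BIOM rendering overtakes the sparse one on disk.

This module generates seeded synthetic tables of controlled shape, density,
value distribution, and metadata richness, measures the byte size of each
serialization under the canonical compact writers, sweeps density, locates
the dense/sparse crossover, and fits the power law ratio = a * density**b on
log-log axes.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .biom_io import write_biom
from .classic_io import write_classic
from .core import AxisEntry, DensePayload, SparsePayload, Table, density as table_density

__all__ = [
    "SynthSpec",
    "SizeReport",
    "PowerLawFit",
    "generate_table",
    "size_report",
    "density_sweep",
    "find_dense_sparse_crossover",
    "fit_power_law",
    "format_sweep_tsv",
    "sweep_to_json",
]

_SEED_MASK = 0x7FFFFFFF

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_NAME_STEMS = (
    "Firmia", "Bactera", "Prota", "Actina", "Clostria", "Bacilla",
    "Rosea", "Pseudia", "Lactia", "Vibria", "Coccia", "Spira",
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic contingency table.

    Defaults emulate a marker-gene OTU table: ~1% non-zero cells, geometric
    integer counts (heavy in 1s and 2s, mean 2), and a 7-rank taxonomy
    lineage (kingdom through species) on every observation.
    """

    n_samples: int
    n_observations: int
    density: float = 0.01
    value_dist: str = "geometric"  # "unit" | "geometric" | "uniform_int"
    geometric_p: float = 0.5
    uniform_lo: int = 1
    uniform_hi: int = 10
    taxonomy_depth: int = 7
    seed: int = 0


@dataclass(frozen=True)
class SizeReport:
    """Serialized byte counts of one table in each dialect."""

    sparse_biom_bytes: int
    dense_biom_bytes: int
    classic_tsv_bytes: int
    density: float
    compression_ratio: float  # classic_tsv_bytes / sparse_biom_bytes


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of ratio = coefficient * density**exponent."""

    coefficient: float
    exponent: float
    r_squared: float


def _lineage(rng: np.random.Generator, depth: int) -> list[str]:
    picks = rng.integers(0, len(_NAME_STEMS), size=depth)
    out = []
    for rank in range(depth):
        prefix = _RANK_PREFIXES[rank % len(_RANK_PREFIXES)]
        out.append(f"{prefix}{_NAME_STEMS[picks[rank]]}{rank}")
    return out


def generate_table(spec: SynthSpec) -> Table:
    """Generate a seeded random table matching ``spec`` exactly.

    Exactly ``round(density * cells)`` non-zero cells are placed uniformly
    at random without collision; values are drawn from the requested
    distribution and are never zero.  Deterministic given the seed.
    """
    n_obs, n_samp = spec.n_observations, spec.n_samples
    if n_obs < 1 or n_samp < 1:
        raise ValueError("table shape must be positive in both dimensions")
    if not (0.0 < spec.density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    cells = n_obs * n_samp
    nnz = int(round(spec.density * cells))
    if nnz < 1:
        raise ValueError("requested density yields zero non-zero cells")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed & _SEED_MASK))

    if nnz == cells:
        flat = np.arange(cells)
    else:
        flat = np.sort(rng.choice(cells, size=nnz, replace=False))
    rows, cols = np.divmod(flat, n_samp)

    if spec.value_dist == "unit":
        values = np.ones(nnz, dtype=np.int64)
    elif spec.value_dist == "geometric":
        if not (0.0 < spec.geometric_p <= 1.0):
            raise ValueError("geometric_p must be in (0, 1]")
        values = rng.geometric(spec.geometric_p, size=nnz)
    elif spec.value_dist == "uniform_int":
        if spec.uniform_lo < 1 or spec.uniform_hi < spec.uniform_lo:
            raise ValueError("uniform_int bounds must satisfy 1 <= lo <= hi")
        values = rng.integers(spec.uniform_lo, spec.uniform_hi + 1, size=nnz)
    else:
        raise ValueError(f"unknown value_dist {spec.value_dist!r}")

    observations = []
    for i in range(n_obs):
        metadata = None
        if spec.taxonomy_depth > 0:
            metadata = {"taxonomy": _lineage(rng, spec.taxonomy_depth)}
        observations.append(AxisEntry(str(i), metadata))
    samples = [AxisEntry(f"S{j}") for j in range(n_samp)]

    vals = values.tolist()
    if spec.density == 1.0:
        grid = [vals[i * n_samp : (i + 1) * n_samp] for i in range(n_obs)]
        payload = DensePayload((n_obs, n_samp), grid)
    else:
        triples = list(zip(rows.tolist(), cols.tolist(), vals))
        payload = SparsePayload._from_checked((n_obs, n_samp), triples)
    return Table(
        observations=observations,
        samples=samples,
        payload=payload,
        table_type="OTU table",
        element_type="int",
        generated_by="biomlite synthetic generator",
        creation_date="2012-01-01T00:00:00",
        table_id=f"synthetic table seed={spec.seed}",
    )


def size_report(table: Table) -> SizeReport:
    """Measure the table's byte size in each canonical serialization."""
    sparse_bytes = len(write_biom(table, "sparse").encode("utf-8"))
    dense_bytes = len(write_biom(table, "dense").encode("utf-8"))
    classic_bytes = len(write_classic(table).encode("utf-8"))
    d = table_density(table)
    return SizeReport(
        sparse_biom_bytes=sparse_bytes,
        dense_biom_bytes=dense_bytes,
        classic_tsv_bytes=classic_bytes,
        density=d,
        compression_ratio=classic_bytes / sparse_bytes,
    )


def _check_densities(densities: Sequence[float]) -> list[float]:
    ds = [float(d) for d in densities]
    if not ds:
        raise ValueError("densities must be non-empty")
    if any(not (0.0 < d <= 1.0) for d in ds):
        raise ValueError("densities must lie in (0, 1]")
    if any(b <= a for a, b in zip(ds, ds[1:])):
        raise ValueError("densities must be strictly increasing")
    return ds


def density_sweep(base_spec: SynthSpec, densities: Sequence[float]) -> list[SizeReport]:
    """One :class:`SizeReport` per density, all else held fixed."""
    return [
        size_report(generate_table(replace(base_spec, density=d)))
        for d in _check_densities(densities)
    ]


def find_dense_sparse_crossover(
    base_spec: SynthSpec,
    lo: float = 0.01,
    hi: float = 0.50,
    step: float = 0.01,
) -> float | None:
    """Smallest swept density where dense BIOM bytes <= sparse BIOM bytes.

    Scans ``lo, lo+step, ...`` up to ``hi`` inclusive and returns the first
    density at which the dense rendering is no larger on disk, or ``None``
    when sparse wins throughout the range.
    """
    if not (0.0 < lo < hi <= 1.0):
        raise ValueError("need 0 < lo < hi <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(math.floor((hi - lo) / step + 1e-9))
    for k in range(n_steps + 1):
        d = round(lo + k * step, 12)
        table = generate_table(replace(base_spec, density=d))
        sparse_bytes = len(write_biom(table, "sparse").encode("utf-8"))
        dense_bytes = len(write_biom(table, "dense").encode("utf-8"))
        if dense_bytes <= sparse_bytes:
            return d
    return None


def fit_power_law(points: Sequence[tuple[float, float]]) -> PowerLawFit:
    """Fit ratio = a * density**b by least squares on log-log axes.

    R-squared is computed on the log scale (the scale on which the model is
    linear); a constant-ratio input has zero residual around the flat fit
    and reports R-squared 1.0.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    ds = np.array([p[0] for p in points], dtype=float)
    rs = np.array([p[1] for p in points], dtype=float)
    if (ds <= 0).any() or (rs <= 0).any():
        raise ValueError("all densities and ratios must be positive")
    x, y = np.log(ds), np.log(rs)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerLawFit(coefficient=float(np.exp(intercept)), exponent=float(slope), r_squared=r2)


def format_sweep_tsv(reports: Sequence[SizeReport]) -> str:
    """Tab-separated rendering of a density sweep (one line per density)."""
    lines = ["density\tsparse_biom_bytes\tdense_biom_bytes\tclassic_tsv_bytes\tcompression_ratio"]
    for r in reports:
        lines.append(
            f"{r.density:.6g}\t{r.sparse_biom_bytes}\t{r.dense_biom_bytes}"
            f"\t{r.classic_tsv_bytes}\t{r.compression_ratio:.6g}"
        )
    return "\n".join(lines) + "\n"


def sweep_to_json(reports: Sequence[SizeReport]) -> str:
    """Machine-readable JSON rendering of a density sweep."""
    return json.dumps(
        [
            {
                "density": r.density,
                "sparse_biom_bytes": r.sparse_biom_bytes,
                "dense_biom_bytes": r.dense_biom_bytes,
                "classic_tsv_bytes": r.classic_tsv_bytes,
                "compression_ratio": r.compression_ratio,
            }
            for r in reports
        ],
        indent=2,
    )
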