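"""Shared fixtures: small deterministic random tables and document builders."""
from __future__ import annotations

import numpy as np
import pytest

from biomlite import AxisEntry, DensePayload, SparsePayload, Table

_TAXA = ["k__Bacteria", "p__Firmicutes", "c__Bacilli", "o__Lactobacillales",
         "f__Streptococcaceae", "g__Streptococcus", "s__mitis"]


def make_random_table(
    seed: int,
    n_obs: int | None = None,
    n_samp: int | None = None,
    element_type: str = "int",
    kind: str = "sparse",
    with_taxonomy: bool = False,
    with_sample_metadata: bool = False,
) -> Table:
    """A small seeded table with ~40% density; shapes default to 2-12 x 2-10."""
    rng = np.random.default_rng(seed)
    n_obs = n_obs if n_obs is not None else int(rng.integers(2, 13))
    n_samp = n_samp if n_samp is not None else int(rng.integers(2, 11))
    mask = rng.random((n_obs, n_samp)) < 0.4
    if element_type == "float":
        vals = np.round(rng.uniform(0.5, 9.5, (n_obs, n_samp)), 3)
    else:
        vals = rng.integers(1, 50, (n_obs, n_samp))
    grid = np.where(mask, vals, 0)
    observations = []
    for i in range(n_obs):
        md = None
        if with_taxonomy:
            depth = int(rng.integers(2, len(_TAXA) + 1))
            md = {"taxonomy": _TAXA[:depth]}
        observations.append(AxisEntry(f"O{i}", md))
    samples = []
    for j in range(n_samp):
        md = {"env": ["soil", "gut", "marine"][j % 3]} if with_sample_metadata else None
        samples.append(AxisEntry(f"S{j}", md))
    if kind == "dense":
        payload = DensePayload((n_obs, n_samp), grid.tolist())
    else:
        rows, cols = np.nonzero(grid)
        triples = list(zip(rows.tolist(), cols.tolist(), grid[rows, cols].tolist()))
        payload = SparsePayload((n_obs, n_samp), triples)
    return Table(
        observations=observations,
        samples=samples,
        payload=payload,
        element_type=element_type,
        generated_by="biomlite tests",
        creation_date="2020-05-01T12:00:00",
        table_id=f"fixture-{seed}",
    )


@pytest.fixture
def table_factory():
    return make_random_table


def make_table(grid, element_type="int", kind="sparse", obs_meta=None, **fields) -> Table:
    """Build a table directly from a nested list of values."""
    n_obs = len(grid)
    n_samp = len(grid[0]) if n_obs else 0
    observations = [
        AxisEntry(f"O{i}", (obs_meta or {}).get(i)) for i in range(n_obs)
    ]
    samples = [AxisEntry(f"S{j}") for j in range(n_samp)]
    if kind == "dense":
        payload = DensePayload((n_obs, n_samp), grid)
    else:
        triples = [
            (r, c, v) for r, row in enumerate(grid) for c, v in enumerate(row) if v != 0
        ]
        payload = SparsePayload((n_obs, n_samp), triples)
    return Table(observations=observations, samples=samples, payload=payload,
                 element_type=element_type, **fields)


@pytest.fixture
def grid_table_factory():
    return make_table


MINIMAL_SPARSE_DOC = {
    "id": None,
    "format": "Biological Observation Matrix 1.0.0",
    "format_url": "http://biom-format.org",
    "type": "OTU table",
    "generated_by": "biomlite tests",
    "date": "2012-03-01T00:00:00",
    "rows": [{"id": "O1", "metadata": None}],
    "columns": [{"id": "S1", "metadata": None}],
    "matrix_type": "sparse",
    "matrix_element_type": "int",
    "shape": [1, 1],
    "data": [[0, 0, 1]],
}


@pytest.fixture
def minimal_sparse_doc():
    import copy

    return copy.deepcopy(MINIMAL_SPARSE_DOC)
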