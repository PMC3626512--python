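"""Rarefaction (collector) curves and the Chao1 richness estimator.

Rarefaction asks how quickly new observations (OTUs, gene families, ...)
accumulate as sequencing effort grows: each sample is subsampled *without
replacement* to a fixed depth -- a multivariate hypergeometric draw from its
counts -- and richness (number of observations with non-zero count) is
averaged over replicates.  Chao1 extrapolates total richness from the
singleton and doubleton counts:

    S_chao1 = S_obs + F1^2 / (2 F2)                     (classic, F2 > 0)
    S_chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1))        (bias-corrected)

where S_obs is observed richness, F1 the number of observations seen exactly
once, and F2 the number seen exactly twice.  The classic form is the
default; the bias-corrected form is used automatically when F2 == 0 (and
always when ``bias_corrected=True``).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .core import SparsePayload, Table, as_array

__all__ = ["RarefactionCurve", "rarefy", "rarefaction_curve", "chao1"]

_SEED_MASK = 0x7FFFFFFF


def _sample_rng(seed: int, depth: int, rep: int, sample_id: str) -> np.random.Generator:
    # One independent stream per (sample, depth, rep): results do not depend
    # on sample order or on which other depths/reps are evaluated.
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([seed & _SEED_MASK, depth, rep, key])
    )


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean richness as a function of subsampling depth."""

    depths: tuple[int, ...]
    mean_richness: tuple[float, ...]
    reps: int
    seed: int


def rarefy(table: Table, depth: int, seed: int, rep: int = 0) -> Table:
    """Subsample every sample to exactly ``depth`` counts, without replacement.

    Each sample whose total is at least ``depth`` is replaced by a
    multivariate hypergeometric draw of ``depth`` counts from it; samples
    with a smaller total are dropped.  The observation axis is unchanged
    (all-zero rows are permitted).  Deterministic given ``seed``; ``rep``
    selects an independent replicate stream.
    """
    if table.element_type != "int":
        raise TypeError("rarefy requires an integer element type")
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    arr = as_array(table)
    totals = arr.sum(axis=0)
    keep: list[int] = []
    cols: list[np.ndarray] = []
    for j, entry in enumerate(table.samples):
        total = int(totals[j])
        if total < depth:
            continue
        keep.append(j)
        if total == depth:
            cols.append(arr[:, j])
        else:
            rng = _sample_rng(seed, depth, rep, entry.id)
            cols.append(rng.multivariate_hypergeometric(arr[:, j], depth))
    n_obs = table.shape[0]
    if cols:
        new_arr = np.column_stack(cols)
    else:
        new_arr = np.zeros((n_obs, 0), dtype=np.int64)
    rows, cs = np.nonzero(new_arr)
    triples = list(
        zip(rows.tolist(), cs.tolist(), new_arr[rows, cs].tolist())
    )
    payload = SparsePayload._from_checked((n_obs, len(keep)), triples)
    result = replace(
        table,
        samples=[table.samples[j] for j in keep],
        payload=payload,
    )
    if table.payload.kind == "dense":
        from .core import to_dense

        result = to_dense(result)
    return result


def rarefaction_curve(
    table: Table, depths: Sequence[int], reps: int, seed: int
) -> RarefactionCurve:
    """Collector curve: mean richness after rarefying, per depth.

    Richness is a per-sample quantity -- the number of observations with a
    non-zero count in that sample after subsampling -- so each depth reports
    the mean over retained samples and over ``reps`` replicates (at depth 1
    this is exactly 1.0: a single draw hits exactly one observation).
    Depths at which every sample is dropped report 0.0.  Reproducible given
    ``seed``.
    """
    depths = [int(d) for d in depths]
    if not depths:
        raise ValueError("depths must be non-empty")
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive integers")
    if sorted(set(depths)) != depths:
        raise ValueError("depths must be strictly increasing")
    if reps < 1:
        raise ValueError("reps must be a positive integer")
    means = []
    for depth in depths:
        richness = []
        for rep in range(reps):
            sub = rarefy(table, depth, seed, rep=rep)
            arr = as_array(sub)
            if arr.shape[1] == 0:
                richness.append(0.0)
            else:
                richness.append(float((arr > 0).sum(axis=0).mean()))
        means.append(float(np.mean(richness)))
    return RarefactionCurve(tuple(depths), tuple(means), reps, seed)


def chao1(counts: Iterable[float], bias_corrected: bool = False) -> float:
    """Chao1 richness estimate from a vector of per-observation counts.

    Zero counts are unobserved and contribute nothing; the estimate is
    always at least the observed richness.  Negative or fractional counts
    are rejected.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.size and not np.all(arr == np.floor(arr)):
        raise ValueError("counts must be integers")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + (f1 * f1) / (2.0 * f2)
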