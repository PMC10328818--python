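"""Beta-diversity distances: Bray–Curtis, Aitchison and Pearson-correlation.

Bray–Curtis is the workhorse.  On proportion vectors p, q it reduces to

    BC(p, q) = 1 - sum_t min(p_t, q_t)

because the general two-term form 1 - 2 C / (S_p + S_q), with C the summed
taxon-wise minima and S the summed abundances, has S_p = S_q = 1.  A
count-space variant (the same formula on raw counts, which differs between
samples of unequal depth) is available via ``on="counts"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CountTable, DistanceMatrix, ValidationError

__all__ = ["bray_curtis", "aitchison", "pearson_distance", "clr"]


def _as_matrix(p) -> tuple[np.ndarray, list[str]]:
    if isinstance(p, pd.DataFrame):
        return p.to_numpy(dtype=float), list(p.columns)
    if isinstance(p, CountTable):
        return p.counts.to_numpy(dtype=float), p.sample_ids
    arr = np.asarray(p, dtype=float)
    return arr, [str(i) for i in range(arr.shape[1])]


def bray_curtis(p, sample_ids: list[str] | None = None, on: str = "proportions") -> DistanceMatrix:
    """Bray–Curtis dissimilarity between the columns of ``p``.

    ``on="proportions"`` (default) expects columns summing to 1 and uses
    ``1 - sum min``; ``on="counts"`` applies the two-term form
    ``1 - 2*sum(min) / (sum_i + sum_j)`` to raw abundance vectors.
    """
    x, ids = _as_matrix(p)
    if sample_ids is not None:
        ids = list(sample_ids)
    if x.size and x.min() < 0:
        raise ValidationError("negative abundances")
    n = x.shape[1]
    if on == "proportions":
        colsum = x.sum(axis=0)
        if n and np.abs(colsum - 1.0).max() > 1e-8:
            raise ValidationError("columns must sum to 1 for proportion-space Bray-Curtis")
    elif on != "counts":
        raise ValidationError(f"unknown Bray-Curtis space {on!r}")
    d = np.zeros((n, n))
    totals = x.sum(axis=0)
    for i in range(n):
        # vectorised over j > i: sum of taxon-wise minima
        mins = np.minimum(x[:, i : i + 1], x[:, i + 1 :]).sum(axis=0)
        denom = totals[i] + totals[i + 1 :]
        with np.errstate(invalid="ignore"):
            dij = np.where(denom > 0, 1.0 - 2.0 * mins / denom, 0.0)
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(d, ids, "bray_curtis")


def clr(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of count columns (taxa x samples)."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    y = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return y - y.mean(axis=0, keepdims=True)


def aitchison(ct, pseudocount: float = 1.0, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Aitchison distance: Euclidean distance between CLR-transformed
    compositions of (counts + pseudocount)."""
    x, ids = _as_matrix(ct)
    if sample_ids is not None:
        ids = list(sample_ids)
    z = clr(x, pseudocount)
    # pairwise Euclidean between columns
    sq = (z**2).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * z.T @ z
    d = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids, "aitchison")


def pearson_distance(p, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """1 - Pearson correlation across taxa between sample columns; range [0, 2]."""
    x, ids = _as_matrix(p)
    if sample_ids is not None:
        ids = list(sample_ids)
    if x.shape[0] < 2:
        raise ValidationError("Pearson distance requires >= 2 taxa")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [ids[j] for j in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance samples: {bad}")
    r = np.corrcoef(x, rowvar=False)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids, "pearson")
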