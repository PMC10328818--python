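"""Taxonomic aggregation, normalisation, rarefaction and alpha diversity.

Alpha indices are computed on genus-aggregated profiles after a single
rarefaction draw to a common depth (the draw's seed is recorded in the
result).  Definitions:

* Shannon  H = -sum p_i ln p_i  (nats, over taxa with p_i > 0)
* observed richness  S_obs = #{i : x_i > 0}
* Chao1 (bias-corrected)  S_obs + F1 (F1 - 1) / (2 (F2 + 1)),
  F1 = number of singletons, F2 = number of doubletons
* Pielou evenness  H / ln S_obs  (undefined when S_obs < 2)
* log-modulo skewness rarity  sample skewness (third standardised moment,
  unbiased-variance denominator) of ln(1 + x_i) over all taxa, zeros included
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import UNKNOWN, CountTable, ValidationError

__all__ = ["aggregate", "relative_abundance", "rarefy", "alpha_panel", "AlphaPanel"]

RANK_SLOT = {"family": 0, "genus": 1}


def aggregate(ct: CountTable, rank: str = "genus") -> CountTable:
    """Sum counts within the requested rank; unknown annotations are dropped.

    Taxon ids are ``family;genus`` lineages.  A taxon whose annotation at the
    requested rank is ``"unknown"`` is removed (with all its reads) before
    aggregation.
    """
    if rank not in RANK_SLOT:
        raise ValidationError(f"unsupported rank {rank!r}")
    slot = RANK_SLOT[rank]
    labels, keep = [], []
    for tid in ct.taxon_ids:
        parts = tid.split(";")
        if len(parts) <= slot:
            raise ValidationError(f"taxon {tid!r} lacks a {rank}-level annotation slot")
        label = parts[slot]
        if label == UNKNOWN:
            continue
        keep.append(tid)
        labels.append(label)
    sub = ct.counts.loc[keep]
    agg = sub.groupby(pd.Index(labels, name="taxon_id")).sum()
    ranks = pd.Series(rank, index=agg.index)
    return CountTable(agg.astype(np.int64), ranks)


def relative_abundance(ct: CountTable) -> pd.DataFrame:
    """Proportion matrix; columns sum to 1.  Zero-depth samples are an error."""
    depths = ct.depths
    if (depths <= 0).any():
        bad = list(depths.index[depths <= 0])
        raise ValidationError(f"zero-depth samples: {bad}")
    return ct.counts / depths


def rarefy(ct: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Single draw, deterministic under ``seed``.  Samples shallower than
    ``depth`` are an error (rarefy to the minimum depth first).
    """
    depths = ct.depths
    too_shallow = list(depths.index[depths < depth])
    if too_shallow:
        raise ValidationError(f"samples shallower than rarefaction depth {depth}: {too_shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(ct.counts.to_numpy())
    counts = ct.counts.to_numpy()
    for j in range(ct.n_samples):
        col = counts[:, j]
        total = col.sum()
        if total == depth:
            out[:, j] = col
        else:
            # multivariate hypergeometric: draw `depth` reads without replacement
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(
        pd.DataFrame(out, index=ct.taxon_ids, columns=ct.sample_ids), ct.ranks.copy()
    )


@dataclass
class AlphaPanel:
    """Per-sample alpha-diversity indices plus the rarefaction depth and seed
    used to compute them."""

    table: pd.DataFrame  # index sample_id; columns shannon, chao1, pielou, observed_richness, rarity_lms
    depth: int
    seed: int

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["depth"] = self.depth
        out["seed"] = self.seed
        out.to_csv(path, sep="\t", index_label="sample_id")


def alpha_panel(ct: CountTable, depth: int | None = None, seed: int = 0) -> AlphaPanel:
    """Rarefy to ``depth`` (default: minimum sample depth) and compute the
    alpha-diversity panel."""
    if depth is None:
        depth = int(ct.depths.min())
    rct = rarefy(ct, depth, seed)
    x = rct.counts.to_numpy().astype(float)
    rows = []
    for j, sid in enumerate(rct.sample_ids):
        rows.append(_alpha_one(x[:, j]))
    tbl = pd.DataFrame(rows, index=rct.sample_ids)
    return AlphaPanel(tbl, depth, seed)


def _alpha_one(x: np.ndarray) -> dict:
    total = x.sum()
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum()) if total > 0 else 0.0
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    pielou = shannon / np.log(s_obs) if s_obs >= 2 else np.nan
    lx = np.log1p(x)
    s = lx.std(ddof=1) if lx.size > 1 else 0.0
    if s > 0:
        m3 = np.mean((lx - lx.mean()) ** 3)
        rarity = float(m3 / s**3)
    else:
        rarity = np.nan
    return {
        "shannon": shannon,
        "chao1": float(chao1),
        "pielou": float(pielou) if np.isfinite(pielou) else np.nan,
        "observed_richness": s_obs,
        "rarity_lms": rarity,
    }
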