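"""Distance-based linear models (PERMANOVA) with sequential sums of squares.

The engine partitions the total sum of squared dissimilarities among ordered
model terms, exactly as ``vegan::adonis2(..., by = "terms")`` does:

1. Gower-center the squared distance matrix:  A = -d^2/2,
   G = (I - 11'/n) A (I - 11'/n);  trace(G) is the total SS.
2. Build the design matrix term by term in declared order (intercept first,
   treatment-coded categoricals, numeric columns, elementwise-product
   interactions); orthonormalise sequentially so that the first k blocks span
   the cumulative design of the first k terms.  Aliased columns drop out with
   reduced df.
3. Sequential SS of term k = tr(H_k G) - tr(H_{k-1} G) with H_k the hat
   projector of the cumulative design; residual SS = tr(G) - tr(H_K G).
4. pseudo-F_term = (SS_term / df_term) / (SS_resid / df_resid); the p-value
   comes from B unrestricted joint row/column permutations of the distance
   matrix, with the +1/+1 convention p = (1 + #{F* >= F}) / (1 + B).

Confounder terms always occupy the earliest positions, so a candidate's
sequential SS is its variance explained *after* the technical confounders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import DistanceMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "DesignSpec",
    "PermanovaResult",
    "DispersionResult",
    "gower_center",
    "fit_permanova",
    "screen_variable",
    "permdisp",
    "within_batch_similarity_test",
]

_ALIAS_TOL = 1e-8


@dataclass(frozen=True)
class Term:
    """One model term: a single variable or a two-way interaction."""

    variables: tuple[str, ...]
    role: str = "candidate"  # "confounder" | "candidate"

    @property
    def name(self) -> str:
        return ":".join(self.variables)

    @property
    def is_interaction(self) -> bool:
        return len(self.variables) == 2


@dataclass
class DesignSpec:
    """Ordered term list; confounders must precede candidates, and an
    interaction must follow both of its main effects."""

    terms: list[Term]

    def __post_init__(self) -> None:
        seen_candidate = False
        declared: set[str] = set()
        for t in self.terms:
            if t.role == "candidate":
                seen_candidate = True
            elif seen_candidate:
                raise ValidationError("confounder terms must precede candidates")
            if t.is_interaction:
                missing = [v for v in t.variables if v not in declared]
                if missing:
                    raise ValidationError(
                        f"interaction {t.name} references undeclared main effect(s) {missing}"
                    )
            declared.update(t.variables)

    @classmethod
    def from_names(
        cls, confounders: list[str] = (), candidates: list[str | tuple[str, str]] = ()
    ) -> "DesignSpec":
        terms = [Term((c,), "confounder") for c in confounders]
        for c in candidates:
            terms.append(Term(tuple(c) if isinstance(c, (tuple, list)) else (c,), "candidate"))
        return cls(terms)

    def names(self) -> list[str]:
        return [t.name for t in self.terms]


@dataclass
class PermanovaResult:
    """Per-term sequential decomposition of a distance model."""

    terms: pd.DataFrame  # index term name; columns df, SS, R2, F, p
    residual_df: int
    residual_ss: float
    total_ss: float
    n: int
    B: int
    seed: int | None = None
    k: int = 0  # design-matrix rank including the intercept
    dropped_samples: list[str] = field(default_factory=list)

    def r2(self, term: str) -> float:
        return float(self.terms.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.loc["Residual"] = [
            self.residual_df,
            self.residual_ss,
            self.residual_ss / self.total_ss if self.total_ss > 0 else np.nan,
            np.nan,
            np.nan,
        ]
        out.loc["Total"] = [self.n - 1, self.total_ss, 1.0, np.nan, np.nan]
        return out


@dataclass
class DispersionResult:
    """Multivariate homogeneity-of-dispersion (PERMDISP) test record."""

    distances: pd.Series  # per-sample distance to its group centroid
    groups: pd.Series
    F: float
    p: float
    n_permutations: int
    seed: int | None = None
    warning: str | None = None

    @property
    def uneven(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < 0.05)


# ---------------------------------------------------------------------------
# core linear algebra


def gower_center(dm: DistanceMatrix) -> np.ndarray:
    """Gower-centered inner-product matrix G of a distance matrix.

    ``trace(G)`` equals the total sum of squares ``(1/n) * sum_{i<j} d_ij^2``.
    """
    d = dm.values
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    return (g + g.T) / 2.0


def _encode_variable(md: SampleMetadata, name: str, samples: list[str]) -> np.ndarray:
    """Design columns for one variable: numeric as-is, categorical
    treatment-coded against its declared (or first-observed) reference."""
    col = md.table.loc[samples, name]
    vdef = md.variables.get(name)
    if vdef is not None and vdef.kind == "numeric":
        return col.to_numpy(dtype=float)[:, None]
    if vdef is None and pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    vals = col.astype(str)
    if vdef is not None and vdef.levels is not None:
        levels = [l for l in vdef.levels if l in set(vals)]
        ref = vdef.reference if vdef.reference in levels else (levels[0] if levels else None)
    else:
        levels = sorted(set(vals))
        ref = levels[0]
    cols = [(vals == lev).to_numpy(dtype=float) for lev in levels if lev != ref]
    if not cols:
        return np.zeros((len(samples), 0))
    return np.column_stack(cols)


def _term_blocks(
    md: SampleMetadata, design: DesignSpec, samples: list[str]
) -> list[np.ndarray]:
    main = {}
    blocks = []
    for t in design.terms:
        if t.is_interaction:
            a = main.get(t.variables[0])
            b = main.get(t.variables[1])
            if a is None:
                a = _encode_variable(md, t.variables[0], samples)
            if b is None:
                b = _encode_variable(md, t.variables[1], samples)
            cols = [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
            blocks.append(np.column_stack(cols) if cols else np.zeros((len(samples), 0)))
        else:
            x = _encode_variable(md, t.variables[0], samples)
            main[t.variables[0]] = x
            blocks.append(x)
    return blocks


def _sequential_basis(blocks: list[np.ndarray], n: int) -> tuple[np.ndarray, list[int]]:
    """Orthonormal basis whose first columns span the intercept and whose
    subsequent column groups span successive term blocks; aliased columns are
    dropped (reduced df)."""
    q_cols = [np.full(n, 1.0 / np.sqrt(n))]
    dfs = []
    for x in blocks:
        kept = 0
        for j in range(x.shape[1]):
            v = x[:, j].astype(float).copy()
            norm0 = np.linalg.norm(v)
            if norm0 == 0:
                continue
            q = np.column_stack(q_cols)
            for _ in range(2):  # twice for numerical stability
                v -= q @ (q.T @ v)
            nv = np.linalg.norm(v)
            if nv > _ALIAS_TOL * max(norm0, 1.0):
                q_cols.append(v / nv)
                kept += 1
        dfs.append(kept)
    return np.column_stack(q_cols), dfs


def fit_permanova(
    dm: DistanceMatrix,
    md: SampleMetadata,
    design: DesignSpec,
    B: int = 999,
    seed: int | None = 0,
    permutations: np.ndarray | None = None,
) -> PermanovaResult:
    """Sequential-SS PERMANOVA of a distance matrix on an ordered design.

    Samples with missing values in any design variable are dropped (and
    logged).  ``B=0`` skips permutation inference (p = NaN), which is enough
    for model selection on residual SS.  ``permutations`` may supply an
    explicit (B, n) array of permutation index rows, e.g. the full
    enumeration for small n.
    """
    varnames = sorted({v for t in design.terms for v in t.variables})
    sub = md.table.reindex(dm.sample_ids)
    complete = sub[varnames].notna().all(axis=1) if varnames else pd.Series(True, index=sub.index)
    samples = [s for s, ok in zip(dm.sample_ids, complete) if ok]
    dropped = [s for s in dm.sample_ids if s not in set(samples)]
    if dropped:
        logger.info("fit_permanova: dropped %d samples with missing design values", len(dropped))
    dmx = dm.select(samples)
    n = dmx.n
    g = gower_center(dmx)
    total_ss = float(np.trace(g))

    blocks = _term_blocks(md, design, samples)
    q, dfs = _sequential_basis(blocks, n)
    rank = q.shape[1]  # includes intercept
    df_resid = n - rank
    if df_resid < 1:
        raise ValidationError(f"n={n} too small for a design of rank {rank}")
    for t, df in zip(design.terms, dfs):
        if df == 0:
            logger.warning("fit_permanova: term %s aliased (df 0)", t.name)
    if min(dfs, default=1) >= 0 and n < sum(dfs) + 2:
        raise ValidationError("n too small: need at least total model df + 2 samples")

    diag = np.einsum("ij,jk,ik->k", g, q, q, optimize=True)  # q_k' G q_k per column
    term_ss = _per_term_ss(diag, dfs)
    model_ss = diag.sum()  # intercept column contributes ~0 (G centered)
    resid_ss = total_ss - model_ss
    f_obs = _pseudo_f(term_ss, dfs, resid_ss, df_resid)

    if permutations is not None:
        perms = np.asarray(permutations, dtype=int)
        B = perms.shape[0]
    elif B > 0:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(B)])
    else:
        perms = None

    if perms is not None and B > 0:
        exceed = np.zeros(len(dfs))
        for ix in perms:
            qp = q[ix]
            diag_p = np.einsum("ij,jk,ik->k", g, qp, qp, optimize=True)
            ss_p = _per_term_ss(diag_p, dfs)
            resid_p = total_ss - diag_p.sum()
            f_p = _pseudo_f(ss_p, dfs, resid_p, df_resid)
            exceed += f_p >= f_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + B)
        pvals = np.where(np.isfinite(f_obs), pvals, np.nan)
    else:
        pvals = np.full(len(dfs), np.nan)

    tbl = pd.DataFrame(
        {
            "df": dfs,
            "SS": term_ss,
            "R2": term_ss / total_ss if total_ss > 0 else np.nan,
            "F": f_obs,
            "p": pvals,
        },
        index=pd.Index(design.names(), name="term"),
    )
    return PermanovaResult(
        terms=tbl,
        residual_df=df_resid,
        residual_ss=float(resid_ss),
        total_ss=total_ss,
        n=n,
        B=B if perms is not None else 0,
        seed=seed,
        k=rank,
        dropped_samples=dropped,
    )


def _per_term_ss(diag: np.ndarray, dfs: list[int]) -> np.ndarray:
    out = np.empty(len(dfs))
    pos = 1  # skip intercept column
    for i, df in enumerate(dfs):
        out[i] = diag[pos : pos + df].sum()
        pos += df
    return out


def _pseudo_f(ss: np.ndarray, dfs: list[int], resid_ss: float, df_resid: int) -> np.ndarray:
    dfs_arr = np.asarray(dfs, dtype=float)
    ms_resid = resid_ss / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss / dfs_arr) / ms_resid
    f[dfs_arr == 0] = np.nan
    return f


def screen_variable(
    dm: DistanceMatrix,
    md: SampleMetadata,
    variable: str,
    confounders: list[str] = (),
    B: int = 999,
    seed: int | None = 0,
    scope: str = "*",
) -> PermanovaResult:
    """Confounder-adjusted single-variable PERMANOVA.

    Fits (confounders..., variable) and reports the variable's sequential R²
    and permutation p after adjustment.  Refuses variables marked excluded by
    metadata screening.
    """
    if variable in confounders:
        raise ValidationError(f"{variable!r} is itself a confounder")
    for sc in (scope, "*"):
        if (variable, sc) in md.exclusions:
            raise ValidationError(
                f"variable {variable!r} excluded in scope {sc}: {md.exclusions[(variable, sc)]}"
            )
    design = DesignSpec.from_names(list(confounders), [variable])
    return fit_permanova(dm, md, design, B=B, seed=seed)


# ---------------------------------------------------------------------------
# beta dispersion


def permdisp(
    dm: DistanceMatrix,
    md: SampleMetadata,
    variable: str,
    B: int = 999,
    seed: int | None = 0,
) -> DispersionResult:
    """Homogeneity-of-dispersion test around group centroids (PERMDISP).

    A full-rank PCoA of the distance matrix gives real coordinates for
    positive eigenvalues and imaginary ones for negative eigenvalues (the
    Bray–Curtis matrix is non-Euclidean).  The squared distance of a sample
    to its group centroid is the positive-axis contribution minus the
    negative-axis contribution, floored at zero before the square root.  A
    one-way F on these distances is tested by permuting group labels.
    """
    groups_all = md.table.reindex(dm.sample_ids)[variable]
    keep = groups_all.notna()
    warning = None
    sizes = groups_all[keep].astype(str).value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warning = f"dropped singleton level(s): {small}"
        logger.warning("permdisp: %s", warning)
        keep &= ~groups_all.astype(str).isin(small)
    samples = list(groups_all.index[keep])
    groups = groups_all[keep].astype(str)
    if groups.nunique() < 2:
        raise ValidationError("permdisp requires >= 2 non-empty groups")
    dmx = dm.select(samples)
    g = gower_center(dmx)
    w, v = np.linalg.eigh(g)
    # coordinates scaled by sqrt(|eigenvalue|); sign tracks the eigenvalue
    coords = v * np.sqrt(np.abs(w))
    pos = w > 1e-10 * max(abs(w).max(), 1.0)
    neg = w < -1e-10 * max(abs(w).max(), 1.0)

    z = _centroid_distances(coords, pos, neg, groups.to_numpy())
    gl = groups.to_numpy()
    F = _anova_f(z, gl)
    if not np.isfinite(F):
        warning = (warning + "; " if warning else "") + "degenerate dispersions (F undefined)"
        return DispersionResult(
            pd.Series(z, index=samples), groups, float("nan"), 1.0, 0, seed, warning
        )
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        Fp = _anova_f(z, gl[rng.permutation(len(gl))])
        if np.isfinite(Fp) and Fp >= F - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + B)
    return DispersionResult(pd.Series(z, index=samples), groups, float(F), float(p), B, seed, warning)


def _centroid_distances(
    coords: np.ndarray, pos: np.ndarray, neg: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    z = np.empty(len(groups))
    for lev in np.unique(groups):
        mask = groups == lev
        c = coords[mask].mean(axis=0)
        diff2 = (coords[mask] - c) ** 2
        d2 = diff2[:, pos].sum(axis=1) - diff2[:, neg].sum(axis=1)
        z[mask] = np.sqrt(np.clip(d2, 0.0, None))
    return z


def _anova_f(z: np.ndarray, groups: np.ndarray) -> float:
    grand = z.mean()
    ss_b = ss_w = 0.0
    k = 0
    for lev in np.unique(groups):
        zz = z[groups == lev]
        ss_b += len(zz) * (zz.mean() - grand) ** 2
        ss_w += ((zz - zz.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, len(z) - k
    if df_w <= 0 or ss_w <= 1e-300:
        return float("nan")
    return (ss_b / df_b) / (ss_w / df_w)


# ---------------------------------------------------------------------------
# within-batch similarity


def within_batch_similarity_test(
    dm: DistanceMatrix,
    md: SampleMetadata,
    batch_variable: str,
    stratum: tuple[str, str] | None = None,
    alternative: str = "two-sided",
) -> dict:
    """Compare within-batch vs between-batch pairwise community distances.

    Within the given (role, timepoint) stratum, the multiset of pairwise
    distances between samples sharing a batch label is compared with the
    between-batch pairs by an unpaired Wilcoxon rank-sum test.  A planted
    batch effect shows up as a lower within-batch median.
    """
    tbl = md.table.reindex(dm.sample_ids)
    mask = tbl[batch_variable].notna()
    if stratum is not None:
        role, tp = stratum
        mask &= (tbl["role"].astype(str) == role) & (tbl["timepoint"].astype(str) == tp)
    samples = list(tbl.index[mask])
    if len(samples) < 4:
        raise ValidationError("need >= 4 samples in stratum")
    batches = tbl.loc[samples, batch_variable].astype(str).to_numpy()
    sizes = pd.Series(batches).value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValidationError("need >= 2 batches with >= 2 samples")
    dmx = dm.select(samples)
    iu, ju = np.triu_indices(len(samples), k=1)
    same = batches[iu] == batches[ju]
    within = dmx.values[iu[same], ju[same]]
    between = dmx.values[iu[~same], ju[~same]]
    if within.size == 0:
        raise ValidationError("no within-batch pairs")
    stat, p = stats.mannwhitneyu(within, between, alternative=alternative)
    return {
        "statistic": float(stat),
        "p": float(p),
        "median_within": float(np.median(within)),
        "median_between": float(np.median(between)),
        "n_within_pairs": int(within.size),
        "n_between_pairs": int(between.size),
    }
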