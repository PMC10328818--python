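"""Per-taxon differential abundance with a model cascade and read offsets.

Each taxon passing a >10% prevalence filter is modelled individually as

    count ~ covariate (+ adjustment), offset = log(processed reads)

trying, in order: a negative-binomial log-linear model (MLE dispersion);
Poisson if the NB fit fails to converge or its dispersion sits at a
boundary; quasi-Poisson (Pearson-scaled standard errors) when the Poisson
fit is overdispersed (Pearson chi-squared / df > 1.5); and finally
generalised least squares on log relative abundance (with half the
minimum nonzero relative abundance as pseudo-abundance) if no count model
fits.  Coefficients are log fold-changes against the declared reference
level; p-values are Wald; BH-FDR is applied across taxa within one
covariate analysis and significance uses the dual rule p < 0.05 and
q < 0.1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .screen import bh_fdr
from .types import CountTable, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["prevalence_filter", "fit_da", "da_direction_table", "DATestResult"]

PREVALENCE_THRESHOLD = 0.10
OVERDISPERSION_LIMIT = 1.5
P_THRESHOLD = 0.05
Q_THRESHOLD = 0.1


def prevalence_filter(ct: CountTable, threshold: float = PREVALENCE_THRESHOLD) -> list[str]:
    """Taxa detected (count > 0) in strictly more than ``threshold`` of samples."""
    prev = (ct.counts > 0).mean(axis=1)
    return list(prev.index[prev > threshold])


@dataclass
class DATestResult:
    """Per-(taxon, contrast) differential-abundance table."""

    table: pd.DataFrame  # taxon, contrast, family, coef, se, p, q, prevalence, significant
    covariate: str
    reference: str | None
    adjust: str | None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].copy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fit_da(
    ct: CountTable,
    md: SampleMetadata,
    covariate: str,
    adjust: str | None = None,
    threshold: float = PREVALENCE_THRESHOLD,
    reference: str | None = None,
    min_n: int = 20,
    offset_var: str = "reads",
) -> DATestResult:
    """Run the NB -> Poisson -> quasi-Poisson -> GLS cascade for one covariate.

    ``adjust`` optionally names a batch (or other) variable entered as a
    nuisance term.  The offset is the per-sample processed-read count: the
    declared ``offset_var`` metadata variable when present, else the table's
    column sums.  Taxa failing every model are flagged ``unfit`` and
    excluded from the FDR family.
    """
    tbl = md.table.reindex(ct.sample_ids)
    needed = [covariate] + ([adjust] if adjust else [])
    ok = tbl[needed].notna().all(axis=1)
    samples = list(tbl.index[ok])
    if len(samples) < min_n:
        raise ValidationError(f"covariate {covariate!r}: only {len(samples)} complete samples")
    sub = ct.select_samples(samples)
    tbl = tbl.loc[samples]
    vdef = md.variables.get(covariate)
    if vdef is not None and vdef.kind == "numeric":
        if tbl[covariate].nunique() < 2:
            raise ValidationError(f"covariate {covariate!r} is constant")
    elif tbl[covariate].astype(str).nunique() < 2:
        raise ValidationError(f"covariate {covariate!r} is constant")

    x_cov, contrasts = _encode(tbl, covariate, vdef, reference)
    x_adj = None
    if adjust:
        x_adj, _ = _encode(tbl, adjust, md.variables.get(adjust), None)
    X = np.column_stack([np.ones(len(samples)), x_cov] + ([x_adj] if x_adj is not None else []))
    if offset_var in tbl.columns and pd.api.types.is_numeric_dtype(tbl[offset_var]):
        reads = tbl[offset_var].to_numpy(dtype=float)
    else:
        reads = sub.depths.to_numpy(dtype=float)
    log_reads = np.log(reads)

    taxa = prevalence_filter(sub, threshold)
    prev = (sub.counts > 0).mean(axis=1)
    rows = []
    for taxon in taxa:
        y = sub.counts.loc[taxon].to_numpy(dtype=float)
        fit = _cascade(y, X, log_reads, reads)
        for ci, cname in enumerate(contrasts):
            j = 1 + ci
            if fit is None:
                rows.append({"taxon": taxon, "contrast": cname, "family": "unfit",
                             "coef": np.nan, "se": np.nan, "p": np.nan,
                             "prevalence": float(prev[taxon])})
            else:
                family, coef, se = fit
                c, s = coef[j], se[j]
                p = 2.0 * stats.norm.sf(abs(c / s)) if s > 0 else (0.0 if c != 0 else 1.0)
                if s == 0 and c == 0:
                    p = 1.0
                rows.append({"taxon": taxon, "contrast": cname, "family": family,
                             "coef": float(c), "se": float(s), "p": float(p),
                             "prevalence": float(prev[taxon])})
    out = pd.DataFrame(rows, columns=["taxon", "contrast", "family", "coef", "se",
                                      "p", "prevalence"])
    out["q"] = np.nan
    for cname in contrasts:
        mask = (out["contrast"] == cname) & (out["family"] != "unfit")
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["significant"] = (out["p"] < P_THRESHOLD) & (out["q"] < Q_THRESHOLD)
    out["significant"] = out["significant"].fillna(False)
    ref = reference if reference is not None else (vdef.reference if vdef else None)
    return DATestResult(out, covariate, ref, adjust)


def _encode(tbl: pd.DataFrame, name: str, vdef, reference: str | None):
    col = tbl[name]
    if (vdef is not None and vdef.kind == "numeric") or (
        vdef is None and pd.api.types.is_numeric_dtype(col)
    ):
        return col.to_numpy(dtype=float)[:, None], [name]
    vals = col.astype(str)
    if vdef is not None and vdef.levels:
        levels = [l for l in vdef.levels if l in set(vals)]
    else:
        levels = sorted(set(vals))
    ref = reference or (vdef.reference if vdef and vdef.reference in levels else levels[0])
    others = [l for l in levels if l != ref]
    cols = np.column_stack([(vals == l).to_numpy(dtype=float) for l in others])
    return cols, [f"{name}[{l} vs {ref}]" for l in others]


def _cascade(y, X, log_reads, reads):
    """Try NB, then Poisson / quasi-Poisson, then GLS on log relabund.
    Returns (family, coef, se) or None."""
    nb = _fit_negbin(y, X, log_reads)
    if nb is not None:
        return nb
    pois = _fit_poisson(y, X, log_reads)
    if pois is not None:
        return pois
    return _fit_gls(y, X, reads)


def _fit_negbin(y, X, log_reads):
    if y.sum() == 0:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X, offset=log_reads)
            res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            return None
        alpha = float(res.params[-1])
        if not np.isfinite(alpha) or alpha < 1e-6 or alpha > 1e4:
            return None  # dispersion at boundary: fall back
        se = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(se[:-1])) or np.any(se[: X.shape[1]] > 1e3):
            return None
        return "NB", np.asarray(res.params[:-1], dtype=float), se[:-1]
    except Exception:
        return None


def _fit_poisson(y, X, log_reads):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Poisson(), offset=log_reads)
            res = model.fit()
        if res.df_resid <= 0:
            return None
        phi = float(res.pearson_chi2 / res.df_resid)
        if phi > OVERDISPERSION_LIMIT:
            qres = model.fit(scale="X2")  # quasi-Poisson: Pearson-scaled SEs
            se = np.asarray(qres.bse, dtype=float)
            if not np.all(np.isfinite(se)):
                return None
            return "quasi-Poisson", np.asarray(qres.params, dtype=float), se
        se = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(se)):
            return None
        return "Poisson", np.asarray(res.params, dtype=float), se
    except Exception:
        return None


def _fit_gls(y, X, reads):
    try:
        rel = y / reads
        nz = rel[rel > 0]
        pseudo = nz.min() / 2.0 if nz.size else 0.5 / reads.max()
        z = np.log(rel + pseudo)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.OLS(z, X).fit()
        se = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(se)):
            return None
        return "GLS", np.asarray(res.params, dtype=float), se
    except Exception:
        return None


def da_direction_table(results: dict[str, DATestResult]) -> pd.DataFrame:
    """Long signed summary across timepoints for heatmap rendering.

    One row per (taxon, timepoint, contrast) with ``direction`` =
    sign(coefficient) when significant, else 0, plus the fold-change.
    """
    rows = []
    for tp, res in sorted(results.items()):
        for _, r in res.table.iterrows():
            rows.append({
                "taxon": r["taxon"],
                "timepoint": tp,
                "contrast": r["contrast"],
                "direction": int(np.sign(r["coef"])) if bool(r["significant"]) else 0,
                "fold_change": float(np.exp(r["coef"])) if np.isfinite(r["coef"]) else np.nan,
            })
    return pd.DataFrame(rows, columns=["taxon", "timepoint", "contrast",
                                       "direction", "fold_change"])
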