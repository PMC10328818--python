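"""Per-timepoint covariate screening with FDR, interaction and stratified
screens, covariate-redundancy diagnostics, and family-dyad distance tests.

The screening convention throughout: a variable's effect on community
composition is its sequential PERMANOVA R² after the technical confounders;
p-values are permutation p-values, corrected by Benjamini–Hochberg within
the variable family of one timepoint, and a finding is significant under the
dual rule p < 0.05 AND q < 0.1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .permanova import DesignSpec, PermanovaResult, Term, fit_permanova, permdisp, screen_variable
from .types import DistanceMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "bh_fdr",
    "ScreenReport",
    "screen_all",
    "screen_interaction",
    "stratified_screen",
    "symmetric_uncertainty",
    "spearman_matrix",
    "family_dyad_analysis",
]

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.1


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class ScreenReport:
    """Long-format screening table: one row per (timepoint, variable)."""

    table: pd.DataFrame
    B: int
    seed: int | None = None

    COLUMNS = ("timepoint", "variable", "df", "SS", "R2", "F", "p", "q",
               "significant", "dispersion_p", "dispersion_uneven", "n")

    def significant_findings(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].copy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def screen_all(
    dms: dict[str, DistanceMatrix],
    md: SampleMetadata,
    variables: list[str],
    confounders: list[str] = (),
    B: int = 999,
    seed: int | None = 0,
    run_dispersion: bool = True,
) -> ScreenReport:
    """Screen each variable at each timepoint, with per-timepoint BH-FDR.

    ``dms`` maps timepoint label to that timepoint's distance matrix.  For
    every (timepoint, variable) the confounder-adjusted sequential R² and
    permutation p are recorded; BH-FDR is applied within each timepoint's
    variable family, and categorical variables additionally get a
    beta-dispersion flag.
    """
    rows = []
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    for ti, (tp, dm) in enumerate(sorted(dms.items())):
        tp_rows = []
        for vi, var in enumerate(variables):
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            try:
                res = screen_variable(dm, md, var, confounders, B=B, seed=sub_seed,
                                      scope=_scope_for(md, dm, tp))
            except ValidationError as e:
                logger.info("screen_all: skipped %s at %s (%s)", var, tp, e)
                continue
            row = {
                "timepoint": tp,
                "variable": var,
                "df": int(res.terms.loc[var, "df"]),
                "SS": res.terms.loc[var, "SS"],
                "R2": res.terms.loc[var, "R2"],
                "F": res.terms.loc[var, "F"],
                "p": res.terms.loc[var, "p"],
                "n": res.n,
                "dispersion_p": np.nan,
                "dispersion_uneven": False,
            }
            vdef = md.variables.get(var)
            if run_dispersion and (vdef is None or vdef.kind == "categorical"):
                try:
                    disp = permdisp(dm, md, var, B=B, seed=sub_seed)
                    row["dispersion_p"] = disp.p
                    row["dispersion_uneven"] = disp.uneven
                except ValidationError:
                    pass
            tp_rows.append(row)
        if tp_rows:
            sub = pd.DataFrame(tp_rows)
            sub["q"] = bh_fdr(sub["p"].to_numpy())
            sub["significant"] = (sub["p"] < P_THRESHOLD) & (sub["q"] < Q_THRESHOLD)
            rows.append(sub)
    table = (
        pd.concat(rows, ignore_index=True)[list(ScreenReport.COLUMNS)]
        if rows
        else pd.DataFrame(columns=list(ScreenReport.COLUMNS))
    )
    return ScreenReport(table, B, seed)


def _scope_for(md: SampleMetadata, dm: DistanceMatrix, tp: str) -> str:
    roles = md.table.reindex(dm.sample_ids)["role"].dropna().astype(str).unique()
    role = roles[0] if len(roles) == 1 else "*"
    return f"{role}:{tp}"


def screen_interaction(
    dm: DistanceMatrix,
    md: SampleMetadata,
    var1: str,
    var2: str,
    confounders: list[str] = (),
    B: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Test a two-way interaction after confounders and both main effects.

    Fits (confounders..., var1, var2, var1:var2); the interaction's
    sequential p and R² decide its admission to the cumulative-model
    candidate set (p < 0.05).  An interaction fully aliased by its mains
    (df 0) is refused.
    """
    terms = [Term((c,), "confounder") for c in confounders]
    terms += [Term((var1,)), Term((var2,)), Term((var1, var2))]
    res = fit_permanova(dm, md, DesignSpec(terms), B=B, seed=seed)
    iname = f"{var1}:{var2}"
    if res.terms.loc[iname, "df"] == 0:
        raise ValidationError(f"interaction {iname} aliased (df 0)")
    return res


def stratified_screen(
    dm: DistanceMatrix,
    md: SampleMetadata,
    variable: str,
    stratifier: str,
    confounders: list[str] = (),
    B: int = 999,
    seed: int | None = 0,
    min_extra: int = 5,
) -> dict[str, PermanovaResult | None]:
    """Run the confounder-adjusted screen separately within each stratum.

    Strata with fewer samples than (model df + ``min_extra``) are skipped
    with a log entry (recorded as None).  Raw per-stratum p-values are
    reported without cross-stratum FDR.
    """
    strat = md.table.reindex(dm.sample_ids)[stratifier]
    out: dict[str, PermanovaResult | None] = {}
    for lev in sorted(strat.dropna().astype(str).unique()):
        samples = [s for s in dm.sample_ids if str(strat.get(s)) == lev]
        sub_dm = dm.select(samples)
        try:
            out[lev] = screen_variable(sub_dm, md, variable, confounders, B=B, seed=seed)
        except ValidationError as e:
            logger.info("stratified_screen: stratum %s skipped (%s)", lev, e)
            out[lev] = None
            continue
        res = out[lev]
        if res is not None and res.n < (res.k - 1) + min_extra:
            logger.info("stratified_screen: stratum %s under-sized (n=%d)", lev, res.n)
    return out


# ---------------------------------------------------------------------------
# covariate redundancy


def symmetric_uncertainty(
    var1, var2, md: SampleMetadata | None = None, bins: int | None = None
) -> float:
    """Normalised mutual information 2·MI / (H1 + H2) between two variables.

    Numeric variables are discretised to equal-frequency bins (default
    ``ceil(n^(1/3))``); entropies and mutual information are plug-in
    estimates in nats.  Returns NaN when either variable is constant
    (zero entropy).  SU(X, X) = 1; SU = 0 iff the empirical MI is 0.
    """
    x = _as_series(var1, md)
    y = _as_series(var2, md)
    ok = x.notna() & y.notna()
    if ok.sum() < 10:
        raise ValidationError("need >= 10 pairwise-complete observations")
    x, y = x[ok], y[ok]
    n = len(x)
    nb = bins if bins is not None else math.ceil(n ** (1.0 / 3.0))
    xd = _discretize(x, nb)
    yd = _discretize(y, nb)
    ct = pd.crosstab(xd, yd).to_numpy(dtype=float)
    pxy = ct / ct.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = _entropy(px)
    hy = _entropy(py)
    if hx == 0 or hy == 0:
        return float("nan")  # constant variable: SU undefined
    mi = hx + hy - _entropy(pxy.ravel())
    return float(max(0.0, 2.0 * mi / (hx + hy)))


def _as_series(v, md: SampleMetadata | None) -> pd.Series:
    if isinstance(v, str):
        if md is None:
            raise ValidationError("variable names require metadata")
        return md.table[v]
    return pd.Series(v)


def _discretize(s: pd.Series, bins: int) -> pd.Series:
    if pd.api.types.is_numeric_dtype(s) and s.nunique() > bins:
        return pd.qcut(s, q=bins, duplicates="drop").astype(str)
    return s.astype(str)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def spearman_matrix(
    md: SampleMetadata, variables: list[str], fair_cutoff: float = 0.3
) -> pd.DataFrame:
    """Pairwise Spearman correlations with a "fair" flag at |rho| > 0.3.

    Long-format table (var1, var2, rho, n, fair) over pairwise-complete
    observations; the cutoff is strict, so rho = 0.3 exactly is not flagged.
    """
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            sub = md.table[[a, b]].dropna()
            if len(sub) < 3:
                continue
            rho, _ = stats.spearmanr(sub[a], sub[b])
            rows.append(
                {"var1": a, "var2": b, "rho": float(rho), "n": len(sub),
                 "fair": bool(abs(rho) > fair_cutoff)}
            )
    return pd.DataFrame(rows, columns=["var1", "var2", "rho", "n", "fair"])


# ---------------------------------------------------------------------------
# family dyads


def family_dyad_analysis(
    dm: DistanceMatrix,
    md: SampleMetadata,
    dyad: str = "mother-infant",
    timepoint: str | None = None,
    alternative: str = "two-sided",
) -> dict:
    """Compare within-family dyad distances against between-family pairs.

    For ``mother-infant`` at a given infant timepoint, the within set holds
    each family's infant-to-own-mother distance and the between set pairs
    every infant with every *other* family's mother.  An unpaired Wilcoxon
    rank-sum test compares the two multisets.
    """
    role_a, role_b = dyad.split("-")
    tbl = md.table.reindex(dm.sample_ids)
    a_samples = _role_samples(tbl, role_a, timepoint if role_a == "infant" else None)
    b_samples = _role_samples(tbl, role_b, timepoint if role_b == "infant" else None)
    fam_a = {tbl.loc[s, "family_id"]: s for s in a_samples}
    fam_b = {tbl.loc[s, "family_id"]: s for s in b_samples}
    shared = sorted(set(fam_a) & set(fam_b))
    if len(shared) < 5:
        raise ValidationError(f"need >= 5 complete {dyad} dyads, have {len(shared)}")
    pos = {s: i for i, s in enumerate(dm.sample_ids)}
    within, between = [], []
    for fa in shared:
        ia = pos[fam_a[fa]]
        for fb in shared:
            d = dm.values[ia, pos[fam_b[fb]]]
            (within if fa == fb else between).append(d)
    stat, p = stats.mannwhitneyu(within, between, alternative=alternative)
    return {
        "dyad": dyad,
        "timepoint": timepoint,
        "statistic": float(stat),
        "p": float(p),
        "median_within": float(np.median(within)),
        "median_between": float(np.median(between)),
        "n_families": len(shared),
        "n_within": len(within),
        "n_between": len(between),
    }


def _role_samples(tbl: pd.DataFrame, role: str, timepoint: str | None) -> list[str]:
    mask = tbl["role"].astype(str) == role
    if timepoint is not None:
        mask &= tbl["timepoint"].astype(str) == str(timepoint)
    # one sample per family per role/timepoint: keep the first
    sub = tbl[mask]
    return list(sub.groupby("family_id", sort=False).head(1).index)
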