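"""Synthetic longitudinal infant-cohort generator with planted effects.

The generator emulates the statistical structure the downstream analyses
assume: a birth cohort of families, each infant sampled at up to eight
timepoints (3 weeks to 24 months) plus parental spot samples around
delivery, with genus-level compositions drawn from an overdispersed
Dirichlet-multinomial model.

For each retained subject x timepoint, the taxon log-abundance is

    eta = baseline(taxon, age) + subject intercept + family intercept
          + sum of planted covariate effects + batch effect

followed by softmax to proportions, a Dirichlet perturbation with the
configured concentration, and a multinomial draw at a log-normal read depth.
Covariates are drawn with realistic dependence: every C-section birth
involves intrapartum antibiotics, parity and the older-siblings indicator
are nearly collinear, and defecation frequency is age-dependent.  Planted
effects come in named variance tiers (none / small ~0.5% / medium ~2% /
large ~6% Bray-Curtis PERMANOVA R-squared); their log-fold-change
magnitudes were fixed once by Monte-Carlo calibration with
:func:`expected_r2`.

Cohort-shape defaults mirror a large Finnish birth cohort: C-section rate
0.163, intrapartum antibiotics in 23.3% of vaginal deliveries, 49%
first-borns, median sequencing depth 16.8k reads, roughly 78 samples per
DNA-extraction batch, and mother/father spot-sample inclusion rates of
0.73/0.57.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distances import bray_curtis
from .diversity import relative_abundance
from .permanova import DesignSpec, fit_permanova
from .types import CountTable, SampleMetadata, ValidationError, VariableDef

__all__ = [
    "GeneratorConfig",
    "EffectSpec",
    "SyntheticTruth",
    "simulate_cohort",
    "expected_r2",
    "demo_truth",
    "tier_truth",
    "TIER_LFC",
    "TIER_TAXA",
]

#: log-fold-change magnitude per variance tier, fixed once by Monte-Carlo
#: calibration (expected_r2 on the canonical tier taxa below) so that the
#: induced Bray-Curtis PERMANOVA R-squared lands near 0.5% / 2% / 6%
TIER_LFC = {"none": 0.0, "small": 0.5, "medium": 0.9, "large": 1.1}

#: disjoint trajectory-balanced taxon triples per tier; each mixes
#: early-abundant, late-abundant and stable genera so the induced
#: R-squared stays comparable across timepoints
TIER_TAXA = {
    "none": ("Prevotella", "Akkermansia", "Lactobacillus"),
    "small": ("Veillonella", "Blautia", "Lactobacillus"),
    "medium": ("Streptococcus", "Ruminococcus", "Clostridium"),
    "large": ("Escherichia", "Faecalibacterium", "Bacteroides"),
}

TIMEPOINT_AGE = {"3w": 0.75, "6w": 1.5, "3m": 3.0, "6m": 6.0,
                 "9m": 9.0, "12m": 12.0, "18m": 18.0, "24m": 24.0}

# (genus, family, early log-abundance, late log-abundance, adult log-abundance)
_NAMED_PROFILE = [
    ("Bifidobacterium", "Bifidobacteriaceae", 4.5, 2.5, 2.0),
    ("Bacteroides", "Bacteroidaceae", 1.5, 3.5, 3.8),
    ("Escherichia", "Enterobacteriaceae", 3.0, 1.0, 0.0),
    ("Blautia", "Lachnospiraceae", 0.5, 2.5, 3.0),
    ("Faecalibacterium", "Ruminococcaceae", -0.5, 2.5, 3.5),
    ("Veillonella", "Veillonellaceae", 2.0, 1.0, 0.5),
    ("Streptococcus", "Streptococcaceae", 2.0, 1.2, 1.0),
    ("Lactobacillus", "Lactobacillaceae", 1.0, 0.5, 0.5),
    ("Clostridium", "Clostridiaceae", 0.5, 1.5, 1.5),
    ("Akkermansia", "Akkermansiaceae", -1.0, 1.0, 1.5),
    ("Ruminococcus", "Oscillospiraceae", -0.5, 1.8, 2.5),
    ("Prevotella", "Prevotellaceae", -1.0, 0.5, 1.5),
]

_FILLER_FAMILIES = ["Lachnospiraceae", "Oscillospiraceae", "Erysipelotrichaceae",
                    "Eggerthellaceae", "Sutterellaceae", "Tannerellaceae"]


@dataclass
class GeneratorConfig:
    """Cohort-shape and noise parameters of the simulator."""

    n_families: int = 300
    timepoints: tuple[str, ...] = ("3w", "6w", "3m", "6m", "9m", "12m", "18m", "24m")
    n_taxa: int = 60
    concentration: float = 60.0       # Dirichlet overdispersion (larger = less noise)
    depth_median: float = 16800.0     # median reads per sample
    depth_sigma: float = 0.45         # log-normal sigma of read depth
    fixed_depth: int | None = None    # overrides the log-normal draw (noise-free depth)
    missing_visit_prob: float = 0.25  # ~6 of 8 infant visits retained on average
    p_mother: float = 0.73
    p_father: float = 0.57
    batch_size: int = 78              # samples per DNA-extraction batch
    n_platforms: int = 2
    n_extractors: int = 5
    cs_prob: float = 0.163
    iap_given_vd: float = 0.233
    firstborn_prob: float = 0.49
    sibling_flip_prob: float = 0.02   # parity vs older-siblings near-collinearity
    unknown_frac: float = 0.0         # fraction of reads diverted to an unknown taxon
    extra_binary_vars: tuple[str, ...] = ()  # iid balanced per-family yes/no covariates
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.missing_visit_prob, self.p_mother, self.p_father,
                  self.cs_prob, self.iap_given_vd, self.firstborn_prob,
                  self.sibling_flip_prob, self.unknown_frac):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")
        if len(self.timepoints) < 2:
            raise ValidationError("need at least 2 timepoints")
        bad = set(self.timepoints) - set(TIMEPOINT_AGE)
        if bad:
            raise ValidationError(f"unknown timepoints {sorted(bad)}")


@dataclass(frozen=True)
class EffectSpec:
    """One planted covariate effect.

    For a categorical variable the effect applies to samples at ``level``
    (indicator coding); for a numeric variable (``level=None``) the
    standardised value multiplies the log-fold-change.  ``timepoints=None``
    means the effect is present at every infant timepoint; otherwise it is
    restricted to the listed ones.
    """

    variable: str
    taxa: tuple[str, ...]
    tier: str = "medium"
    level: str | None = None
    sign: int = 1
    lfc: float | None = None
    timepoints: tuple[str, ...] | None = None

    @property
    def magnitude(self) -> float:
        base = TIER_LFC[self.tier] if self.lfc is None else self.lfc
        return self.sign * base


@dataclass
class SyntheticTruth:
    """Planted-effect descriptors plus noise scales; augmented after
    simulation with the realised per-covariate design columns."""

    effects: list[EffectSpec] = field(default_factory=list)
    subject_sd: float = 0.7
    family_sd: float = 0.0     # parent-infant shared component (dyad similarity)
    batch_sd: float = 0.0      # multiplicative batch effect scale (log units)
    batch_taxon_frac: float = 0.2
    seed: int | None = None
    realized: dict = field(default_factory=dict)

    def tiers(self) -> dict[str, str]:
        return {e.variable: e.tier for e in self.effects}


def demo_truth(batch_tier: str = "large", delivery_tier: str = "medium",
               sibling_tier: str = "small", stool_tier: str = "small") -> SyntheticTruth:
    """Packaged demonstration truth: extraction-batch, delivery, older-sibling
    and stool-consistency effects in decreasing order of magnitude."""
    eff = []
    if delivery_tier != "none":
        eff.append(EffectSpec("delivery3", ("Bacteroides", "Bifidobacterium", "Prevotella"),
                              delivery_tier, level="CS+AB", sign=-1))
    if sibling_tier != "none":
        # stable mid-abundance taxa keep the sibling effect at its small tier
        eff.append(EffectSpec("older_siblings", TIER_TAXA["small"],
                              sibling_tier, level="yes"))
    if stool_tier != "none":
        eff.append(EffectSpec("stool_consistency",
                              ("Faecalibacterium", "Ruminococcus", "Akkermansia"),
                              stool_tier, level=None))
    batch_sd = {"none": 0.0, "small": 0.25, "medium": 0.5, "large": 1.2}[batch_tier]
    return SyntheticTruth(effects=eff, subject_sd=0.7, batch_sd=batch_sd)


def tier_truth(timepoints: tuple[str, ...] | None = None) -> tuple[SyntheticTruth, tuple[str, ...]]:
    """Canonical tier experiment: four independent balanced binary covariates
    planted at tiers none/small/medium/large on disjoint trajectory-balanced
    taxa triples.  Returns the truth and the extra binary variable names to
    pass to GeneratorConfig."""
    names = ("tier_none", "tier_small", "tier_medium", "tier_large")
    effects = [
        EffectSpec(n, TIER_TAXA[n.split("_")[1]], tier=n.split("_")[1],
                   level="yes", timepoints=timepoints)
        for n in names
    ]
    return SyntheticTruth(effects=effects, subject_sd=0.7, batch_sd=0.0), names


# ---------------------------------------------------------------------------


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _baseline_profile(cfg: GeneratorConfig, rng: np.random.Generator):
    """Taxon ids plus (early, late, adult) log-abundance vectors."""
    named = _NAMED_PROFILE[: min(len(_NAMED_PROFILE), cfg.n_taxa)]
    taxon_ids = [f"{fam};{gen}" for gen, fam, *_ in named]
    early = [e for _g, _f, e, _l, _a in named]
    late = [l for _g, _f, _e, l, _a in named]
    adult = [a for _g, _f, _e, _l, a in named]
    n_fill = cfg.n_taxa - len(named)
    for i in range(n_fill):
        fam = _FILLER_FAMILIES[i % len(_FILLER_FAMILIES)]
        taxon_ids.append(f"{fam};Genus_{i + 1:02d}")
        base = float(rng.normal(-0.5, 1.0))
        drift = float(rng.normal(0.0, 0.4))
        early.append(base)
        late.append(base + drift)
        adult.append(base + drift + float(rng.normal(0.0, 0.3)))
    return taxon_ids, np.array(early), np.array(late), np.array(adult)


def _age_logmean(early: np.ndarray, late: np.ndarray, age_months: float) -> np.ndarray:
    lo, hi = np.log(0.75), np.log(24.0)
    w = float(np.clip((np.log(age_months) - lo) / (hi - lo), 0.0, 1.0))
    return (1.0 - w) * early + w * late


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-family covariates with the declared dependence structure."""
    n = cfg.n_families
    cs = rng.random(n) < cfg.cs_prob
    iap = np.where(cs, True, rng.random(n) < cfg.iap_given_vd)
    parity_extra = rng.choice([1, 2, 3], size=n, p=[0.70, 0.20, 0.10])
    parity = np.where(rng.random(n) < cfg.firstborn_prob, 1, 1 + parity_extra)
    sib = parity > 1
    flip = rng.random(n) < cfg.sibling_flip_prob
    sib = np.where(flip, ~sib, sib)
    bf_months = np.clip(rng.normal(9.0, 4.0, n), 0.0, 24.0)
    out = pd.DataFrame(
        {
            "delivery_mode": np.where(cs, "CS", "VD"),
            "intrapartum_antibiotics": np.where(iap, "yes", "no"),
            "delivery3": np.where(cs, "CS+AB", np.where(iap, "VD+AB", "VD-AB")),
            "parity": np.where(parity == 1, "1", np.where(parity == 2, "2", "3+")),
            "older_siblings": np.where(sib, "yes", "no"),
            "bf_months": bf_months,
        },
        index=[f"F{i:04d}" for i in range(n)],
    )
    for name in cfg.extra_binary_vars:
        out[name] = np.where(rng.random(n) < 0.5, "yes", "no")
    return out


def _defecation_level(age: float, u: float) -> str:
    p_high = float(np.clip(0.75 - 0.03 * age, 0.05, 1.0))
    p_mid = 0.2 if age < 12 else 0.35
    if u < p_high:
        return "high"
    if u < p_high + p_mid:
        return "mid"
    return "low"


def simulate_cohort(
    cfg: GeneratorConfig, truth: SyntheticTruth
) -> tuple[CountTable, SampleMetadata, SyntheticTruth]:
    """Draw one synthetic cohort; deterministic under ``cfg.seed``.

    Returns the count table, metadata (with declared variable types and the
    two technical confounders flagged), and the truth augmented with the
    realised per-covariate design columns.
    """
    rngs = _substreams(cfg.seed, ["profile", "covariates", "visits", "composition",
                                  "depths", "batch"])
    taxon_ids, early, late, adult = _baseline_profile(cfg, rngs["profile"])
    n_taxa = len(taxon_ids)
    fam = _draw_covariates(cfg, rngs["covariates"])
    families = list(fam.index)

    # visit schedule: infants at each timepoint w.p. 1 - missing_visit_prob,
    # parents once around delivery
    rv = rngs["visits"]
    sample_rows = []
    for fid in families:
        for tp in cfg.timepoints:
            if rv.random() >= cfg.missing_visit_prob:
                sample_rows.append((fid, "infant", tp))
        if rv.random() < cfg.p_mother:
            sample_rows.append((fid, "mother", "parental"))
        if rv.random() < cfg.p_father:
            sample_rows.append((fid, "father", "parental"))

    # extraction batches follow collection order (timepoint-major), so batch,
    # platform and extractor are interlinked with sampling age
    order = {tp: i for i, tp in enumerate(list(cfg.timepoints) + ["parental"])}
    sample_rows.sort(key=lambda r: (order[r[2]], r[0], r[1]))
    n_samples = len(sample_rows)
    n_batches = max(1, int(np.ceil(n_samples / cfg.batch_size)))
    batch_of = np.arange(n_samples) // cfg.batch_size

    rb = rngs["batch"]
    n_affected = max(1, int(round(truth.batch_taxon_frac * n_taxa)))
    batch_eff = np.zeros((n_batches, n_taxa))
    if truth.batch_sd > 0:
        for b in range(n_batches):
            affected = rb.choice(n_taxa, size=n_affected, replace=False)
            batch_eff[b, affected] = rb.normal(0.0, truth.batch_sd, n_affected)

    rc = rngs["composition"]
    u_subject: dict[str, np.ndarray] = {}
    u_family: dict[str, np.ndarray] = {}
    for fid in families:
        u_family[fid] = (rc.normal(0.0, truth.family_sd, n_taxa)
                         if truth.family_sd > 0 else np.zeros(n_taxa))
        for role in ("infant", "mother", "father"):
            u_subject[f"{fid}-{role}"] = rc.normal(0.0, truth.subject_sd, n_taxa)

    # per-sample covariate values and planted-effect design columns
    taxon_pos = {t.split(";")[1]: i for i, t in enumerate(taxon_ids)}
    for t in taxon_ids:
        taxon_pos.setdefault(t, taxon_ids.index(t))
    for e in truth.effects:
        missing = [t for t in e.taxa if t not in taxon_pos]
        if missing:
            raise ValidationError(f"planted effect {e.variable}: unknown taxa {missing}")

    rd = rngs["depths"]
    meta_rows = []
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    sample_ids = []
    stool_mean = {tp: 6.0 - 0.09 * TIMEPOINT_AGE.get(tp, 0.0) for tp in cfg.timepoints}
    x_numeric_cache: dict[str, float] = {}

    for idx, (fid, role, tp) in enumerate(sample_rows):
        sid = f"{fid}-{role}" + (f"-{tp}" if role == "infant" else "")
        sample_ids.append(sid)
        age = TIMEPOINT_AGE.get(tp)
        if role == "infant":
            base = _age_logmean(early, late, age)
        else:
            base = adult.copy()
        eta = base + u_subject[f"{fid}-{role}"] + u_family[fid]
        eta = eta + batch_eff[batch_of[idx]]

        stool = (float(np.clip(rc.normal(stool_mean[tp], 1.2), 1.0, 7.0))
                 if role == "infant" else float(np.clip(rc.normal(4.0, 1.2), 1.0, 7.0)))
        defec = _defecation_level(age, rc.random()) if role == "infant" else None
        bf = ("yes" if age < fam.loc[fid, "bf_months"] else "no") if role == "infant" else None

        row = {
            "sample_id": sid,
            "subject_id": f"{fid}-{role}",
            "family_id": fid,
            "role": role,
            "timepoint": tp,
            "extraction_batch": f"B{batch_of[idx]:03d}",
            "platform": "P1" if batch_of[idx] < 0.6 * n_batches else "P2",
            "extractor": f"E{batch_of[idx] % cfg.n_extractors}",
            "stool_consistency": stool,
            "defecation_freq": defec,
            "breastfeeding": bf,
            "dna_yield": float(np.exp(rc.normal(3.0, 0.6))),
        }
        for c in ("delivery_mode", "intrapartum_antibiotics", "delivery3",
                  "parity", "older_siblings", *cfg.extra_binary_vars):
            row[c] = fam.loc[fid, c] if role == "infant" else None
        meta_rows.append(row)

        if role == "infant":
            for e in truth.effects:
                if e.timepoints is not None and tp not in e.timepoints:
                    continue
                x = _effect_x(e, row, fam.loc[fid])
                if x:
                    for t in e.taxa:
                        eta[taxon_pos[t]] += e.magnitude * x

        p = np.exp(eta - eta.max())
        p /= p.sum()
        p = rc.dirichlet(cfg.concentration * p)
        p = np.clip(p, 1e-12, None)
        p /= p.sum()
        if cfg.fixed_depth is not None:
            depth = int(cfg.fixed_depth)
        else:
            depth = int(np.round(np.exp(rd.normal(np.log(cfg.depth_median), cfg.depth_sigma))))
            depth = max(depth, 1000)
        counts[:, idx] = rc.multinomial(depth, p)

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    ct_counts = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)

    if cfg.unknown_frac > 0:
        unk = np.zeros(n_samples, dtype=np.int64)
        for j in range(n_samples):
            total = ct_counts.iloc[:, j].sum()
            unk[j] = rd.binomial(total, cfg.unknown_frac)
        ct_counts.loc["unknown;unknown"] = unk
    ranks = pd.Series(
        ["genus" if t != "unknown;unknown" else "unknown" for t in ct_counts.index],
        index=ct_counts.index,
    )
    ct = CountTable(ct_counts, ranks)

    meta["reads"] = ct.depths.reindex(meta.index).astype(float)
    variables = _variable_defs()
    for name in cfg.extra_binary_vars:
        variables[name] = VariableDef(name, "categorical", levels=("no", "yes"),
                                      reference="no")
    md = SampleMetadata(meta, variables)

    realized = {}
    infant_mask = meta["role"] == "infant"
    for e in truth.effects:
        realized[e.variable] = meta.loc[infant_mask, e.variable].copy()
    realized["extraction_batch"] = meta["extraction_batch"].copy()
    out_truth = replace(truth, seed=cfg.seed, realized=realized)
    return ct, md, out_truth


def _effect_x(e: EffectSpec, row: dict, fam_row: pd.Series) -> float:
    val = row.get(e.variable, fam_row.get(e.variable))
    if val is None:
        return 0.0
    if e.level is not None:
        return 1.0 if str(val) == e.level else 0.0
    # numeric covariate: center/scale by the generative distribution
    if e.variable == "stool_consistency":
        return (float(val) - 5.0) / 1.2
    return float(val)


def _variable_defs() -> dict[str, VariableDef]:
    v = {
        "delivery_mode": VariableDef("delivery_mode", "categorical",
                                     levels=("VD", "CS"), reference="VD"),
        "intrapartum_antibiotics": VariableDef("intrapartum_antibiotics", "categorical",
                                               levels=("no", "yes"), reference="no"),
        "delivery3": VariableDef("delivery3", "categorical",
                                 levels=("VD-AB", "VD+AB", "CS+AB"), reference="VD-AB"),
        "parity": VariableDef("parity", "categorical",
                              levels=("1", "2", "3+"), reference="1"),
        "older_siblings": VariableDef("older_siblings", "categorical",
                                      levels=("no", "yes"), reference="no"),
        "breastfeeding": VariableDef("breastfeeding", "categorical",
                                     levels=("no", "yes"), reference="no"),
        "defecation_freq": VariableDef("defecation_freq", "categorical",
                                       levels=("low", "mid", "high"), reference="low"),
        "stool_consistency": VariableDef("stool_consistency", "numeric"),
        "dna_yield": VariableDef("dna_yield", "numeric", role="technical"),
        "extraction_batch": VariableDef("extraction_batch", "categorical", role="confounder"),
        "platform": VariableDef("platform", "categorical", role="technical",
                                levels=("P1", "P2"), reference="P1"),
        "extractor": VariableDef("extractor", "categorical", role="technical"),
        "reads": VariableDef("reads", "numeric", role="confounder"),
    }
    return v


# ---------------------------------------------------------------------------


def expected_r2(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    n_mc: int = 300,
    replicates: int = 1,
    timepoints: tuple[str, ...] | None = None,
    adjust_confounders: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo estimate of the Bray-Curtis PERMANOVA R-squared each
    planted effect induces at each timepoint.

    Simulates a cohort of ``n_mc`` families at a large fixed read depth
    (suppressing sampling noise from sequencing) and runs the engine with
    B=0 (no permutations; only R-squared is needed).  With ``replicates>1``
    the seed is advanced per replicate and the mean and SD across replicates
    are returned (columns ``R2`` and ``R2_sd``).
    """
    cfg = replace(cfg, n_families=n_mc, fixed_depth=cfg.fixed_depth or 100_000)
    rows = []
    for r in range(replicates):
        ct, md, tr = simulate_cohort(replace(cfg, seed=cfg.seed + r), truth)
        genus = _genus_table(ct)
        tps = timepoints or cfg.timepoints
        for tp in tps:
            samples = [s for s in genus.sample_ids
                       if md.table.loc[s, "role"] == "infant"
                       and md.table.loc[s, "timepoint"] == tp]
            sub = genus.select_samples(samples)
            dm = bray_curtis(relative_abundance(sub))
            variables = [e.variable for e in truth.effects]
            if truth.batch_sd > 0:
                variables.append("extraction_batch")
            for var in variables:
                conf = ["extraction_batch", "reads"] if adjust_confounders else []
                if var in conf:
                    conf = []
                design = DesignSpec.from_names(conf, [var])
                res = fit_permanova(dm, md, design, B=0)
                rows.append({"replicate": r, "timepoint": tp, "variable": var,
                             "R2": res.r2(var), "n": res.n})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["variable", "timepoint"])
        .agg(R2=("R2", "mean"), R2_sd=("R2", "std"), n=("n", "mean"))
        .reset_index()
    )
    return out


def _genus_table(ct: CountTable) -> CountTable:
    from .diversity import aggregate

    return aggregate(ct, "genus")
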