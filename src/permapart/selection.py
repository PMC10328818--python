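"""Cumulative distance-model construction by AICc backward elimination.

The cumulative per-timepoint model starts from all screened-in candidate
terms (plus admitted interactions) behind the fixed technical confounders,
and removes one term at a time.  Model quality is scored by the
small-sample-corrected Akaike criterion applied to the distance model's
residual sum of squares,

    AICc = 2k + n * ln(RSS / n) + 2k(k + 1) / (n - k - 1),

with k the design-matrix rank including the intercept, n the number of
samples and RSS the residual SS of the sequential decomposition.  A removal
is accepted only when it lowers AICc by at least 2 units; elimination stops
when no single removal achieves that.  Confounders are never droppable, and
an interaction must leave the model before either of its main effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .permanova import DesignSpec, PermanovaResult, Term, fit_permanova
from .types import DistanceMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["aicc", "backward_select", "pooled_model", "ModelSelectionTrace"]

MIN_IMPROVEMENT = 2.0


def aicc(n: int, k: int, rss: float, literal: bool = False) -> float:
    """Small-sample-corrected AIC for a least-squares model.

    Default: ``2k + n*ln(rss/n) + 2k(k+1)/(n-k-1)``.  ``literal=True``
    selects the variant ``2k + n + ln(rss/n) + 2k(k+1)/(n-k-1)`` in which the
    sample-size term enters additively rather than scaling the log-RSS; the
    default is used for selection because the additive variant is nearly
    insensitive to fit quality.
    """
    if n <= k + 1:
        raise ValidationError(f"AICc undefined: n={n} <= k+1={k + 1}")
    if rss <= 0:
        raise ValidationError("AICc requires rss > 0")
    corr = 2.0 * k * (k + 1) / (n - k - 1)
    if literal:
        return 2.0 * k + n + np.log(rss / n) + corr
    return 2.0 * k + n * np.log(rss / n) + corr


@dataclass
class SelectionStep:
    terms: tuple[str, ...]
    k: int
    n: int
    rss: float
    aicc: float
    action: str  # "start" | "drop <term>" | "stop"


@dataclass
class ModelSelectionTrace:
    """Replayable record of one backward-elimination run."""

    steps: list[SelectionStep]
    final: PermanovaResult
    confounders: tuple[str, ...]
    literal_aicc: bool = False
    dropped: list[str] = field(default_factory=list)

    @property
    def final_terms(self) -> list[str]:
        return list(self.steps[-1].terms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": i, "terms": "+".join(s.terms), "k": s.k, "n": s.n,
                 "rss": s.rss, "aicc": s.aicc, "action": s.action}
                for i, s in enumerate(self.steps)
            ]
        )

    def replay_ok(self) -> bool:
        """Recompute every step's AICc from its stored (n, k, RSS) and check
        each accepted drop improved by at least the required 2 units."""
        for s in self.steps:
            if abs(aicc(s.n, s.k, s.rss, self.literal_aicc) - s.aicc) > 1e-9:
                return False
        for a, b in zip(self.steps, self.steps[1:]):
            if b.action.startswith("drop") and a.aicc - b.aicc < MIN_IMPROVEMENT - 1e-9:
                return False
        return True


def _droppable(terms: list[Term]) -> list[Term]:
    """Candidate terms that may be removed now: interactions always; a main
    effect only once no retained interaction references it."""
    inter_vars = {v for t in terms if t.is_interaction for v in t.variables}
    out = []
    for t in terms:
        if t.role != "candidate":
            continue
        if not t.is_interaction and t.variables[0] in inter_vars:
            continue
        out.append(t)
    return out


def backward_select(
    dm: DistanceMatrix,
    md: SampleMetadata,
    candidates: list[str | tuple[str, str]],
    confounders: list[str] = (),
    B: int = 999,
    seed: int | None = 0,
    literal_aicc: bool = False,
) -> ModelSelectionTrace:
    """Backward-eliminate candidate terms under the AICc >= 2 rule.

    ``candidates`` may mix single variables and (var1, var2) interaction
    pairs; confounders are fixed in the model.  Permutation p-values are
    computed only for the final model (AICc needs only the residual SS).
    Ties between equally scoring removals go to the larger-df term, then
    lexicographically by name.
    """
    design = DesignSpec.from_names(list(confounders), list(candidates))
    terms = list(design.terms)
    dropped: list[str] = []

    def refit(ts: list[Term]) -> tuple[PermanovaResult, float]:
        res = fit_permanova(dm, md, DesignSpec(ts), B=0, seed=seed)
        return res, aicc(res.n, res.k, res.residual_ss, literal_aicc)

    res, score = refit(terms)
    # candidates fully aliased in the full model leave immediately (df 0)
    aliased = [t for t in terms if t.role == "candidate" and res.terms.loc[t.name, "df"] == 0]
    for t in aliased:
        logger.warning("backward_select: dropping aliased candidate %s (df 0)", t.name)
        terms = [x for x in terms if x is not t]
        dropped.append(t.name)
    if aliased:
        res, score = refit(terms)

    steps = [SelectionStep(tuple(t.name for t in terms), res.k, res.n, res.residual_ss,
                           score, "start")]
    while True:
        options = []
        for t in _droppable(terms):
            reduced = [x for x in terms if x is not t]
            r, s = refit(reduced)
            options.append((s, -_term_df(res, t), t.name, t, reduced, r))
        if not options:
            break
        options.sort(key=lambda o: (o[0], o[1], o[2]))
        best = options[0]
        if score - best[0] >= MIN_IMPROVEMENT - 1e-12:
            _, _, tname, t, terms, res = best
            score = best[0]
            dropped.append(tname)
            steps.append(
                SelectionStep(tuple(x.name for x in terms), res.k, res.n,
                              res.residual_ss, score, f"drop {tname}")
            )
        else:
            break
    steps.append(SelectionStep(steps[-1].terms, steps[-1].k, steps[-1].n,
                               steps[-1].rss, steps[-1].aicc, "stop"))
    final = fit_permanova(dm, md, DesignSpec(terms), B=B, seed=seed)
    return ModelSelectionTrace(steps, final, tuple(confounders), literal_aicc, dropped)


def _term_df(res: PermanovaResult, t: Term) -> int:
    try:
        return int(res.terms.loc[t.name, "df"])
    except KeyError:
        return 1


def pooled_model(
    dm: DistanceMatrix,
    md: SampleMetadata,
    extra_terms: list[str | tuple[str, str]] = (),
    reads_confounder: str = "reads",
    subject_var: str = "subject_id",
    age_var: str = "timepoint",
    B: int = 99,
    seed: int | None = 0,
) -> PermanovaResult:
    """All-timepoint PERMANOVA: reads confounder, then subject identity,
    then age, then the remaining key variables.

    The pooled model quantifies how much of the total community variation is
    inter-individual (subject term) versus developmental (age term) versus
    attributable to the screened covariates.  Subjects with a single sample
    are permitted (they contribute df; logged).
    """
    tbl = md.table.reindex(dm.sample_ids)
    if tbl[age_var].nunique() < 2:
        raise ValidationError("pooled model needs >= 2 timepoints (age term df 0)")
    singles = (tbl.groupby(subject_var).size() == 1).sum()
    if singles:
        logger.info("pooled_model: %d subjects contribute a single sample", singles)
    terms = [Term((reads_confounder,), "confounder"),
             Term((subject_var,)), Term((age_var,))]
    for c in extra_terms:
        terms.append(Term(tuple(c) if isinstance(c, (tuple, list)) else (c,)))
    return fit_permanova(dm, md, DesignSpec(terms), B=B, seed=seed)
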