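"""Core data containers for cohort microbiota analysis.

Three structures travel through every stage of the pipeline: a taxon-by-sample
count table, per-sample metadata with typed variable declarations, and a
sample-by-sample dissimilarity matrix.  All are thin, validated wrappers around
pandas/numpy objects so that downstream code can rely on their invariants
(non-negative counts, unique ids, symmetric zero-diagonal distances) without
re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "VariableDef",
    "SampleMetadata",
    "DistanceMatrix",
    "ValidationError",
    "UNKNOWN",
]

#: sentinel used in taxon lineages for missing rank annotation
UNKNOWN = "unknown"


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass
class CountTable:
    """Taxon-by-sample table of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Taxa in rows, samples in columns, integer dtype.  The row index holds
        taxon ids; by convention a taxon id is a semicolon-separated lineage
        ``family;genus`` where either slot may be ``"unknown"``.
    ranks : pandas.Series
        Rank annotation per taxon (``genus``, ``family`` or ``unknown``),
        aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    ranks: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValidationError("duplicate taxon ids")
        if not self.counts.columns.is_unique:
            raise ValidationError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValidationError("negative counts present")
        if not np.issubdtype(vals.dtype, np.integer):
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise ValidationError("non-integer counts present")
            self.counts = self.counts.astype(np.int64)
        self.ranks = self.ranks.reindex(self.counts.index)
        if self.ranks.isna().any():
            raise ValidationError("rank annotation missing for some taxa")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        """Subset to the given samples, preserving current order."""
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return CountTable(self.counts[keep], self.ranks.copy())

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        keep = [t for t in self.taxon_ids if t in set(taxon_ids)]
        return CountTable(self.counts.loc[keep], self.ranks.loc[keep])


@dataclass(frozen=True)
class VariableDef:
    """Declaration of one metadata variable.

    kind is ``"categorical"`` or ``"numeric"``; role is ``"biological"``,
    ``"technical"`` or ``"confounder"``.  ``levels`` enumerates the allowed
    categories (categorical only) and ``reference`` names the baseline level
    used for treatment coding and model contrasts.
    """

    name: str
    kind: str
    role: str = "biological"
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise ValidationError(f"unknown variable kind {self.kind!r}")
        if self.role not in ("biological", "technical", "confounder"):
            raise ValidationError(f"unknown variable role {self.role!r}")
        if self.kind == "categorical" and self.levels is not None:
            if self.reference is None:
                object.__setattr__(self, "reference", self.levels[0])
            elif self.reference not in self.levels:
                raise ValidationError(
                    f"reference {self.reference!r} not among levels of {self.name!r}"
                )


# required structural columns of the metadata table
STRUCTURAL_COLUMNS = ("subject_id", "family_id", "role", "timepoint")


@dataclass
class SampleMetadata:
    """Per-sample metadata with typed variable declarations.

    ``table`` is indexed by sample id and carries the structural columns
    ``subject_id``, ``family_id``, ``role`` (infant/mother/father) and
    ``timepoint``, plus one column per declared variable.  Missing values are
    NaN/None, never zero.  ``exclusions`` logs variables marked unusable by
    the screening step, keyed by (variable, scope); samples are never removed
    by screening.
    """

    table: pd.DataFrame
    variables: dict[str, VariableDef] = field(default_factory=dict)
    exclusions: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValidationError("duplicate sample ids in metadata")
        for col in STRUCTURAL_COLUMNS:
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing structural column {col!r}")
        for name in self.variables:
            if name not in self.table.columns:
                raise ValidationError(f"declared variable {name!r} absent from table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def variable(self, name: str) -> pd.Series:
        return self.table[name]

    def vdef(self, name: str) -> VariableDef:
        try:
            return self.variables[name]
        except KeyError:
            raise KeyError(f"variable {name!r} not declared") from None

    def confounders(self) -> list[str]:
        return [n for n, d in self.variables.items() if d.role == "confounder"]

    def is_excluded(self, name: str, scope: str = "*") -> bool:
        return (name, scope) in self.exclusions or (name, "*") in self.exclusions

    def exclude(self, name: str, scope: str, reason: str) -> None:
        self.exclusions[(name, scope)] = reason

    def select_samples(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return SampleMetadata(
            self.table.loc[keep].copy(), dict(self.variables), dict(self.exclusions)
        )

    def with_variable(
        self, name: str, values: Mapping[str, object] | pd.Series, vdef: VariableDef
    ) -> "SampleMetadata":
        tbl = self.table.copy()
        tbl[name] = pd.Series(values).reindex(tbl.index)
        variables = dict(self.variables)
        variables[name] = vdef
        return SampleMetadata(tbl, variables, dict(self.exclusions))


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity with a method tag."""

    values: np.ndarray
    sample_ids: list[str]
    method: str = "bray_curtis"

    _SYM_TOL = 1e-12

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n},{n})")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in distance matrix")
        if n and np.abs(v - v.T).max() > self._SYM_TOL:
            raise ValidationError("distance matrix not symmetric")
        v = (v + v.T) / 2.0
        if n and np.abs(np.diag(v)).max() > self._SYM_TOL:
            raise ValidationError("distance matrix diagonal not zero")
        np.fill_diagonal(v, 0.0)
        if n and v.min() < -self._SYM_TOL:
            raise ValidationError("negative distances present")
        v[v < 0] = 0.0
        if self.method == "bray_curtis" and n and v.max() > 1 + 1e-9:
            raise ValidationError("Bray–Curtis distances must be <= 1")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def select(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        """Subset (and reorder) to the given sample ids."""
        ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            ix = np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in distance matrix") from None
        return DistanceMatrix(self.values[np.ix_(ix, ix)], ids, self.method)
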