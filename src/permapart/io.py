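"""Readers, writers, QC filters and derived-variable construction.

File conventions
----------------
* Count table: TSV with a ``#taxa-in-rows`` sentinel header line, first column
  ``taxon_id`` (semicolon lineage ``family;genus``), second column ``rank``,
  remaining columns samples.  A sparse BIOM-style triplet TSV
  (taxon, rank, sample, count) is also accepted.
* Metadata: TSV, one row per sample, with a YAML sidecar declaring each
  variable's type, levels, role and reference level.
* Distance matrix: square labelled TSV, 12 decimal digits.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    UNKNOWN,
    CountTable,
    DistanceMatrix,
    SampleMetadata,
    ValidationError,
    VariableDef,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "filter_samples_by_depth",
    "filter_unknown_fraction",
    "screen_variables",
    "derive_delivery3",
    "ParseError",
    "EARLY_TIMEPOINTS",
]

#: infant timepoints collected at three months of age or earlier
EARLY_TIMEPOINTS = frozenset({"3w", "6w", "3m"})

SENTINEL = "#taxa-in-rows"


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


# ---------------------------------------------------------------------------
# count table I/O


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a taxon-by-sample count table.

    ``format`` is ``"tsv"`` (dense, taxa in rows) or ``"biom"`` (sparse
    triplet TSV).  Cells must parse as non-negative integers; a malformed
    cell raises :class:`ParseError` naming the offending row and column.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    if format == "biom":
        return _read_biom_triplets(path, text)
    lines = text.splitlines()
    start = 1 if lines[0].startswith(SENTINEL) else 0
    header = lines[start].rstrip("\n").split("\t")
    if len(header) < 3 or header[0] != "taxon_id" or header[1] != "rank":
        raise ParseError(
            f"{path}: expected header 'taxon_id\\trank\\t<samples...>', got {header[:3]}"
        )
    samples = header[2:]
    taxa, ranks, rows = [], [], []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        taxa.append(parts[0])
        ranks.append(parts[1])
        rows.append(
            [_parse_count(val, path, parts[0], samples[j]) for j, val in enumerate(parts[2:])]
        )
    counts = pd.DataFrame(rows, index=taxa, columns=samples, dtype=np.int64)
    return CountTable(counts, pd.Series(ranks, index=taxa))


def _parse_count(val: str, path: Path, taxon: str, sample: str) -> int:
    try:
        x = int(val)
    except ValueError:
        raise ParseError(f"{path}: malformed count {val!r} at taxon {taxon!r}, sample {sample!r}")
    if x < 0:
        raise ValidationError(f"{path}: negative count at taxon {taxon!r}, sample {sample!r}")
    return x


def _read_biom_triplets(path: Path, text: str) -> CountTable:
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    if header[:4] != ["taxon_id", "rank", "sample_id", "count"]:
        raise ParseError(f"{path}: expected triplet header taxon_id/rank/sample_id/count")
    recs = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields")
        recs.append((parts[0], parts[1], parts[2], _parse_count(parts[3], path, parts[0], parts[2])))
    df = pd.DataFrame(recs, columns=["taxon_id", "rank", "sample_id", "count"])
    ranks = df.drop_duplicates("taxon_id").set_index("taxon_id")["rank"]
    wide = (
        df.pivot_table(index="taxon_id", columns="sample_id", values="count", aggfunc="sum")
        .fillna(0)
        .astype(np.int64)
    )
    wide = wide.loc[ranks.index.intersection(wide.index)]
    return CountTable(wide, ranks.loc[wide.index])


def write_count_table(ct: CountTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SENTINEL + "\n")
        fh.write("taxon_id\trank\t" + "\t".join(ct.sample_ids) + "\n")
        for tid, rank, row in zip(ct.taxon_ids, ct.ranks, ct.counts.to_numpy()):
            fh.write(tid + "\t" + str(rank) + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# metadata I/O


def read_metadata(table_path: str | Path, variables_path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV plus its YAML variable-declaration sidecar."""
    tbl = pd.read_csv(table_path, sep="\t", index_col="sample_id", dtype={"sample_id": str})
    spec = yaml.safe_load(Path(variables_path).read_text()) or {}
    variables: dict[str, VariableDef] = {}
    for name, d in spec.get("variables", {}).items():
        levels = tuple(str(x) for x in d["levels"]) if d.get("levels") else None
        variables[name] = VariableDef(
            name=name,
            kind=d["kind"],
            role=d.get("role", "biological"),
            levels=levels,
            reference=str(d["reference"]) if d.get("reference") is not None else None,
        )
        if variables[name].kind == "numeric":
            tbl[name] = pd.to_numeric(tbl[name], errors="coerce")
        else:
            tbl[name] = tbl[name].astype("object").where(tbl[name].notna(), None)
            tbl[name] = tbl[name].map(lambda v: None if v is None else str(v))
    return SampleMetadata(tbl, variables)


def write_metadata(md: SampleMetadata, table_path: str | Path, variables_path: str | Path) -> None:
    md.table.to_csv(table_path, sep="\t", index_label="sample_id")
    spec = {
        "variables": {
            name: {
                "kind": d.kind,
                "role": d.role,
                "levels": list(d.levels) if d.levels else None,
                "reference": d.reference,
            }
            for name, d in md.variables.items()
        }
    }
    Path(variables_path).write_text(yaml.safe_dump(spec, sort_keys=False))


# ---------------------------------------------------------------------------
# distance matrix I/O


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square labelled TSV; 17 significant digits make the
    round trip exact (beyond the 12-digit contract)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#method={dm.method}\n")
        fh.write("sample_id\t" + "\t".join(dm.sample_ids) + "\n")
        for sid, row in zip(dm.sample_ids, dm.values):
            fh.write(sid + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    method = "bray_curtis"
    if lines and lines[0].startswith("#method="):
        method = lines[0].split("=", 1)[1]
        lines = lines[1:]
    header = lines[0].split("\t")
    ids = header[1:]
    vals = np.array(
        [[float(x) for x in line.split("\t")[1:]] for line in lines[1 : 1 + len(ids)]]
    )
    try:
        return DistanceMatrix(vals, ids, method)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None


# ---------------------------------------------------------------------------
# sample QC filters


def filter_samples_by_depth(
    ct: CountTable,
    md: SampleMetadata,
    cutoff_early: int = 3000,
    cutoff_late: int = 5000,
    early_timepoints: frozenset[str] | set[str] = EARLY_TIMEPOINTS,
    known_timepoints: set[str] | None = None,
) -> tuple[CountTable, SampleMetadata]:
    """Remove samples below their age-specific read-depth cutoff.

    Samples collected at three months of age or before (timepoints in
    ``early_timepoints``) use ``cutoff_early``; all other samples, including
    parental spot samples, use ``cutoff_late``.  Removal is strict: a sample
    is dropped when ``depth < cutoff``.
    """
    depths = ct.depths
    tps = md.table["timepoint"]
    if known_timepoints is not None:
        bad = set(tps.unique()) - set(known_timepoints)
        if bad:
            raise ValidationError(f"unknown timepoint labels: {sorted(bad)}")
    keep, removed = [], []
    for sid in ct.sample_ids:
        if sid not in tps.index:
            raise ValidationError(f"sample {sid!r} missing from metadata")
        cutoff = cutoff_early if tps[sid] in early_timepoints else cutoff_late
        if depths[sid] < cutoff:
            removed.append((sid, int(depths[sid]), cutoff))
        else:
            keep.append(sid)
    for sid, d, c in removed:
        logger.info("depth filter: removed %s (depth %d < %d)", sid, d, c)
    return ct.select_samples(keep), md.select_samples(keep)


def filter_unknown_fraction(ct: CountTable, max_unknown: float = 0.20) -> CountTable:
    """Drop unknown-annotated taxa and exclude samples dominated by them.

    A sample is excluded when its unknown-annotation read fraction, computed
    before removing the unknown rows, strictly exceeds ``max_unknown``.
    """
    unknown_rows = [
        t for t, r in zip(ct.taxon_ids, ct.ranks) if r == UNKNOWN or _lineage_all_unknown(t)
    ]
    depths = ct.depths.to_numpy().astype(float)
    if unknown_rows:
        unk = ct.counts.loc[unknown_rows].sum(axis=0).to_numpy().astype(float)
    else:
        unk = np.zeros(ct.n_samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depths > 0, unk / depths, 0.0)
    keep_samples = [s for s, f in zip(ct.sample_ids, frac) if f <= max_unknown]
    dropped = [s for s in ct.sample_ids if s not in set(keep_samples)]
    for s in dropped:
        logger.info("unknown-fraction filter: excluded sample %s", s)
    keep_taxa = [t for t in ct.taxon_ids if t not in set(unknown_rows)]
    return ct.select_taxa(keep_taxa).select_samples(keep_samples)


def _lineage_all_unknown(taxon_id: str) -> bool:
    parts = taxon_id.split(";")
    return all(p == UNKNOWN for p in parts)


# ---------------------------------------------------------------------------
# variable screening & derived variables


def screen_variables(
    md: SampleMetadata,
    min_group: int = 10,
    max_missing: float = 0.75,
    scopes: list[tuple[str, str]] | None = None,
) -> SampleMetadata:
    """Mark unusable variables per analysis scope; never removes samples.

    A scope is a (sample role, timepoint) pair; by default every combination
    present in the metadata.  Within each scope a categorical variable is
    excluded when all but one of its observed levels have fewer than
    ``min_group`` samples (strict ``<``), and any variable is excluded when
    its missingness fraction strictly exceeds ``max_missing``.
    """
    out = SampleMetadata(md.table.copy(), dict(md.variables), dict(md.exclusions))
    if scopes is None:
        scopes = sorted(
            set(zip(md.table["role"].astype(str), md.table["timepoint"].astype(str)))
        )
    for role, tp in scopes:
        mask = (md.table["role"].astype(str) == role) & (md.table["timepoint"].astype(str) == tp)
        sub = md.table.loc[mask]
        if sub.empty:
            continue
        scope = f"{role}:{tp}"
        for name, vdef in md.variables.items():
            col = sub[name]
            miss = col.isna().mean()
            if miss > max_missing:
                out.exclude(name, scope, f"missingness {miss:.2f} > {max_missing}")
                logger.info("screen: %s excluded in %s (missingness %.2f)", name, scope, miss)
                continue
            if vdef.kind == "categorical":
                sizes = col.dropna().value_counts()
                if len(sizes) >= 2 and (sizes >= min_group).sum() <= 1:
                    out.exclude(
                        name, scope, f"all but one level have < {min_group} samples"
                    )
                    logger.info("screen: %s excluded in %s (imbalanced levels)", name, scope)
    return out


def derive_delivery3(
    md: SampleMetadata,
    delivery_var: str = "delivery_mode",
    antibiotics_var: str = "intrapartum_antibiotics",
    name: str = "delivery3",
) -> SampleMetadata:
    """Combine birth mode and intrapartum antibiotic exposure into the
    three-class delivery variable {CS+AB, VD+AB, VD-AB}.

    Every Caesarean birth in the cohort involves intrapartum antibiotics;
    a CS record without antibiotics is rejected as impossible.
    """
    dmode = md.table[delivery_var]
    ab = md.table[antibiotics_var]
    values = {}
    for sid in md.sample_ids:
        d, a = dmode[sid], ab[sid]
        if pd.isna(d) or pd.isna(a):
            values[sid] = None
            continue
        if d == "CS":
            if a != "yes":
                raise ValidationError(
                    f"sample {sid!r}: C-section without intrapartum antibiotics"
                )
            values[sid] = "CS+AB"
        elif d == "VD":
            values[sid] = "VD+AB" if a == "yes" else "VD-AB"
        else:
            raise ValidationError(f"sample {sid!r}: unknown delivery mode {d!r}")
    vdef = VariableDef(
        name, "categorical", role="biological",
        levels=("VD-AB", "VD+AB", "CS+AB"), reference="VD-AB",
    )
    return md.with_variable(name, values, vdef)
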