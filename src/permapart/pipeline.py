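"""Configuration-driven orchestration of the full analysis graph.

``run_full`` executes, on a dataset directory: QC filters -> genus
aggregation -> per-timepoint distances -> technical-variable screen
(unadjusted) -> confounder-adjusted biological screen with dispersion flags
-> interaction screen -> stratified analyses -> per-timepoint cumulative
models -> pooled all-timepoint model -> alpha-diversity panel ->
differential abundance -> family-dyad tests.  Every stage reads its inputs
from files written by earlier stages and writes TSV outputs plus a manifest
recording the package version, seeds and a hash of the configuration, so a
rerun with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .da import fit_da
from .distances import aitchison, bray_curtis, pearson_distance
from .diversity import aggregate, alpha_panel, relative_abundance
from .io import (
    filter_samples_by_depth,
    filter_unknown_fraction,
    read_count_table,
    read_distance_matrix,
    read_metadata,
    screen_variables,
    write_count_table,
    write_distance_matrix,
    write_metadata,
)
from .permanova import within_batch_similarity_test
from .screen import family_dyad_analysis, screen_all, screen_interaction, stratified_screen
from .selection import backward_select, pooled_model
from .types import CountTable, DistanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Global constants and paths of one pipeline run."""

    counts: str
    metadata: str
    variables: str
    outdir: str
    rank: str = "genus"
    distance: str = "bray_curtis"
    confounders: tuple[str, ...] = ("extraction_batch", "reads")
    biological_variables: tuple[str, ...] = ()
    technical_variables: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    stratified: tuple[tuple[str, str], ...] = ()  # (variable, stratifier)
    da_covariates: tuple[str, ...] = ()
    da_adjust: str | None = "extraction_batch"
    dyads: tuple[str, ...] = ("mother-infant", "father-infant")
    dyad_timepoints: tuple[str, ...] = ("3w",)
    timepoints: tuple[str, ...] = ()
    cutoff_early: int = 3000
    cutoff_late: int = 5000
    max_unknown: float = 0.20
    min_group: int = 10
    max_missing: float = 0.75
    p_threshold: float = 0.05
    q_threshold: float = 0.1
    prevalence: float = 0.10
    aicc_improvement: float = 2.0
    B: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kw = dict(raw)
        for k in ("confounders", "biological_variables", "technical_variables",
                  "da_covariates", "dyads", "dyad_timepoints", "timepoints"):
            if k in kw and kw[k] is not None:
                kw[k] = tuple(kw[k])
        for k in ("interactions", "stratified"):
            if k in kw and kw[k] is not None:
                kw[k] = tuple(tuple(x) for x in kw[k])
        return cls(**kw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_DISTANCES = {"bray_curtis": None, "aitchison": None, "pearson": None}


def _compute_distance(ct: CountTable, method: str) -> DistanceMatrix:
    if method == "bray_curtis":
        return bray_curtis(relative_abundance(ct))
    if method == "aitchison":
        return aitchison(ct)
    if method == "pearson":
        return pearson_distance(relative_abundance(ct))
    raise ValueError(f"unknown distance method {method!r}")


def run_full(config: RunConfig) -> Path:
    """Execute the full analysis graph; returns the output directory.

    Any stage failure aborts with a stage-named diagnostic; outputs written
    so far are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "B": config.B,
        "stages": {},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def stage(name):
        def deco(fn):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                fn()
            except Exception as e:
                manifest["stages"][name] = {"status": "failed", "error": str(e)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

        return deco

    state: dict = {}

    @stage("qc")
    def _qc():
        ct = read_count_table(config.counts)
        md = read_metadata(config.metadata, config.variables)
        md = md.select_samples(ct.sample_ids)
        ct, md = filter_samples_by_depth(ct, md, config.cutoff_early, config.cutoff_late)
        ct = filter_unknown_fraction(ct, config.max_unknown)
        md = md.select_samples(ct.sample_ids)
        md = screen_variables(md, config.min_group, config.max_missing)
        write_count_table(ct, out / "counts_qc.tsv")
        write_metadata(md, out / "metadata_qc.tsv", out / "variables_qc.yaml")
        pd.DataFrame(
            [{"variable": k[0], "scope": k[1], "reason": v} for k, v in md.exclusions.items()]
        ).to_csv(out / "variable_exclusions.tsv", sep="\t", index=False)
        state["ct"], state["md"] = ct, md

    @stage("distances")
    def _distances():
        ct, md = state["ct"], state["md"]
        genus = aggregate(ct, config.rank)
        state["genus"] = genus
        tps = config.timepoints or tuple(
            sorted(md.table.loc[md.table["role"] == "infant", "timepoint"].unique())
        )
        state["tps"] = tps
        dms = {}
        for tp in tps:
            samples = [s for s in genus.sample_ids
                       if md.table.loc[s, "role"] == "infant"
                       and md.table.loc[s, "timepoint"] == tp]
            if len(samples) < 5:
                continue
            dm = _compute_distance(genus.select_samples(samples), config.distance)
            write_distance_matrix(dm, out / f"distance_{tp}.tsv")
            dms[tp] = dm
        infant = [s for s in genus.sample_ids if md.table.loc[s, "role"] == "infant"]
        dm_all = _compute_distance(genus.select_samples(infant), config.distance)
        write_distance_matrix(dm_all, out / "distance_pooled.tsv")
        parental = [s for s in genus.sample_ids if md.table.loc[s, "role"] != "infant"]
        if len(parental) >= 5:
            dm_par = _compute_distance(genus.select_samples(parental), config.distance)
            write_distance_matrix(dm_par, out / "distance_parental.tsv")
        state["dms"], state["dm_all"] = dms, dm_all

    @stage("diversity")
    def _diversity():
        panel = alpha_panel(state["genus"], seed=config.seed)
        panel.to_tsv(out / "alpha_panel.tsv")

    @stage("technical_screen")
    def _tech():
        md = state["md"]
        tech = list(config.technical_variables) or [
            n for n, d in md.variables.items() if d.role in ("technical", "confounder")
        ]
        rep = screen_all(state["dms"], md, tech, confounders=[],
                         B=config.B, seed=config.seed)
        rep.to_tsv(out / "screen_technical.tsv")

    @stage("biological_screen")
    def _bio():
        md = state["md"]
        bio = list(config.biological_variables) or [
            n for n, d in md.variables.items() if d.role == "biological"
        ]
        rep = screen_all(state["dms"], md, bio, confounders=list(config.confounders),
                         B=config.B, seed=config.seed)
        rep.to_tsv(out / "screen_biological.tsv")
        state["screen"] = rep

    @stage("interactions")
    def _inter():
        rows = []
        for tp, dm in state["dms"].items():
            for v1, v2 in config.interactions:
                try:
                    res = screen_interaction(dm, state["md"], v1, v2,
                                             list(config.confounders),
                                             B=config.B, seed=config.seed)
                except Exception as e:
                    logger.info("interaction %s:%s at %s skipped (%s)", v1, v2, tp, e)
                    continue
                nm = f"{v1}:{v2}"
                rows.append({"timepoint": tp, "interaction": nm,
                             "R2": res.r2(nm), "p": res.p(nm),
                             "admitted": res.p(nm) < config.p_threshold})
        pd.DataFrame(rows, columns=["timepoint", "interaction", "R2", "p", "admitted"]).to_csv(
            out / "interactions.tsv", sep="\t", index=False)
        state["admitted"] = {
            (r["timepoint"], tuple(r["interaction"].split(":"))) for r in rows if r["admitted"]
        }

    @stage("stratified")
    def _strat():
        rows = []
        for tp, dm in state["dms"].items():
            for var, strat in config.stratified:
                res = stratified_screen(dm, state["md"], var, strat,
                                        list(config.confounders),
                                        B=config.B, seed=config.seed)
                for lev, r in res.items():
                    rows.append({"timepoint": tp, "variable": var, "stratifier": strat,
                                 "stratum": lev,
                                 "R2": r.r2(var) if r else np.nan,
                                 "p": r.p(var) if r else np.nan,
                                 "n": r.n if r else 0})
        pd.DataFrame(rows, columns=["timepoint", "variable", "stratifier", "stratum",
                                    "R2", "p", "n"]).to_csv(
            out / "stratified.tsv", sep="\t", index=False)

    @stage("cumulative")
    def _cumulative():
        rep = state.get("screen")
        rows = []
        for tp, dm in state["dms"].items():
            if rep is not None and not rep.table.empty:
                sub = rep.table[rep.table["timepoint"] == tp]
                cands = list(sub.loc[sub["significant"], "variable"])
            else:
                cands = []
            cands += [pair for (t, pair) in state.get("admitted", set()) if t == tp]
            if not cands:
                continue
            trace = backward_select(dm, state["md"], cands, list(config.confounders),
                                    B=config.B, seed=config.seed)
            tf = trace.to_frame()
            tf.insert(0, "timepoint", tp)
            rows.append(tf)
            trace.final.to_frame().to_csv(out / f"cumulative_{tp}.tsv", sep="\t")
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(out / "cumulative_trace.tsv",
                                                      sep="\t", index=False)

    @stage("pooled")
    def _pooled():
        res = pooled_model(state["dm_all"], state["md"], B=min(config.B, 99),
                           seed=config.seed)
        res.to_frame().to_csv(out / "pooled_model.tsv", sep="\t")

    @stage("da")
    def _da():
        for cov in config.da_covariates:
            adj = config.da_adjust
            if cov == "dna_yield":
                adj = "stool_consistency"
            elif cov == "platform":
                adj = None
            res = fit_da(state["genus"], state["md"], cov, adjust=adj,
                         threshold=config.prevalence)
            res.to_tsv(out / f"da_{cov}.tsv")

    @stage("dyads")
    def _dyads():
        rows = []
        genus = state["genus"]
        md = state["md"]
        dm_full = _compute_distance(genus, config.distance)
        for dyad in config.dyads:
            for tp in config.dyad_timepoints:
                try:
                    rows.append(family_dyad_analysis(dm_full, md, dyad, tp))
                except Exception as e:
                    logger.info("dyad %s at %s skipped (%s)", dyad, tp, e)
        pd.DataFrame(rows).to_csv(out / "dyads.tsv", sep="\t", index=False)

    @stage("summary")
    def _summary():
        rep = state.get("screen")
        if rep is not None and not rep.table.empty:
            sig = rep.significant_findings()
            sig.to_csv(out / "significant_findings.tsv", sep="\t", index=False)

    return out
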