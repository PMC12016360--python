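"""End-to-end orchestration: cluster -> correlate -> fit -> score -> evaluate.

A session runs one or more structural priors over the same inputs and emits
a comparison table with one row per model (columns: model, p_value,
nagelkerke_r2, aic, pct_probes_clustered).  Every output file embeds the
session seed and config hash in a header comment so a report is reproducible
from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blockcorr, clustering, io, scoring
from .gibbs import GibbsConfig, GibbsDivergenceError, MethylationScoreModel

logger = logging.getLogger("methscore")

__all__ = ["SessionConfig", "PipelineError", "run_pipeline", "REPORT_COLUMNS"]

REPORT_COLUMNS = ["model", "p_value", "nagelkerke_r2", "aic", "pct_probes_clustered"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SessionConfig:
    """One pipeline session: input paths, priors to run, sampler settings."""

    summary_stats: str
    methylation: str
    annotation: str
    phenotypes: str
    out_dir: str
    priors: list = field(default_factory=lambda: ["window:100000"])
    tad_bed: str | None = None
    corr_matrix: str | None = None  # optional independent reference matrix
    cmr: dict = field(default_factory=dict)  # corlo / maxprbdst / corlodst
    gibbs: dict = field(default_factory=dict)  # GibbsConfig fields
    baseline: dict = field(default_factory=dict)  # r2_prune / p_thresh / cluster
    shrink: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "summary_stats": self.summary_stats,
            "methylation": self.methylation,
            "annotation": self.annotation,
            "phenotypes": self.phenotypes,
            "out_dir": self.out_dir,
            "priors": list(self.priors),
            "tad_bed": self.tad_bed,
            "corr_matrix": self.corr_matrix,
            "cmr": dict(self.cmr),
            "gibbs": dict(self.gibbs),
            "baseline": dict(self.baseline),
            "shrink": self.shrink,
            "seed": self.seed,
        }

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def _build_clusters(spec: str, cfg: SessionConfig, ann, mat, tads, seed: int):
    if spec.startswith("window:"):
        return [clustering.sliding_window_clusters(ann, int(spec.split(":", 1)[1]))]
    if spec in ("cmr", "cmr-nosingleton"):
        params = clustering.CmrParams(
            corlo=cfg.cmr.get("corlo", 0.2),
            maxprbdst=cfg.cmr.get("maxprbdst", 100_000),
            corlodst=cfg.cmr.get("corlodst", 800),
        )
        cs = clustering.cmr_clusters(ann, mat, params)
        if spec == "cmr-nosingleton":
            cs, n_dropped = clustering.drop_singletons(cs)
            logger.info("cmr-nosingleton: dropped %d singleton probes", n_dropped)
        return [cs]
    if spec == "tad":
        if tads is None:
            raise io.ValidationError("prior 'tad' requested but no tad_bed configured")
        return [clustering.tad_clusters(ann, tads)]
    if spec.startswith("random:"):
        k = int(spec.split(":", 1)[1])
        return clustering.random_clusters(ann, n_sets=k, seed=seed)
    raise io.ValidationError(f"unknown prior spec {spec!r}")


def run_pipeline(cfg: SessionConfig) -> pd.DataFrame:
    """Execute every requested prior and return the comparison table.

    Prior specs: ``cmr`` | ``cmr-nosingleton`` | ``window:<bp>`` | ``tad`` |
    ``random:<k>`` | ``baseline-pt``.  Any stage error aborts with the stage
    name; partial outputs written so far persist.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"seed={cfg.seed} config_hash={cfg.hash()}"

    stats = _stage("read")(io.read_summary_stats)(cfg.summary_stats)
    mat = _stage("read")(io.read_methylation_matrix)(cfg.methylation)
    ann = _stage("read")(io.read_probe_annotation)(cfg.annotation)
    pheno = _stage("read")(io.read_phenotypes)(cfg.phenotypes)
    tads = _stage("read")(io.read_tad_scaffold)(cfg.tad_bed) if cfg.tad_bed else None
    corr_mat = (
        _stage("read")(io.read_methylation_matrix)(cfg.corr_matrix)
        if cfg.corr_matrix
        else mat
    )

    stats, mat, ann, report = _stage("intersect")(io.intersect_probes)(stats, mat, ann)
    logger.info(
        "intersection: %d common probes (dropped stats=%d matrix=%d annotation=%d)",
        report.n_common,
        report.dropped_from_stats,
        report.dropped_from_matrix,
        report.dropped_from_annotation,
    )
    if corr_mat is not mat:
        corr_mat = corr_mat.subset([p for p in mat.probe_ids if p in set(corr_mat.probe_ids)])

    rows = []
    for spec in cfg.priors:
        if spec == "baseline-pt":
            rows.append(_run_baseline(cfg, stats, mat, ann, pheno, out_dir, tag))
            continue
        for cs in _build_clusters(spec, cfg, ann, mat, tads, cfg.seed):
            rows.append(_run_model(cfg, cs, stats, mat, corr_mat, ann, pheno, out_dir, tag))

    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    with open(out_dir / "report.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    with open(out_dir / "report.json", "w") as fh:
        json.dump({"seed": cfg.seed, "config_hash": cfg.hash(), "models": rows}, fh, indent=2)
    return table


def _run_model(cfg, cs, stats, mat, corr_mat, ann, pheno, out_dir, tag) -> dict:
    name = cs.label
    safe = name.replace(":", "_").replace(",", "_").replace("=", "")
    logger.info("model %s: %d probes in %d clusters", name, len(cs), cs.n_clusters)
    clustering.write_cluster_assignments(cs, out_dir / f"clusters_{safe}.tsv", tag)
    summ = clustering.cluster_summary(cs)

    # restrict to the cluster set's probe universe (cmr-nosingleton shrinks it)
    probes = [p for p in mat.probe_ids if p in cs.assignment]
    stats_u, mat_u = stats.subset(probes), mat.subset(probes)
    corr_u = corr_mat.subset([p for p in probes if p in set(corr_mat.probe_ids)])

    R = _stage("corr")(blockcorr.build_block_correlation)(corr_u, cs)
    if cfg.shrink > 0:
        R = blockcorr.regularize_blocks(R, cfg.shrink)
    cond = blockcorr.conditioning_report(R)
    if cond.ill_conditioned:
        logger.warning(
            "model %s: %d ill-conditioned block(s), min eigenvalue %.3g",
            name, cond.n_flagged, cond.min_eigenvalues.min(),
        )

    model = _stage("fit")(MethylationScoreModel.from_summary_stats)(stats_u, R)
    gcfg = GibbsConfig(**{"seed": cfg.seed, **cfg.gibbs})
    try:
        res = model.fit(gcfg)
    except GibbsDivergenceError:
        raise
    except io.ValidationError as exc:
        raise PipelineError("fit", exc) from exc
    logger.info(
        "model %s: posterior mean h2=%.4g p=%.4g", name, res.h2_posterior_mean, res.p_posterior_mean
    )
    io._write_tsv(res.to_frame(), out_dir / f"effects_{safe}.tsv", tag)
    io._write_tsv(res.chains_frame(), out_dir / f"chains_{safe}.tsv", tag)

    scores = _stage("score")(res.score)(mat_u)
    io.write_scores(scores, out_dir / f"scores_{safe}.tsv", tag)
    ev = _stage("evaluate")(scoring.evaluate_scores)(scores, pheno)
    return {
        "model": name,
        "p_value": ev.wald_p,
        "nagelkerke_r2": ev.nagelkerke_r2,
        "aic": ev.aic,
        "pct_probes_clustered": summ.pct_nonsingleton_probes,
    }


def _run_baseline(cfg, stats, mat, ann, pheno, out_dir, tag) -> dict:
    spec = cfg.baseline.get("cluster", "window:100000")
    cs = _build_clusters(spec, cfg, ann, mat, None, cfg.seed)[0]
    summ = clustering.cluster_summary(cs)
    scores = _stage("score")(scoring.clump_threshold_baseline)(
        stats,
        mat,
        cs,
        r2_prune=cfg.baseline.get("r2_prune", 0.25),
        p_thresh=cfg.baseline.get("p_thresh", 0.05),
    )
    io.write_scores(scores, out_dir / "scores_baseline-pt.tsv", tag)
    ev = _stage("evaluate")(scoring.evaluate_scores)(scores, pheno)
    return {
        "model": "baseline-pt",
        "p_value": ev.wald_p,
        "nagelkerke_r2": ev.nagelkerke_r2,
        "aic": ev.aic,
        "pct_probes_clustered": summ.pct_nonsingleton_probes,
    }
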