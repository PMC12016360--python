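"""Synthetic methylation studies with the structure the pipeline assumes.

The generator emulates what the real analyses consume: a training cohort
whose per-probe marginal statistics stand in for an MWAS meta-analysis, and
an independent test cohort with individual-level residualized methylation
and a binary phenotype.  Methylation is drawn as standardized Gaussians with
block-compound-symmetric correlation (residualized beta values are
effectively unbounded, so no [0, 1] clamp is applied); sparse true effects
follow a point-normal prior; the phenotype is a liability-threshold
dichotomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import (
    MethylationMatrix,
    PhenotypeTable,
    ProbeAnnotation,
    SummaryStatsTable,
    ValidationError,
)

__all__ = ["SimConfig", "SyntheticStudy", "generate_study", "per_probe_mwas"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generator.

    m_probes
        Total probes on the synthetic array.
    n_train / n_test
        Cohort sizes (the marginal statistics come from the training half
        only; the score is evaluated on the test half).
    block_size
        Probes per correlated block.
    rho
        Within-block compound-symmetric correlation, in [0, 1).
    h2_true / p_true
        Liability variance explained by methylation and the fraction of
        causal probes (point-normal prior).
    prevalence
        Case fraction implied by the liability threshold.
    probe_spacing
        bp between consecutive probes within a block; consecutive blocks
        are separated by ``block_gap`` (default 10x spacing) so a sliding
        window between the two recovers the true blocks exactly.
    """

    m_probes: int = 2000
    n_train: int = 5000
    n_test: int = 1000
    block_size: int = 10
    rho: float = 0.5
    h2_true: float = 0.3
    p_true: float = 0.02
    prevalence: float = 0.4
    probe_spacing: int = 1000
    seed: int = 0
    block_gap: int | None = None

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 <= self.h2_true < 1:
            raise ValueError("h2_true must be in [0, 1)")
        if not 0 < self.p_true <= 1:
            raise ValueError("p_true must be in (0, 1]")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.m_probes < 1 or self.block_size < 1:
            raise ValueError("m_probes and block_size must be >= 1")

    @property
    def gap(self) -> int:
        return self.block_gap if self.block_gap is not None else 10 * self.probe_spacing


@dataclass(frozen=True)
class SyntheticStudy:
    annotation: ProbeAnnotation
    train_matrix: MethylationMatrix
    train_phenotypes: PhenotypeTable
    test_matrix: MethylationMatrix
    test_phenotypes: PhenotypeTable
    true_beta: np.ndarray  # per probe, annotation order
    summary: SummaryStatsTable  # computed from the training half only
    config: SimConfig


def _annotation(cfg: SimConfig) -> ProbeAnnotation:
    """Probes at regular spacing, blocks separated by a larger gap, spread
    over up to 22 synthetic chromosomes."""
    n_blocks = int(np.ceil(cfg.m_probes / cfg.block_size))
    n_chroms = min(22, n_blocks)
    blocks_per_chrom = int(np.ceil(n_blocks / n_chroms))
    records = []
    probe = 0
    for b in range(n_blocks):
        chrom = f"chr{b // blocks_per_chrom + 1}"
        within = b % blocks_per_chrom
        block_start = 1000 + within * (cfg.block_size * cfg.probe_spacing + cfg.gap)
        for i in range(cfg.block_size):
            if probe >= cfg.m_probes:
                break
            records.append(
                (f"cg{probe:08d}", chrom, block_start + i * cfg.probe_spacing)
            )
            probe += 1
    return ProbeAnnotation(pd.DataFrame(records, columns=["probe_id", "chrom", "pos"]))


def _draw_methylation(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """n x m matrix with block-compound-symmetric correlation, standardized
    columns (empirical mean 0, sd 1 per probe)."""
    m = cfg.m_probes
    x = np.empty((n, m))
    sr, sn = np.sqrt(cfg.rho), np.sqrt(1.0 - cfg.rho)
    for start in range(0, m, cfg.block_size):
        stop = min(start + cfg.block_size, m)
        shared = rng.standard_normal(n)[:, None]
        x[:, start:stop] = sr * shared + sn * rng.standard_normal((n, stop - start))
    x -= x.mean(axis=0)
    x /= x.std(axis=0)
    return x


def _liability_phenotype(
    cfg: SimConfig, x: np.ndarray, beta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    liability = x @ beta + rng.standard_normal(x.shape[0]) * np.sqrt(1.0 - cfg.h2_true)
    threshold = sps.norm.ppf(1.0 - cfg.prevalence)
    return (liability > threshold).astype(int)


def generate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate a complete two-cohort study from a config (deterministic in
    the seed; train and test are independent given the config).

    The causal set has exactly round(p_true * m_probes) probes with effects
    ~ Normal(0, h2_true / (m_probes * p_true)), so the liability variance is
    h2_true in expectation; the residual liability is Normal(0, 1 - h2_true)
    and cases are samples above the theoretical (1 - prevalence) quantile.
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _annotation(cfg)
    m = cfg.m_probes

    n_causal = int(np.round(cfg.p_true * m))
    true_beta = np.zeros(m)
    if n_causal > 0 and cfg.h2_true > 0:
        causal = rng.choice(m, size=n_causal, replace=False)
        true_beta[causal] = rng.standard_normal(n_causal) * np.sqrt(
            cfg.h2_true / (m * cfg.p_true)
        )

    x_train = _draw_methylation(cfg, cfg.n_train, rng)
    y_train = _liability_phenotype(cfg, x_train, true_beta, rng)
    x_test = _draw_methylation(cfg, cfg.n_test, rng)
    y_test = _liability_phenotype(cfg, x_test, true_beta, rng)

    probe_ids = ann.probe_ids
    train_mat = MethylationMatrix(
        probe_ids, [f"train{i:05d}" for i in range(cfg.n_train)], x_train.T
    )
    test_mat = MethylationMatrix(
        probe_ids, [f"test{i:05d}" for i in range(cfg.n_test)], x_test.T
    )
    train_pheno = PhenotypeTable(
        pd.DataFrame({"sample_id": train_mat.sample_ids, "y": y_train})
    )
    test_pheno = PhenotypeTable(
        pd.DataFrame({"sample_id": test_mat.sample_ids, "y": y_test})
    )
    summary = per_probe_mwas(train_mat, train_pheno)
    return SyntheticStudy(
        annotation=ann,
        train_matrix=train_mat,
        train_phenotypes=train_pheno,
        test_matrix=test_mat,
        test_phenotypes=test_pheno,
        true_beta=true_beta,
        summary=summary,
        config=cfg,
    )


def per_probe_mwas(mat: MethylationMatrix, pheno: PhenotypeTable) -> SummaryStatsTable:
    """Marginal association scan: OLS of y on each standardized probe.

    For each probe, fits y = a + b * x_std and reports the slope, its
    standard error, the sample size and the two-sided t-test p-value —
    the linear analogue of the per-probe scan a training meta-analysis
    provides.  Vectorized over probes via the simple-regression closed form.
    """
    pheno_samples = set(pheno.sample_ids)
    common = [s for s in mat.sample_ids if s in pheno_samples]
    if len(common) < 3:
        raise ValidationError("per-probe MWAS needs >= 3 shared samples")
    mat = mat.subset_samples(common)
    y = pheno.subset(common).frame["y"].to_numpy(float)
    n = len(y)
    x = mat.values  # probes x samples
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = mat.probe_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValidationError(f"zero-variance probe {bad!r} in MWAS")
    xc = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]  # centered, unit sd
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=1)
    sxy = xc @ yc
    slope = sxy / sxx
    resid_ss = (yc * yc).sum() - slope * sxy
    dof = n - 2
    se = np.sqrt(np.maximum(resid_ss, 0.0) / dof / sxx)
    se = np.where(se == 0, np.finfo(float).tiny, se)
    tstat = slope / se
    pval = 2.0 * sps.t.sf(np.abs(tstat), df=dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return SummaryStatsTable(
        pd.DataFrame(
            {
                "probe_id": mat.probe_ids,
                "beta": slope,
                "se": se,
                "n": np.full(len(mat.probe_ids), n, dtype=int),
                "p": pval,
            }
        )
    )
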