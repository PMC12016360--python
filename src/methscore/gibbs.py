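"""Spike-and-slab Gibbs sampler over summary statistics with a block prior.

The model is the point-normal ("spike-and-slab") prior of summary-statistic
polygenic-score methods, transplanted to methylation probes: each probe's
standardized effect is

    beta_j = 0                   with probability 1 - p,
    beta_j ~ Normal(0, sigma^2)  with probability p,   sigma^2 = h2 / (M p),

where M is the number of probes, p the polygenicity and h2 the total
variance explained.  The observed data are standardized marginal effects
``beta_hat_j`` with sampling variance ~ 1/n_j, and the probe-probe
correlation structure R enters as a block-diagonal prior built from one of
the structural clusterings (CMR / sliding window / TAD / random).

The "auto" scheme infers h2 and p internally: after every sweep the
polygenicity is redrawn from its Beta conditional and the heritability is
updated deterministically as beta' R beta (computed blockwise), floored at
``h2_floor`` so the scale parameter stays positive.  A closed-form
infinitesimal solver (all probes causal, Gaussian prior) doubles as a
deterministic oracle and fallback.

Usage follows the statsmodels convention::

    model = MethylationScoreModel.from_summary_stats(stats, R)
    res = model.fit(GibbsConfig(seed=7))
    print(res.summary())
    scores = res.score(test_matrix)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .blockcorr import BlockCorrelationMatrix
from .io import SummaryStatsTable, ValidationError

__all__ = [
    "StandardizedEffects",
    "GibbsConfig",
    "GibbsDivergenceError",
    "MethylationScoreModel",
    "MethylationScoreResults",
    "standardize_effects",
    "estimate_h2_init",
    "simulate_standardized_effects",
]


class GibbsDivergenceError(RuntimeError):
    """The chain diverged (an effect exceeded the configured bound).

    Typically caused by an ill-conditioned correlation block; see
    :func:`methscore.blockcorr.conditioning_report` and
    :func:`methscore.blockcorr.regularize_blocks`.
    """


@dataclass(frozen=True)
class StandardizedEffects:
    """Standardized marginal effects aligned to a correlation matrix.

    ``beta_hat_std_j = (beta_j / se_j) / sqrt(n_j)`` — the z-score over
    sqrt(n), i.e. the sample correlation scale with sampling variance
    approximately 1/n_j.
    """

    probe_ids: list[str]
    beta_hat_std: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.beta_hat_std, float)
        n = np.asarray(self.n, float)
        object.__setattr__(self, "beta_hat_std", b)
        object.__setattr__(self, "n", n)
        if not (len(self.probe_ids) == b.size == n.size):
            raise ValidationError("misaligned standardized-effect fields")
        if not np.all(np.isfinite(b)):
            bad = self.probe_ids[int(np.flatnonzero(~np.isfinite(b))[0])]
            raise ValidationError(f"non-finite standardized effect for probe {bad!r}")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def reorder(self, probe_ids) -> "StandardizedEffects":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        rows = np.array([idx[p] for p in probe_ids])
        return StandardizedEffects(list(probe_ids), self.beta_hat_std[rows], self.n[rows])


def standardize_effects(stats: SummaryStatsTable) -> StandardizedEffects:
    """Convert marginal (beta, se, n) rows to the standardized scale."""
    df = stats.frame
    beta_std = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) / np.sqrt(
        df["n"].to_numpy(float)
    )
    return StandardizedEffects(stats.probe_ids, beta_std, df["n"].to_numpy(float))


def estimate_h2_init(eff: StandardizedEffects, R: BlockCorrelationMatrix) -> float:
    """Moment (LD-score-regression-style) estimate of total h2.

    With chi2_j = n_j * beta_hat_std_j^2 and l_j = sum_k R_jk^2 (the probe's
    within-block score), returns M * (mean(chi2) - 1) / (mean(n) * mean(l)).
    The estimate is allowed to be <= 0 — a real failure mode on weak or
    ill-conditioned data — in which case the sampler demands an explicit
    ``h2_init`` override.
    """
    eff = eff.reorder(R.probe_order)
    chi2 = eff.n * eff.beta_hat_std**2
    ell = np.concatenate([(blk**2).sum(axis=1) for _, blk in R.blocks])
    m = len(eff)
    return float(m * (chi2.mean() - 1.0) / (eff.n.mean() * ell.mean()))


def simulate_standardized_effects(
    R: BlockCorrelationMatrix,
    h2: float,
    p: float,
    n: int,
    seed: int,
) -> tuple[StandardizedEffects, np.ndarray]:
    """Draw summary statistics from the model's own generative process.

    True effects follow the point-normal prior (round(p M) causal probes,
    slab variance h2 / (M p)); the observed standardized marginals are

        beta_hat ~ Normal(R beta, R / n)

    blockwise, the standard sampling model for marginal effects under a
    correlation structure R.  This is the reference process for parameter
    recovery: the "true h2" here lives on the same (standardized-effect)
    scale the sampler infers, unlike a dichotomized phenotype, where
    liability-threshold attenuation shrinks the observable value.

    Returns the effects object and the true beta vector in R's probe order.
    """
    rng = np.random.default_rng(seed)
    m = R.n_probes
    beta = np.zeros(m)
    n_causal = int(np.round(p * m))
    if n_causal > 0 and h2 > 0:
        causal = rng.choice(m, size=n_causal, replace=False)
        beta[causal] = rng.standard_normal(n_causal) * np.sqrt(h2 / (m * p))
    beta_hat = np.empty(m)
    start = 0
    for pids, blk in R.blocks:
        stop = start + len(pids)
        # symmetric square root is robust to the near-singular blocks a
        # compound-symmetric or empirical R can produce
        w, v = np.linalg.eigh(blk)
        root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
        noise = root @ rng.standard_normal(len(pids)) / np.sqrt(n)
        beta_hat[start:stop] = blk @ beta[start:stop] + noise
        start = stop
    eff = StandardizedEffects(R.probe_order, beta_hat, np.full(m, float(n)))
    return eff, beta


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler settings.

    burn_in / n_iter
        Discarded and retained sweeps; chains have length ``n_iter``.
    p_init
        Initial polygenicity in (0, 1].
    h2_init
        Optional explicit initial heritability; overrides the moment
        estimate.  Required when the estimate is non-positive (the
        conventional override value is 1e-5).
    h2_floor
        Lower clamp keeping sigma^2 positive; default 1e-5.
    clamp
        "init": floor applies as the running minimum of the chain;
        "chain": the chain is additionally floored at the initial h2.
    fix_p / fix_h2
        Freeze a hyperparameter at its initial value (used for oracle
        comparisons against the infinitesimal solver).
    beta_bound
        Divergence guard on |beta_j| (standardized effects are O(1), so a
        generous bound only trips on genuine divergence).
    sparse_output
        If set, exports keep only probes with nonzero posterior mean.
    """

    burn_in: int = 500
    n_iter: int = 500
    p_init: float = 0.1
    h2_init: float | None = None
    h2_floor: float = 1e-5
    seed: int = 0
    clamp: str = "init"
    fix_p: bool = False
    fix_h2: bool = False
    beta_bound: float = 50.0
    sparse_output: bool = False

    def __post_init__(self):
        if self.burn_in < 1 or self.n_iter < 1:
            raise ValueError("burn_in and n_iter must be >= 1")
        if not 0 < self.p_init <= 1:
            raise ValueError("p_init must be in (0, 1]")
        if self.h2_floor <= 0:
            raise ValueError("h2_floor must be > 0")
        if self.clamp not in ("init", "chain"):
            raise ValueError("clamp must be 'init' or 'chain'")


@dataclass(frozen=True)
class MethylationScoreResults:
    """Posterior effects plus hyperparameter chains and diagnostics."""

    probe_ids: list[str]
    beta_post: np.ndarray
    p_chain: np.ndarray
    h2_chain: np.ndarray
    inclusion_rate: np.ndarray  # per-probe fraction of retained sweeps with beta != 0
    method: str
    config: GibbsConfig | None = None
    h2_init_used: float | None = None

    @property
    def h2_posterior_mean(self) -> float:
        return float(np.mean(self.h2_chain))

    @property
    def p_posterior_mean(self) -> float:
        return float(np.mean(self.p_chain))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "beta_post": self.beta_post,
                "inclusion_rate": self.inclusion_rate,
            }
        )
        if self.config is not None and self.config.sparse_output:
            df = df[df["beta_post"] != 0.0].reset_index(drop=True)
        return df

    def chains_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sweep": np.arange(len(self.h2_chain)),
                "h2": self.h2_chain,
                "p": self.p_chain,
            }
        )

    def score(self, mat):
        """Per-sample methylation scores S = M' B on a test matrix."""
        from .scoring import compute_scores

        return compute_scores(mat, self)

    def plot_chains(self, path=None):
        """Trace plot of the h2 and p chains (saved to ``path`` if given)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
        axes[0].plot(self.h2_chain, lw=0.7)
        axes[0].set_ylabel("h2")
        axes[1].plot(self.p_chain, lw=0.7, color="darkorange")
        axes[1].set_ylabel("p")
        axes[1].set_xlabel("retained sweep")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        lines = [
            "Methylation score posterior effects",
            "===================================",
            f"method:            {self.method}",
            f"probes (M):        {len(self.probe_ids)}",
            f"nonzero beta_post: {int(np.count_nonzero(self.beta_post))}",
            f"posterior mean h2: {self.h2_posterior_mean:.6g}",
            f"posterior mean p:  {self.p_posterior_mean:.6g}",
        ]
        if self.h2_init_used is not None:
            lines.append(f"initial h2:        {self.h2_init_used:.6g}")
        if self.config is not None:
            lines.append(
                f"sweeps:            {self.config.burn_in} burn-in + {self.config.n_iter} retained"
            )
            lines.append(f"seed:              {self.config.seed}")
        return "\n".join(lines)


class MethylationScoreModel:
    """Summary-statistic methylation-score model with a block correlation prior.

    Parameters
    ----------
    effects
        Standardized marginal effects; reordered internally to match the
        correlation matrix's canonical probe order.
    R
        Block-diagonal probe-probe correlation matrix.
    """

    def __init__(self, effects: StandardizedEffects, R: BlockCorrelationMatrix):
        if set(effects.probe_ids) != set(R.probe_order):
            diff = set(effects.probe_ids) ^ set(R.probe_order)
            raise ValidationError(
                f"effects and correlation matrix cover different probes "
                f"(symmetric difference size {len(diff)})"
            )
        self.effects = effects.reorder(R.probe_order)
        self.R = R
        self._groups = self._group_blocks(R)

    @classmethod
    def from_summary_stats(cls, stats: SummaryStatsTable, R: BlockCorrelationMatrix):
        return cls(standardize_effects(stats), R)

    @staticmethod
    def _group_blocks(R: BlockCorrelationMatrix):
        """Stack same-size blocks into (indices, R-tensor) groups.

        Blocks are conditionally independent given (p, h2), so they can be
        updated in any order within a sweep; grouping lets the sweep run as
        a handful of vectorized operations.  Randomness is indexed by
        canonical probe position (not processing order), so the result is
        bit-identical under any block ordering.
        """
        start = 0
        by_size: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
        for pids, blk in R.blocks:
            k = len(pids)
            by_size.setdefault(k, []).append((np.arange(start, start + k), blk))
            start += k
        groups = []
        for k in sorted(by_size):
            idx = np.stack([i for i, _ in by_size[k]])
            mats = np.stack([b for _, b in by_size[k]])
            groups.append((idx, mats))
        return groups

    # -- estimation ---------------------------------------------------------

    def estimate_h2(self) -> float:
        return estimate_h2_init(self.effects, self.R)

    def fit(self, config: GibbsConfig | None = None, **overrides) -> MethylationScoreResults:
        """Run the spike-and-slab Gibbs sampler with internal (h2, p) inference."""
        cfg = replace(config or GibbsConfig(), **overrides)
        m = len(self.effects)
        beta_hat = self.effects.beta_hat_std
        n = self.effects.n

        h2_0 = cfg.h2_init if cfg.h2_init is not None else self.estimate_h2()
        if h2_0 <= 0:
            raise ValidationError(
                f"initial h2 estimate is non-positive ({h2_0:.3g}); supply an explicit "
                "h2_init override (conventionally 1e-5) or abort"
            )
        floor = cfg.h2_floor if cfg.clamp == "init" else max(cfg.h2_floor, h2_0)
        h2 = max(h2_0, cfg.h2_floor)
        p = cfg.p_init

        rng = np.random.default_rng(cfg.seed)
        beta = np.zeros(m)
        beta_sum = np.zeros(m)
        incl_sum = np.zeros(m)
        p_chain = np.empty(cfg.n_iter)
        h2_chain = np.empty(cfg.n_iter)
        # randomness is keyed to probe identity (lexicographic rank), not to
        # position, so the chain is bit-identical under block reordering
        id_order = np.argsort(np.array(self.effects.probe_ids))
        u = np.empty(m)
        z = np.empty(m)

        total = cfg.burn_in + cfg.n_iter
        for sweep in range(total):
            u[id_order] = rng.random(m)
            z[id_order] = rng.standard_normal(m)
            sigma2 = h2 / (m * p)
            self._sweep(beta, beta_hat, n, u, z, sigma2, p)
            if np.max(np.abs(beta)) > cfg.beta_bound:
                raise GibbsDivergenceError(
                    f"effect magnitude exceeded {cfg.beta_bound} at sweep {sweep}; "
                    "the correlation matrix is likely ill-conditioned "
                    "(see conditioning_report / regularize_blocks)"
                )
            m_c = int(np.count_nonzero(beta))
            if not cfg.fix_p:
                p = float(rng.beta(1 + m_c, 1 + m - m_c))
                p = min(max(p, 1e-12), 1.0)
            if not cfg.fix_h2:
                h2 = max(self._h2_update(beta), floor)
            if sweep >= cfg.burn_in:
                t = sweep - cfg.burn_in
                p_chain[t] = p
                h2_chain[t] = h2
                beta_sum += beta
                incl_sum += beta != 0
        return MethylationScoreResults(
            probe_ids=list(self.effects.probe_ids),
            beta_post=beta_sum / cfg.n_iter,
            p_chain=p_chain,
            h2_chain=h2_chain,
            inclusion_rate=incl_sum / cfg.n_iter,
            method="gibbs-auto",
            config=cfg,
            h2_init_used=h2_0,
        )

    def _h2_update(self, beta):
        """beta' R beta, blockwise; summed with fsum so the result does not
        depend on block ordering (needed for bit-exact reorder invariance)."""
        import math

        contribs = []
        for idx, mats in self._groups:
            if idx.shape[1] == 1:
                contribs.extend(beta[idx[:, 0]] ** 2)
            else:
                seg = beta[idx]
                contribs.extend(np.einsum("bi,bij,bj->b", seg, mats, seg))
        return math.fsum(contribs)

    def _sweep(self, beta, beta_hat, n, u, z, sigma2, p):
        """One Gibbs sweep over all probes, block-local residual updates."""
        for idx, mats in self._groups:
            k = idx.shape[1]
            if k == 1:
                j = idx[:, 0]
                self._update(beta, beta_hat, n, u, z, sigma2, p, j, None, None, None)
                continue
            beta_g = beta[idx]
            for i in range(k):
                j = idx[:, i]
                self._update(beta, beta_hat, n, u, z, sigma2, p, j, mats, beta_g, i)
            beta[idx] = beta_g

    @staticmethod
    def _update(beta, beta_hat, n, u, z, sigma2, p, j, mats, beta_g, i):
        if mats is None:
            btilde = beta_hat[j]
        else:
            r_i = mats[:, i, :]
            btilde = beta_hat[j] - np.einsum("bk,bk->b", r_i, beta_g) + beta_g[:, i]
        nj = n[j]
        a = nj * sigma2
        shrink = a / (1.0 + a)
        post_mean = btilde * shrink
        post_sd = np.sqrt(shrink / nj)
        log_bf = 0.5 * btilde**2 * nj * shrink  # btilde^2 n^2 sigma^2 / (1 + n sigma^2) / 2
        odds = ((1.0 - p) / p) * np.sqrt(1.0 + a) * np.exp(-log_bf)
        pbar = 1.0 / (1.0 + odds)
        draw = np.where(u[j] < pbar, post_mean + post_sd * z[j], 0.0)
        if mats is None:
            beta[j] = draw
        else:
            beta_g[:, i] = draw

    def fit_infinitesimal(self, h2: float) -> MethylationScoreResults:
        """Closed-form posterior means under the all-causal Gaussian prior.

        Solves, per block, (R + (M / (n_bar h2)) I) beta = beta_hat, where
        n_bar is the mean per-probe sample size.  Deterministic; serves as
        the oracle and fallback for the sampler.
        """
        if h2 <= 0:
            raise ValueError("h2 must be > 0")
        m = len(self.effects)
        lam = m / (self.effects.n.mean() * h2)
        beta_hat = self.effects.beta_hat_std
        out = np.empty(m)
        start = 0
        for pids, blk in self.R.blocks:
            stop = start + len(pids)
            a = blk + lam * np.eye(len(pids))
            try:
                out[start:stop] = np.linalg.solve(a, beta_hat[start:stop])
            except np.linalg.LinAlgError as exc:
                raise ValidationError(
                    f"singular infinitesimal system in block starting at {pids[0]!r}"
                ) from exc
            start = stop
        return MethylationScoreResults(
            probe_ids=list(self.effects.probe_ids),
            beta_post=out,
            p_chain=np.array([1.0]),
            h2_chain=np.array([h2]),
            inclusion_rate=np.ones(m),
            method="infinitesimal",
            h2_init_used=h2,
        )
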