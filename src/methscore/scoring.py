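"""Score computation S = M'B and logistic-regression evaluation.

A methylation score is the per-sample weighted sum of methylation levels,
weights being either posterior effects from the Gibbs sampler or raw
marginal effects (for the clump+threshold baseline).  Scores are judged by
logistic regression of case/control status on the score: the Wald p-value
of the score coefficient, Nagelkerke's pseudo-R2, and the model AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .clustering import ClusterSet
from .io import MethylationMatrix, PhenotypeTable, SummaryStatsTable, ValidationError

__all__ = [
    "EvaluationResult",
    "compute_scores",
    "evaluate_scores",
    "nagelkerke_r2",
    "clump_threshold_baseline",
]


def nagelkerke_r2(ll0: float, ll1: float, n: int) -> float:
    """Nagelkerke's rescaled pseudo-R2 from the two log-likelihoods.

    Exactly zero when ll1 == ll0.
    """
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    return float(cox_snell / (1.0 - np.exp(2.0 * ll0 / n)))


@dataclass(frozen=True)
class EvaluationResult:
    """Logistic-regression evaluation of a score against a binary phenotype."""

    nagelkerke_r2: float
    wald_p: float
    aic: float
    n_samples: int
    n_cases: int
    lr_p: float  # likelihood-ratio p, logged alongside the Wald p
    separation_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "nagelkerke_r2": self.nagelkerke_r2,
            "wald_p": self.wald_p,
            "aic": self.aic,
            "n_samples": self.n_samples,
            "n_cases": self.n_cases,
            "lr_p": self.lr_p,
            "separation_flag": self.separation_flag,
        }


def compute_scores(mat: MethylationMatrix, eff) -> pd.DataFrame:
    """Per-sample scores S = M' B.

    ``eff`` is anything carrying aligned ``probe_ids`` and ``beta_post``
    (e.g. a :class:`~methscore.gibbs.MethylationScoreResults`).  The matrix
    must cover exactly the effect probes; a mismatch reports the symmetric
    difference.
    """
    beta = np.asarray(eff.beta_post, float)
    if set(mat.probe_ids) != set(eff.probe_ids):
        diff = sorted(set(mat.probe_ids) ^ set(eff.probe_ids))
        raise ValidationError(
            f"matrix and effects cover different probes; symmetric difference "
            f"({len(diff)}): {diff[:10]}{'...' if len(diff) > 10 else ''}"
        )
    mat = mat.subset(list(eff.probe_ids))
    scores = mat.values.T @ beta
    return pd.DataFrame({"sample_id": mat.sample_ids, "score": scores})


def evaluate_scores(scores: pd.DataFrame, pheno: PhenotypeTable) -> EvaluationResult:
    """Fit logit(Pr(y=1)) = a + b * score and report Wald p, Nagelkerke R2, AIC.

    Nagelkerke R2 rescales the Cox-Snell pseudo-R2 to [0, 1]:

        R2 = [1 - exp(2 (l0 - l1) / n)] / [1 - exp(2 l0 / n)],

    with l0 the intercept-only and l1 the fitted log-likelihood.  AIC uses
    k = 2 parameters (intercept + score).  Complete separation is flagged
    (R2 reported as 1 - eps with a warning) rather than raised.
    """
    pheno_samples = set(pheno.sample_ids)
    common = [s for s in scores["sample_id"] if s in pheno_samples]
    if not common:
        raise ValidationError("no samples shared between scores and phenotypes")
    sc = scores.set_index("sample_id").loc[common, "score"].to_numpy(float)
    y = pheno.subset(common).frame["y"].to_numpy(int)
    n = len(y)
    n_cases = int(y.sum())
    if n_cases < 2 or n - n_cases < 2:
        raise ValidationError("need >= 2 samples per class for evaluation")

    x = sm.add_constant(sc)
    null_x = np.ones((n, 1))
    ll0 = float(sm.Logit(y, null_x).fit(disp=0).llf)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, x).fit(disp=0)
        ll1 = float(fit.llf)
        wald_p = float(fit.pvalues[1])
        separated = not np.isfinite(fit.bse[1])
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separated = True
        ll1 = -1e-9  # saturated fit: likelihood -> 1
        wald_p = np.nan
    if separated:
        warnings.warn("complete separation: score perfectly predicts phenotype", stacklevel=2)
        eps = 1e-9
        return EvaluationResult(
            nagelkerke_r2=1.0 - eps,
            wald_p=np.nan if not np.isfinite(wald_p) else wald_p,
            aic=4.0 - 2.0 * ll1,
            n_samples=n,
            n_cases=n_cases,
            lr_p=0.0,
            separation_flag=True,
        )
    r2 = nagelkerke_r2(ll0, ll1, n)
    from scipy import stats as sps

    lr_stat = 2.0 * (ll1 - ll0)
    lr_p = float(sps.chi2.sf(max(lr_stat, 0.0), df=1))
    return EvaluationResult(
        nagelkerke_r2=r2,
        wald_p=wald_p,
        aic=2.0 * 2 - 2.0 * ll1,
        n_samples=n,
        n_cases=n_cases,
        lr_p=lr_p,
    )


def clump_threshold_baseline(
    stats: SummaryStatsTable,
    mat: MethylationMatrix,
    cs: ClusterSet,
    r2_prune: float,
    p_thresh: float,
) -> pd.DataFrame:
    """Pruning-and-thresholding comparator scored with raw marginal effects.

    Within each cluster, probes are visited by ascending p-value (ties by
    probe id); a probe is kept unless its squared correlation with an
    already-kept probe reaches ``r2_prune``.  Survivors with p <= p_thresh
    are scored via :func:`compute_scores` using the raw beta.
    """
    if not 0 < r2_prune <= 1 or not 0 < p_thresh <= 1:
        raise ValueError("r2_prune and p_thresh must be in (0, 1]")
    df = stats.frame.set_index("probe_id")
    row_idx = {p: i for i, p in enumerate(mat.probe_ids)}
    r_thresh = np.sqrt(r2_prune)
    kept: list[str] = []
    for members in cs.members():
        ranked = sorted(members, key=lambda p: (df.loc[p, "p"], p))
        kept_rows: list[np.ndarray] = []
        for pid in ranked:
            row = mat.values[row_idx[pid]]
            pruned = any(abs(_corr(row, kr)) >= r_thresh for kr in kept_rows)
            if not pruned:
                kept.append(pid)
                kept_rows.append(row)
    survivors = [p for p in kept if df.loc[p, "p"] <= p_thresh]
    if not survivors:
        raise ValidationError(
            "no probes survive clumping + thresholding; loosen r2_prune or p_thresh"
        )
    survivors = [p for p in mat.probe_ids if p in set(survivors)]  # canonical order

    class _RawEffects:
        probe_ids = survivors
        beta_post = df.loc[survivors, "beta"].to_numpy(float)

    return compute_scores(mat.subset(survivors), _RawEffects())


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float((xc @ yc) / denom)
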