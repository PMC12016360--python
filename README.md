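# methscore

Methylation risk scores from MWAS summary statistics, using a
spike-and-slab Gibbs sampler with structural correlation priors.

## The problem

A methylome-wide association study (MWAS) yields one marginal effect per
array probe. A methylation score (MS) compresses these into a single
per-individual predictor, `S = Mᵀβ`, where `M` is the (probes × samples)
matrix of residualized methylation levels and `β` a vector of per-probe
weights — the methylation analogue of a polygenic risk score (PRS).

The best PRS weighting methods regularize the marginal effects jointly
using a correlation reference (linkage disequilibrium, LD). Methylation has
no LD, so a substitute structure is needed. This package implements the
whole pipeline around that substitution, for methods researchers working on
epigenetic prediction:

* **structural priors** partitioning probes into correlation blocks:
  co-methylated regions (CMR: proximity + correlation chaining with the
  `corlo` / `maxprbdst` / `corlodst` knobs), pure genomic **sliding
  windows** (5 kb – 1 Mb), **topologically associating domains** (TADs,
  from a BED scaffold), and **random clusters** as a structure-free null
  (cluster counts ~ Normal(2880, 144), sizes ~ LogNormal(log 82, 0.7));
* a sparse **block-diagonal Pearson correlation matrix** `R` built from the
  within-cluster probe correlations, with conditioning diagnostics and
  optional shrinkage toward the identity;
* the **spike-and-slab ("point-normal") Gibbs sampler** over standardized
  marginal effects, inferring the hyperparameters internally ("auto"
  scheme): per probe `β_j = 0` with probability `1 − p`, else
  `β_j ~ N(0, h²/(M p))`; after each sweep `p` is redrawn from its Beta
  conditional and `h²` is updated as `βᵀRβ`. A closed-form infinitesimal
  solver is provided as oracle and fallback;
* **scoring and evaluation**: `S = Mᵀβ̂`, then logistic regression of
  case/control status on the score, reporting the Wald p-value,
  Nagelkerke's pseudo-R² and AIC, plus a clump+threshold (P + T) baseline;
* a **synthetic-study generator** (block-correlated methylation, sparse
  liability effects, liability-threshold binary phenotype, training-cohort
  MWAS) so every stage is testable without any download.

## Worked example

```python
from methscore import *

cfg = SimConfig(m_probes=2000, n_train=5000, n_test=1000, block_size=10,
                rho=0.5, h2_true=0.3, p_true=0.02, prevalence=0.4, seed=42)
study = generate_study(cfg)

cs = sliding_window_clusters(study.annotation, window=2000)
R = build_block_correlation(study.test_matrix, cs)

model = MethylationScoreModel.from_summary_stats(study.summary, R)
res = model.fit(GibbsConfig(seed=42))
print(res.summary())

scores = res.score(study.test_matrix)
ev = evaluate_scores(scores, study.test_phenotypes)
print(f"p={ev.wald_p:.3g}  NagelkerkeR2={ev.nagelkerke_r2:.4f}  AIC={ev.aic:.1f}")
```

prints

```
Methylation score posterior effects
===================================
method:            gibbs-auto
probes (M):        2000
nonzero beta_post: 2000
posterior mean h2: 0.0950949
posterior mean p:  0.0342286
initial h2:        0.097011
sweeps:            500 burn-in + 500 retained
seed:              42

p=9.53e-16  NagelkerkeR2=0.0948  AIC=1261.8
```

The posterior `h²` (~0.10) is the variance the score explains on the
*observed* binary scale; it is smaller than the generating liability-scale
`h² = 0.3` because dichotomizing the liability at 40% prevalence attenuates
observable effects (see `docs/methods.md`). The score nonetheless separates
cases strongly: Nagelkerke R² ≈ 0.095 with Wald p ≈ 1e-15 on 1,000 held-out
samples.

The same comparison can be driven from the shell:

```bash
methscore simulate --m-probes 2000 --seed 42 --out-dir study/
methscore all --config session.yaml    # priors: cmr | window:<bp> | tad | random:<k> | baseline-pt
```

which emits a per-model report (`model`, `p_value`, `nagelkerke_r2`, `aic`,
`pct_probes_clustered`).

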