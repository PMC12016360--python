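# Methods

## Model

The sampler operates on *standardized* marginal effects
`β̂_j = (b_j / se_j) / √n_j` (the per-probe z-score over √n), which have
sampling variance ≈ 1/n_j and, for weak effects, equal the sample
correlation between the standardized probe and the phenotype. The prior is
point-normal ("spike-and-slab"): with polygenicity `p` and total variance
explained `h²`,

    β_j = 0                  with probability 1 − p,
    β_j ~ N(0, σ²),  σ² = h² / (M p),   otherwise.

Probe-probe correlation enters through a block-diagonal matrix `R`
(within-cluster Pearson correlations; cross-cluster entries are structural
zeros). One Gibbs sweep visits every probe in canonical order within its
block and samples from the exact single-site conditional:

    β̃_j  = β̂_j − Σ_{k≠j, same block} R_jk β_k          (residual)
    a_j  = n_j σ²
    P(include) = 1 / (1 + ((1−p)/p) √(1+a_j) · exp(−½ β̃_j² n_j a_j/(1+a_j)))
    β_j | include ~ N( β̃_j a_j/(1+a_j),  (1/n_j) a_j/(1+a_j) )

After each sweep the hyperparameters update ("auto" scheme): `p ~
Beta(1 + M_c, 1 + M − M_c)` with `M_c` the number of nonzero effects, and
`h² = βᵀRβ` computed blockwise — a deterministic update, which keeps the
scheme cheap and reproducible. The reported effects are the posterior means
over the retained sweeps.

The infinitesimal solver (`fit_infinitesimal`) is the `p = 1` Gaussian
limit in closed form: per block it solves `(R + (M/(n̄ h²)) I) β = β̂` with
`n̄` the mean per-probe sample size (per-probe `n` is collapsed to its mean
here — a documented approximation; the sampler itself uses per-probe `n`).
With `p` fixed at 1 and `h²` fixed, the sampler's stationary mean equals
this solution, which is how the two routes cross-check each other.

## Hyperparameter initialization and the negative-h² failure mode

The initial `h²` is a moment estimate in the LD-score-regression style:
with `χ²_j = n_j β̂_j²` and `ℓ_j = Σ_k R_jk²`,

    ĥ² = M (mean(χ²) − 1) / (mean(n) · mean(ℓ)).

On null or ill-conditioned data this estimate is legitimately ≤ 0 — a real
failure mode of block-correlation pipelines, reproduced here on purpose.
Since a non-positive `h²` is not admissible in the sampler, `fit()` then
refuses to run unless an explicit `h2_init` override is supplied; the
conventional override is `1e-5`, which is also the default `h2_floor`.
Two clamping policies are exposed because the choice is genuinely open:
`clamp="init"` (default) floors the running chain at `h2_floor` only, while
`clamp="chain"` additionally floors it at the initial value. In both modes
every recorded `h²` is ≥ `h2_floor`, keeping `σ² > 0` throughout.

A divergence guard aborts the run (naming the sweep) if any |β_j| exceeds
`beta_bound` (default 50 on the standardized scale, where honest effects
are O(1)); this is the signature of a near-singular correlation block.
`conditioning_report` flags blocks with minimum eigenvalue below 1e-8, and
`regularize_blocks` shrinks blocks toward the identity
(`B → (1−s)B + sI`); shrinkage is off by default, since the conventional
remedy is the `h²` override rather than modifying `R`.

## Structural priors

* **Sliding windows** — per chromosome, position-sorted probes chain while
  consecutive gaps are ≤ the window; standard sizes 5 kb, 10 kb, 20 kb,
  100 kb, 500 kb, 1 Mb.
* **CMR** — the same chain requires additionally adjacent-pair Pearson
  correlation ≥ `corlo` (defaults: `corlo` 0.2, `maxprbdst` 100,000 bp,
  `corlodst` 800 bp) and, when a reference CpG map is supplied, every
  inter-probe CpG gap ≤ `corlodst`. This three-predicate chaining is a
  documented approximation of the full published CMR algorithm, which also
  tracks unmeasured-CpG density; only the three knobs above are modeled.
  A threshold ≤ 1e-9 disables the correlation predicate entirely, so the
  conventional bypass value 1e-10 degenerates the construction *exactly*
  into the sliding window — a signed `r ≥ 1e-10` test would still split
  the occasional negatively-correlated neighbors. Zero-variance rows have
  undefined correlation and conservatively fail the predicate (at real
  thresholds). Whether correlations should be tested between all pairs in
  a candidate region rather than adjacent pairs is open; adjacent-pair
  chaining is implemented.
* **TADs** — each probe joins the interval containing its 0-based position
  (BED half-open convention; probe annotations are 1-based, so position
  `pos − 1` is tested). Probes in no interval become singletons; probes in
  several go to the interval with the smallest start, ties broken by the
  smaller end.
* **Random clusters** — the null: cluster count C ~ Normal(2880, 144)
  (rounded; non-positive draws resampled), target sizes ~
  LogNormal(log 82, 0.7) (rounded, clamped ≥ 1), and a single random
  permutation of the probes cut according to the drawn sizes. Overshoot
  truncates the tail clusters; undershoot leaves the remaining probes as
  singletons — one consistent reading of an underdetermined step.
  Chromosome coherence is deliberately *not* enforced: a null model must
  carry no genomic structure. Each of the sets uses stream `seed + k`, so
  individual sets are reproducible in isolation.

`drop_singletons` removes probes in size-1 clusters (which contribute no
off-diagonal correlation) and shrinks the analysis universe accordingly;
correlations are recomputed on the reduced universe, which for Pearson
blocks is identical to subsetting the original matrix.

## Synthetic studies

`generate_study` emulates the data the pipeline consumes: probes at regular
spacing in blocks separated by a 10× larger gap (so a window between the
two spacings recovers the true blocks exactly); methylation drawn as
standardized Gaussians with block-compound-symmetric correlation `rho` —
residualized methylation is effectively unbounded, so no [0, 1] beta-value
clamp is applied; a causal set of exactly `round(p·M)` probes with
`N(0, h²/(M p))` effects; liability `Σ xβ + e`, `e ~ N(0, 1 − h²)`,
thresholded at the theoretical `(1 − prevalence)` quantile; and per-probe
marginal statistics from an OLS scan of the binary phenotype on each
standardized training probe (linear, not logistic, consistent with the
standardized-effect bridge). Training and test cohorts are independent
given the config, and the same seed reproduces byte-identical files.

What the generator does *not* emulate: cell-type composition, batch
effects, the residualization step itself, bounded beta-value noise, or
array-specific probe density. Passing tests therefore demonstrate
correctness of the algorithms under the assumed statistical structure, not
robustness to those real-data artifacts.

### Scale of h² under a binary phenotype

Dichotomizing a liability at prevalence K attenuates every observable
marginal correlation by `φ(t)/√(K(1−K))` (t the threshold), so the
variance a score can explain on the observed 0/1 scale is roughly
`φ(t)²/(K(1−K))` ≈ 0.62 (at K = 0.4) times the liability-scale h². The
sampler and the moment estimator are consistent on the observed scale —
the worked example recovers ≈ 0.10 from data generated at liability
h² = 0.3. Parameter-recovery tests therefore draw summary statistics from
the summary-statistic model itself (`simulate_standardized_effects`:
`β̂ ~ N(Rβ, R/n)` blockwise), where the generating h² lives on the same
scale the sampler infers.

## Numerical and design choices

* Sampler defaults: 500 burn-in + 500 retained sweeps, `p_init` 0.1, seed
  required in the CLI. These are package-level choices; chain export and
  trace plots are provided for convergence inspection.
* Per-sweep uniforms and normals are pre-drawn keyed to probe *identity*
  (lexicographic rank), and the `h²` quadratic form is accumulated with
  exact summation, so results are bit-identical under any reordering of
  the correlation blocks. Same-size blocks are updated as stacked tensors;
  blocks are conditionally independent given (p, h²), making this exact.
* Canonical probe order is (normalized chromosome, position, probe id);
  probes at identical positions order lexicographically by id.
* Evaluation fits `logit P(y=1) = a + b·S` by ML (statsmodels). The
  reported p-value is the Wald test on `b` (a likelihood-ratio p is also
  recorded); AIC uses k = 2; Nagelkerke R² rescales Cox–Snell by its
  maximum. Complete separation is flagged (R² reported as 1 − 1e-9 with a
  warning) rather than raised. Test methylation is used as-is — the
  pipeline assumes it was residualized upstream; no covariate adjustment
  is performed.
* The clump+threshold baseline keeps, per cluster, probes in ascending
  p-value order, dropping any whose |r| with an already-kept probe is
  ≥ √(r²-threshold) (inclusive, so duplicate probes always prune), then
  applies the p-value cutoff and scores with raw marginal betas.
* Correlation blocks are built from the scoring (test) matrix by default,
  mirroring common practice and its acknowledged leakage; an independent
  reference matrix can be supplied (`corr_matrix` in the session config).

## Problem sizes

The default test-suite and acceptance runs use m = 2,000 probes with
training/test cohorts of 5,000/1,000 (the end-to-end and recovery checks)
and smaller instances elsewhere; these sizes give stable Monte-Carlo
behavior while keeping a full run in tens of seconds on one CPU. The
implementation itself scales to array-sized problems: memory grows with
the sum of squared block sizes, never with the square of the probe count.

## Known limitations

* The grid/validation-set variant of the hyperparameter search is not
  implemented (only the internal "auto" scheme).
* The CMR construction approximates the published algorithm by its three
  documented knobs; byte-exact reproduction of its CpG-density bookkeeping
  is out of scope.
* Only binary phenotypes are supported in evaluation; no covariate
  adjustment, survival or continuous outcomes.
* No genome-build liftover: TAD scaffolds must already match the probe
  annotation's build.
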