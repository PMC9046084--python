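# Methods

## Model

`cellmix` treats a bulk RNA-seq sample as a mixture of reads emitted by
cell states whose expression is known up to multinomial sampling.  Let
`X_ng` be the raw count of gene `g` in bulk sample `n` with total
`R_n`, and let `phi` be an `S x G` row-stochastic reference built from
labelled scRNA-seq: row `s` is the maximum-likelihood multinomial
profile of cell state `s` (reads summed over the state's cells, then
normalized).  Zero entries of each row are floored at `pseudo_min`
(default `1e-8`) after normalization, so every gene has nonzero
probability under every state.  The generative model per sample is

    mu_n        ~ Dirichlet(alpha)            (fractions over S states)
    R_n,s       ~ multinomial(mu_n, R_n)      (reads per state)
    U_n,s,.     ~ multinomial(phi_s, R_n,s)   (reads per gene within a state)
    X_ng        = sum_s U_nsg

with a symmetric, near-flat `alpha = 1e-8` by default.  A Gibbs sampler
alternates the two standard conditionals of the augmented model:
gene-wise assignments `U[., g] | mu, x_g` are multinomial over states
with weights proportional to `mu_s * phi_sg`, and `mu | U` is
`Dirichlet(alpha + reads per state)`.  The default schedule is 1000
sweeps, 500 discarded as burn-in, every 2nd retained; posterior means
`mu_bar` and `U_bar` are arithmetic means over retained draws.  Cell
*types* aggregate states through the surjective map `h`:
`theta0[n,t] = sum_{s: h(s)=t} mu_bar[n,s]` and likewise for the read
assignments `Z`.

Samples run as independent chains whose RNG streams derive from
`(seed, sample_index)`, so results are reproducible and independent of
processing order.  Assignments are drawn as a chain of binomials
vectorized across genes (S-1 vectorized draws per sweep instead of G
multinomial calls), which is what makes desk-scale cohorts take seconds
per sample.

## Reference update

Two regimes follow the first pass:

* **Malignant** expression varies strongly between tumours, so a
  per-sample profile `psi_mal[n] = Z[n, mal, .] / sum_g Z[n, mal, g]`
  is taken as the MLE (with the same pseudo-count floor).  Samples with
  no malignant reads fall back to the prior row with a warning.
* **Environment** (nonmalignant) types are assumed similar across
  samples, so their assigned reads are pooled over the cohort and each
  type's profile is re-estimated as the MAP of

      sum_n Z[n,t,g] log psi_tg  -  sum_g log(gamma_tg)^2 / (2 sigma^2),
      psi_tg = phi'_tg gamma_tg / sum_g phi'_tg gamma_tg,

  a multinomial likelihood under a log-normal fold-change prior centred
  on the per-type reference `phi'` (`sigma = 2` by default; `sigma -> 0`
  or no reads pins the estimate to the prior).  The optimization runs in
  unconstrained log-gamma space with an analytic gradient and a
  conjugate-gradient optimizer capped at `1e5` iterations (gradient
  tolerance `1e-8`); the normalization leaves one flat direction that
  the Gaussian prior regularizes.  The problem separates across types
  and is solved independently per type.

A per-sample reference `psi_n` (sample-specific malignant row, shared
environment rows) then replaces the prior and the same Gibbs sampler is
re-run at the type level, giving the final fractions `theta_f`.  When no
malignant type is designated, all types are pooled as environment.
Exactly one update-and-refit round is performed.

## Gene-program embedding

After deconvolution, malignant expression across a cohort is summarized
as `K` gene programs.  Bulk counts are modelled as `X ~ upsilon . zeta`
where the rows of `zeta` are `K` learned row-stochastic bases `eta`
followed by the fixed environment profiles `psi_env`, and the rows of
`upsilon` are program weights `omega` (summing per sample to the
malignant fraction `tau_n = 1 - sum_t theta_env[n,t]`) followed by the
fixed `theta_env`.  `eta` carries the same log-normal fold-change prior
relative to a prior guess `eta0`; `omega = tau * kappa` with
`kappa ~ Dirichlet(alpha)`.  EM alternates expected multinomial read
assignments with (a) the per-basis MAP update (same optimizer as
`psi_env`) and (b) the posterior mean of `omega` given expected program
counts, `omega_nk = tau_n (alpha + V_nk) / sum_k' (alpha + V_nk')`.
The tracked objective (observed-data log likelihood plus the basis
prior) must be non-decreasing; a decrease beyond `1e-8` relative raises.
The E-step never materializes the `N x M x G` tensor — only pooled
per-basis and per-(sample, basis) sums.

`eta0` comes from consensus NMF (Kullback–Leibler loss, multiplicative
updates) on normalized malignant expression: for each candidate `K`
(default grid 2–12), samples are repeatedly factorized from random
starts and co-clustered by dominant basis; the cophenetic correlation of
the consensus matrix scores stability, and the chosen `K` is the largest
one scored before the first drop exceeding 10 % of the observed score
range (the full curve is always returned so users can override).  The
final fit at the chosen `K` uses 200 random restarts (default) and
keeps the basis with minimal reconstruction error.  Rank selection uses
30 runs per `K` — enough for a stable consensus without dominating the
runtime.

## Microenvironment screens

* `rank_correlation` ranks genes by Spearman correlation (average ranks
  for ties) between per-sample-normalized malignant expression and a
  query cell type's fraction; zero-variance genes are flagged `NaN`.
* `regress_out_filter` guards against the confound where the query
  cell's own expression of a gene explains the fraction association: a
  likelihood-ratio test between nested Gaussian linear models (null:
  fraction ~ query expression; alternative: + malignant expression),
  chi-squared with 1 df.  Its type-I error is verified by simulation at
  alpha 0.01 and 0.05 rather than against any particular reference
  implementation.  Rank-deficient designs return p = 1, flagged.
* `malignant_specificity_filter` requires a gene to be expressed higher
  in at least one malignant state than in every nonmalignant type: a
  fold-change floor (default 1.5x) plus a one-sided two-proportion
  z-test on the underlying count sums, Benjamini–Hochberg corrected at
  0.05.  All thresholds are exposed.
* `signature_score` restricts to samples whose cell-type fraction
  exceeds 5 % (below that the deconvolved expression estimate is mostly
  prior), depth-normalizes, applies `log2(CPM + 1)`, and reports the
  per-sample Pearson r against each signature profile over a marker set.
  The log2 transform stands in for a variance-stabilizing transform; as
  a monotone per-gene map it leaves the correlation-based score
  essentially unchanged, and the transform used is recorded in the
  output.

## Synthetic benchmark

The generator emulates the pseudo-bulk benchmark design: state profiles
are sparse log-normal draws around a shared gene baseline (30 % of genes
silenced, log-sd 1), with states of a type mixing the type mean with a
state-specific draw at weight 0.3 so within-type correlation exceeds
between-type correlation (asserted in tests).  Cells are multinomial
draws per state (default 50 cells x 1000 reads), the reference is built
through the same code path users run on real data, and pseudo-bulks are
drawn hierarchically (reads per state multinomial in the fractions, then
genes multinomial per state), recording *realized* read fractions as
ground truth — the quantity the model actually estimates.  A cell-mixing
mode (summing resampled cells) is also provided.  The batch effect
between reference and bulk is a gene-wise multiplicative term
`exp(N(0, sigma_noise))` applied to the generating profiles with row
renormalization; `sigma_noise` defaults to 0.5, with 0/0.25/0.5/1.0 the
conventional sweep.

Benchmark cohort defaults: 4 types, one malignant with 3 states, 1000
genes, 30 samples of 50k reads, type fractions Dirichlet(1).  The
malignant-expression benchmark uses 20 samples with true purity uniform
on [0.55, 0.95] and per-sample malignant profiles perturbed at
`sigma_noise`.  These sizes keep a full two-pass run under a minute on
one CPU while leaving enough samples per type for stable per-type
correlations.

What the generator does **not** emulate: gene-length and platform
biases, dropout curves, ambient RNA, doublets, and missing cell states.
Passing benchmarks therefore demonstrate correctness of the inference
machinery under the stated noise model, not robustness to every artifact
of real data.

## Numerical choices and edge cases

* `norm_to_one` errors on all-zero rows and on `pseudo_min` too large
  for the number of zeros; nonzero entries keep their mutual
  proportions exactly.
* Real-valued (TPM-like) single-cell input is summed as-is with a
  logged warning; real-valued bulk input is rounded to counts with a
  logged warning — the model is defined on counts.
* Gene matching is by case-normalized exact id; duplicate ids error.
  Gene filtering happens before the pseudo-count floor: the reference is
  subset on raw count sums and then renormalized.
* Outlier-gene rule uses strict inequalities on both thresholds
  (> 1 % of a sample's reads in > 10 % of samples).
* The Dirichlet draw guards against an all-zero gamma vector (possible
  at near-zero shapes) by falling back to the uniform simplex point.
* Chain ergodicity: at the default near-zero `alpha` the exact
  posterior on `mu` can be multimodal, with mass split across simplex
  corners; a single chain then reports the mode it settles in rather
  than the across-mode mean.  This matters only when profiles are
  near-identical or reads are very few — in the intended operating
  regime (distinct reference profiles anchoring the states, thousands of
  reads) the posterior is effectively unimodal and seeds agree to well
  under 0.01.  Sampler-vs-enumeration calibration tests therefore run
  with a smooth Dirichlet(1) prior, where the chain is ergodic.
* EM monotonicity is asserted at `1e-8` relative tolerance; the
  `omega` posterior-mean update deviates from the exact M-step only by
  the negligible `alpha = 1e-8` perturbation.

## Known limitations

* States must be provided as labels; no clustering is performed.
* No convergence diagnostics beyond the fixed schedule; no
  marginal-likelihood computation.
* The environment update presupposes low cross-sample heterogeneity and
  presence above ~1 % in at least one sample; types never reaching 1 %
  are logged as poorly informed rather than excluded.
* Only a marker-free mode is implemented: inference always uses all
  filtered genes.
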