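# Methods

## Model

A compositional item presents *D* statements, one per latent dimension, and
the respondent splits a fixed total *C* among them. With the last slot of
each item as the additive log-ratio (ALR) reference, the lognormal ipsative
model (LIM) assumes, for person *n*, item *i* and non-reference dimension
*k*,

```
Y_nik = log(X_nik / X_niD) = (θ_nk + δ_{s(i,k)}) − (θ_nD + δ_{s(i,D)}) + ε_nik
ε_nik ~ N(0, σ²_ε)   i.i.d. over n, i, k
```

* `θ_n` — the person's trait vector, constrained to sum to zero within
  person (the ipsative constraint mirrors the fixed response total).
* `δ_s` — the utility of statement *s*; a statement may occupy slots in
  several items and keeps one utility throughout. Identification fixes the
  sum of utilities over each dimension's item slots (one term per slot, so
  repeated statements are weighted by occurrence) to zero.
* `σ²_ε` — a single noise variance shared by all persons, items and
  dimensions.

The reference slot is in principle arbitrary; we fix it to the last
dimension of every item. Because the D−1 log ratios within an item are
treated as independent (the likelihood is a product of univariate
normals), the likelihood is *not* invariant to this choice; generation and
estimation use the same convention, so the model is internally consistent.
A per-statement error decomposition would induce correlated ratio errors
within an item; we implement the i.i.d.-ratio form, and the simulator
generates data the same way.

The Thurstonian comparator (TMC) generalizes the ratio mean to
`loc_ik + β_{s(i,k)} θ_nk − β_{s(i,D)} θ_nD` with a slope per statement and
a free location per (item, non-reference slot). The LIM is the β ≡ 1,
ipsatively constrained special case.

## Priors and sampler

Priors: `δ_s ~ N(0, 1)`; the D−1 free trait coordinates
`θ_{n,−D} ~ MVN(μ, Σ)`; `μ_d ~ N(0, 1)`; `Σ ~ inverse-Wishart(I, K)` with
`K = D − 1` degrees of freedom (the smallest integer making the prior
proper for a (D−1)-dimensional scale matrix); `σ²_ε ~ inverse-gamma(1, 1)`.

Every full conditional is available in closed form, so `fit_lim` is a
blocked Gibbs sweep:

1. **Traits.** Per person, the free coordinates have a Gaussian
   conditional with precision `(I/σ²) A'A + Σ⁻¹`, `A = I + 11'` the map
   from free coordinates to reference contrasts. The precision is shared
   across persons, so one Cholesky factorization serves the whole panel.
   The reference coordinate is the negative sum, so every stored draw is
   ipsative to machine precision.
2. **Utilities.** The joint conditional of all utilities is Gaussian
   (`Λ = (N/σ²) B'B + I/s²_δ` with B the slot design matrix). The draw is
   conditioned *exactly* on the per-dimension slot-sum-zero constraint by
   Gaussian conditioning (kriging residual), which is both a valid Gibbs
   step on the constrained model and satisfies the constraint to machine
   precision — no post-hoc projection error.
3. **Noise variance.** Inverse gamma `IG(1 + nIK/2, 1 + SSR/2)`.
4. **Population mean and covariance.** Normal and inverse-Wishart
   conjugate updates.

All blocks accept with probability one; runs are bit-reproducible from
(data, design, config): per-chain generators are spawned from a single seed
sequence. The comparator's slopes are the one non-conjugate block and use
adaptive random-walk Metropolis on the log scale (lognormal(0, 0.5)
prior, adaptation toward ~0.35 acceptance, frozen after burn-in). The TMC's
identification under MCMC (unconstrained zero-mean MVN traits,
inverse-Wishart trait covariance, N(0,1) locations) is comparator
scaffolding: with equally keyed statements the model is genuinely
unidentified and its non-convergence is the reported result, not a defect
to fix.

Convergence uses the classical (non-split) Gelman–Rubin potential scale
reduction factor, `sqrt(((n−1)/n W + B/n) / W)`, per monitored scalar; it
can fall slightly below 1 and equals 1 exactly for degenerate zero-variance
chains (guarded, with a warning). Monitored by default: all utilities, the
noise variance, the population mean and covariance entries, and a seeded
random subsample of 50 trait scalars — monitoring every trait is possible
but slow at scale. A fit is "converged" when all monitored PSR fall below
the threshold (default 1.1, the usual convention; empirical runs of the
sampler sit in the 0.998–1.003 range). The convergence *rate* of a
simulation study is the fraction of replications passing this check.

## Identifiability and gauges

The likelihood sees utilities only through within-item contrasts, leaving
two invariances:

* a per-dimension shift of utilities compensated by an opposite trait
  shift (shifts summing to zero) — removed by the slot-sum-zero
  constraint;
* a per-item constant shift — removed *by the data* only when statements
  are shared across items (a connected linkage design, as in the bundled
  40-item value test). In the simulation layout each slot carries a fresh
  statement, so the item shifts are pinned solely by the N(0, 1) utility
  prior, which centres them at zero — exactly where the item-centred
  generating utilities put them.

Recovery comparisons therefore map the generating parameters into the
estimation gauge first (`gauge_align`): each dimension's utilities are
shifted to zero slot-sum and the traits absorb the opposite shift. Expected
log ratios, and hence the data distribution, are unchanged; trait
covariances are unaffected.

## Synthetic data

The generator mirrors the reference study conditions and is first-class,
tested code:

* utilities uniform on [−1.2, 1.2], centred within each item;
* normative traits MVN(0, R) with unit SDs; R either exchangeable with a
  common correlation (0.8, 0.5, 0.2, 0, −0.2) or the four-dimensional
  "real-world" matrix, which ships symmetrized from its lower triangle
  (the printed source is sign-inconsistent in one pair; the lower triangle
  yields a valid positive-definite matrix);
* ipsatization by subtracting the within-person mean — the ipsative set is
  the recovery truth;
* responses: expected log ratios plus i.i.d. N(0, σ²) noise, mapped to raw
  scores by the inverse ALR. The generating noise variance defaults to
  0.087, the scale observed when fitting a real 40-item value test; the
  default grid is 10/20/40 items × 250/500/1000 persons at D = 4.

What the generator does *not* emulate: response styles, careless or
rounded allocations (real respondents use multiples of 5), zero inflation
beyond what the noise model produces, person-specific noise variances, and
unfolding (ideal-point) response processes. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to these violations.

## Recovery metrics

Per parameter over T replications: bias `Σ_t(π̂_t − π_t)/T` and RMSE
`sqrt(Σ_t(π̂_t − π_t)²/T)`, averaged within blocks (traits, utilities,
covariances). Trait covariance entries additionally get relative bias
`Σ_t(π̂_t − π_t)/(T|π_t|)` and relative absolute bias
`Σ_t|(π̂_t − π_t)/(T π_t)|`. The truth `π_t` for a covariance entry is the
*realized* sample covariance of that replication's generated ipsative
traits (the quantity the fit can actually see); entries with |truth| below
1e−8 — e.g. under the zero-correlation condition — are excluded from
relative metrics and listed. The D×D covariance estimate extends the
posterior-mean free-coordinate covariance via `M Σ M'`, `M = [I; −1']`.
Replications failing the PSR check are excluded from the main summaries
with counts reported, and a parallel summary including them is kept.

## Zero repair and screening

Zeros make the ALR undefined. Each zero becomes κ and the nonzero entries
of the same row are multiplied by `1 − mκ/C` (m zeros in the row), which
preserves the row total exactly and the rank order of positive entries.
Default κ = 0.5, appropriate for 100-point items answered in whole points;
κ = 0.65 × (smallest possible response) is the cited alternative and can
be passed explicitly. When more than 10% of entries are zero the repair is
of doubtful validity and a warning is raised (not an error). Screening
removes respondents who allocate the full total to the *same slot position
in every item* — generalized from "all on the first statement" to any
slot, since the pattern class, not the particular slot, is the nonsense
signature — and, when completion times are supplied, respondents under 300
seconds.

## Fit diagnostics

* Fisher information of an I-item test is `diag(I/σ², I/σ²)`; the
  approximate trait SE is `√(σ²/I)`, constant in θ and δ.
* Reliability per dimension is `ρ_d = (var(θ̂_d) − err_d)/var(θ̂_d)`,
  reported unclipped. The error variance entering it is ambiguous in
  principle; the default is the per-dimension mean squared posterior SD of
  the trait estimates, with the Fisher-based `σ²/I` variant behind a flag.
  The two differ: posterior SDs reflect the hierarchical shrinkage, the
  Fisher value is likelihood-only.
* PPMC: T posterior draws (evenly spaced across chains) each generate a
  replicated dataset at the log-ratio level, mapped through the inverse
  ALR; the discrepancy ξ is the sum over persons of profile
  differentiation computed on *raw scores* (the statistic is defined on
  observed scores; proportions would only rescale it by C). `pr` is the
  fraction of replicated ξ at least as large as the observed one (ties
  count); `pr` outside [0.025, 0.975] flags misfit.

## Numerical and interface choices

* All arrays are 0-based internally; files and reports are 1-based.
* Responses travel as long-form CSV with the total declared in a
  `# total=` comment, supporting any D; designs as wide CSV with one
  statement column per dimension.
* Posterior serialization keeps every block as a (chain, iteration,
  parameter, value) CSV; trait draws can be thinned on storage
  (`theta_thin`) to bound memory on large panels — estimation itself never
  thins.
* Desk-scale chain settings used throughout the test suite and the
  acceptance script (2 chains, 1,000–1,500 draws after comparable burn-in,
  10 replications per condition) were chosen as the smallest runs at which
  the conjugate sampler's diagnostics are stable; full-length runs
  (2 × 10,000 after 10,000) remain the config default.

## Known limitations

* The likelihood's independence-across-ratios assumption makes results
  depend (mildly) on which slot is the reference; this is inherent to the
  model form, not the implementation.
* Reliabilities computed from real fits depend on which error variance
  definition is chosen; the package exposes both rather than asserting
  either reproduces any particular published figure.
* No EM/maximum-likelihood estimator is provided, by design; the
  comparator is fit by MCMC only.
* Unidimensional tests (D = 1) are meaningless under the ipsative
  constraint and are rejected.
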