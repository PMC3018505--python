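# Methods

## The model

`profilereg` implements Bayesian profile regression for case-control data
with integer-coded categorical and ordinal exposures. The unit of inference
is the *covariate profile* x_i = (x_i1, …, x_iP) of subject i; profiles are
clustered into latent groups, and each group carries a disease-association
parameter, so the clustering and the outcome inform each other within one
joint model.

**Assignment submodel.** Subject i belongs to latent cluster z_i = k with
probability w_k. Within cluster k, covariate p takes value x with
probability φ_k^p(x).

- *Nominal* covariates: φ_k^p is a free probability vector with a
  Dirichlet(1, …, 1) prior (conjugate; the posterior update is a direct
  Dirichlet draw from prior + within-cluster counts).
- *Ordinal* covariates: category probabilities are induced by ordered
  cutpoints on a latent standard normal, φ_k^p(j) = Φ(λ_{j+1}) − Φ(λ_j)
  with λ_0 = −∞ < λ_1 < … < λ_{M−1} < λ_M = +∞. This imposes nothing beyond
  the category order: any interior point of the probability simplex is
  reachable. The prior is uniform on the induced probabilities
  (equivalently, the cutpoints have density ∝ Π_j ϕ(λ_j) on the ordered
  region, ϕ the standard normal pdf). Cutpoints are updated by a
  random-walk Metropolis step on one interior cutpoint at a time, rejecting
  order violations (the proposal is symmetric, so the acceptance ratio is
  the posterior ratio); the per-cutpoint proposal scales are adapted during
  burn-in toward 0.44 acceptance and frozen afterwards. The update is
  batched across clusters, so its cost is independent of the truncation
  level. For M = 2 the construction collapses to a reparameterised
  Bernoulli, which the tests exploit: the posterior of Φ(λ_1) must match
  the conjugate Beta oracle of the equivalent nominal model.

**Mixing weights.** The cluster weights follow a truncated stick-breaking
Dirichlet process: V_k ~ Beta(1, α), w_k = V_k Π_{j<k}(1 − V_j), with K
truncation slots and V_K = 1 so the weights sum to one exactly
(blocked-Gibbs construction). The number of *occupied* clusters is not
fixed; it adapts to the data from iteration to iteration. The truncation
level (default 50) only needs to make the stick tail negligible — the
sampler logs a warning when the post-burn-in mass at the last slot exceeds
1e-4. The concentration α has a Gamma(2, 1) hyperprior and is updated by
random-walk Metropolis on log α.

**Disease submodel.** In *plain* mode each cluster carries a risk
θ_k ∈ (0, 1) with a Beta(1, 1) prior and P(y_i = 1) = θ_{z_i}; the full
conditional is Beta(1 + cases, 1 + controls), drawn exactly. In *logistic*
mode, logit P(y_i = 1) = β·w_i + θ_k: θ_k is the baseline log-odds of the
cluster (the log-odds when all confounders sit at their reference value of
zero) and β the confounder coefficients, both with Normal(0, 10²) priors —
wide enough to be practically noninformative while preventing separation
blow-ups; both prior scales are configurable. A prospective Bernoulli
likelihood is used even though the data are case-control; with categorical
exposures and noninformative priors this does not distort the
exposure-group contrasts, and it is what makes the clustering and outcome
jointly estimable. Empty clusters draw their parameters from the prior,
which is what keeps the variable-cluster-count sampler valid.

**Missing covariates.** Missing entries (missing completely/at random) are
imputed inside the Gibbs sweep: each missing x_ip is redrawn every
iteration from its current cluster's category distribution, so imputation
uncertainty propagates into all posterior summaries. Outcomes and
confounders are never imputed; rows missing either are dropped at load
time.

**One Gibbs sweep** updates, in order: allocations z (vectorised
categorical draw via Gumbel-max), stick weights and α, per-cluster φ /
cutpoints, disease parameters, and the imputed entries. Everything retained
in the trace is label-invariant — per-subject risks on the probability
scale, pairwise co-clustering counts (accumulated online into an n×n
matrix rather than storing allocation vectors), and the
imputation-completed covariate draws — so label switching requires no
post-hoc correction.

## Post-processing

- **Similarity matrix.** S_ij = fraction of retained iterations with
  z_i = z_j; symmetric, unit diagonal, invariant to relabelling and to the
  varying number of clusters.
- **Best partition.** A deterministic search for the partition minimising
  the least-squares discrepancy Σ_{i<j}(S_ij − A_ij)², A the partition's
  co-membership indicator. The search runs partitioning-around-medoids on
  the dissimilarity 1 − S for each candidate group count (deterministic
  farthest-point seeding, multi-started over forced first medoids — all
  subjects when n ≤ 12, five quantile-spaced subjects otherwise), then
  refines every candidate by greedy local search: single-subject
  relocations always, joint two-subject relocations on instances up to 60
  subjects. Instances with n ≤ 8 are solved exactly by enumerating all set
  partitions; the enumeration also serves as the test oracle for the
  heuristic, which attains the enumerated optimum on hundreds of random
  instances.
- **Group summaries.** For the best partition's group g, the per-iteration
  group risk is the average of its members' risks r_i(t); its spread over
  iterations reflects how stably the sampler co-clusters those subjects.
  Reported per group: posterior mean and equal-tailed 95% interval;
  exceedance probabilities P(θ_g > θ̄) and P(θ_g < θ̄) against the
  per-iteration sample-average risk θ̄(t) (strict inequalities, ties — a
  measure-zero event for continuous risks — counting toward neither side;
  probabilities above 0.9 flag high/low-risk groups); and the posterior
  odds ratio against the lowest-risk reference group, computed per
  iteration as OR(t) = [θ_g(1 − θ_ref)]/[θ_ref(1 − θ_g)] and summarised by
  mean, equal-tailed 95% interval and P(OR > 1). θ̄ is recomputed per
  iteration rather than fixed at a posterior mean — the coherent Bayesian
  reading of "average sample risk".
- **Profile deviations.** Per group, covariate and category: the
  per-iteration difference between the group's empirical category
  frequency (over imputation-completed covariates of the group's members)
  and the whole-sample frequency, summarised by an equal-tailed 95%
  interval and classified positive / negative / null by whether the
  interval excludes zero. Using completed-covariate frequencies rather than
  raw φ draws keeps the quantity well defined when a reporting group spans
  several sampler clusters within an iteration, and reduces to the φ draws
  when groups and clusters coincide.
- **Model fit.** Σ_i (y_i − p̂_i)², with p̂_i the posterior-mean subject
  risk (or any comparator model's fitted probability). A simple squared
  residual sum was chosen as the fit score because it is model-agnostic and
  directly comparable across methods on the same subjects; it is
  config-exposed at the call site, so deviance-type residuals can be
  substituted.

## MDR comparator

Multifactor dimensionality reduction labels every observed cell of a factor
combination high- or low-risk by whether its case:control ratio exceeds a
threshold (default 1) on the training 90%, predicts the held-out 10%, and
repeats over 10 outcome-stratified folds. For each order p the scan is
exhaustive over all p-subsets; the reported winner maximises mean
cross-validated prediction accuracy, and its cross-validation consistency
is the number of folds whose training-accuracy winner it was. Deterministic
conventions for MDR's sparse-cell weakness: unseen cells predict the
majority class ("low" under prevalence < 0.5), non-empty zero-control
cells are "high", ties break lexicographically by factor indices, and folds
are stratified so low-prevalence samples keep cases in every fold.

Note an implication of the default threshold: a cell is labelled high only
when cases outnumber controls, i.e. cell risk > 0.5. Interactions that only
elevate risk to below 0.5 are invisible at threshold 1 regardless of sample
size; the threshold is a parameter precisely so lower-prevalence contrasts
(e.g. the sample case:control ratio) can be used instead.

## Synthetic data

The generator draws cluster labels from fixed weights, covariates from
cluster-specific category probabilities, outcomes from cluster risks
(optionally through a logistic link with standard-normal confounders), and
applies missing-completely-at-random masking per covariate — exactly the
model's generative assumptions, plus ground truth for recovery tests.
Shipped scenarios:

- `paper_shape`: 829 subjects, nine covariates (three binary, four 3-level,
  two 4-level), three clusters of expected sizes 96/112/621 with risks
  0.15/0.12/0.09 (overall prevalence ≈ 0.10), 30% missingness on one
  4-level ordinal covariate. A study-shaped stress case: overlapping
  moderate-risk groups.
- `separable`: 900 subjects, three equal clusters with risks
  0.25/0.10/0.05 and strongly separated profiles (80% anchor mass); the
  recovery benchmark.
- `null`: one cluster, prevalence 0.10, no structure; calibration runs.
- `xor_pair`: six fair binary factors, risk 0.15 vs 0.65 by the XOR of one
  pair — a pure interaction with null marginals for the MDR scan.

What the generator does **not** emulate: center- or covariate-dependent
missingness (only MCAR), matched-set sampling, correlated covariates within
a cluster beyond what the mixture induces, and confounder distributions
other than iid standard normal. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Numerical and design choices

- Allocation sampling uses the Gumbel-max trick on log scale: exact
  categorical draws without normalisation, robust to zero-probability
  clusters (−∞ logits are never selected).
- Degenerate proposal scales (exactly 0) leave Metropolis states unchanged
  and count as accepted — useful for tests and for freezing components.
- Proposal-scale adaptation is Robbins-Monro with step (t+10)^{-0.6},
  active only during burn-in, so the post-burn-in chain is a fixed-kernel
  Markov chain and detailed balance holds for all retained draws.
- A numerically degenerate cutpoint state (underflowed category
  probability with positive counts) is treated as arbitrarily unlikely
  rather than −∞ so the chain can always escape it.
- Default run lengths (30,000 iterations, 10,000 burn-in, thin 10,
  truncation 50) suit an 800×9 study on one CPU in minutes. The shipped
  validation runs use 14,000 iterations / 4,000 burn-in / thin 5 /
  truncation 25 on the recovery scenario and 21,000 iterations for the
  single-cluster conjugate check — sizes at which the Monte Carlo error of
  interval endpoints is small relative to interval widths.
- The joint model is validated by a successive-conditional (Geweke-style)
  test at n = 10, P = 2: alternating "regenerate data from the state /
  apply one sweep" must reproduce prior moments of θ, φ, the first stick
  weight and log α; batch-means z-scores are required below 3.

## Known limitations

- Continuous covariates are out of scope; so are conditional likelihoods
  for matched sets (matching variables can only be adjusted for as
  confounders in logistic mode).
- The best-partition search is heuristic for n > 8; it is exhaustively
  verified only on small instances, and the refinement's pair moves are
  disabled above 60 subjects for cost reasons.
- The co-clustering matrix is dense (n² memory), appropriate up to a few
  thousand subjects.
- In logistic mode the reported per-subject risk fixes confounders at
  their reference value; it is a baseline risk, not a marginal one.
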