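# profilereg

Bayesian **profile regression** for case-control studies with categorical
and ordinal exposures, plus a multifactor-dimensionality-reduction (MDR)
comparator and synthetic-data generators with planted structure.

## The problem

Epidemiological studies of multifactorial diseases face many weak,
correlated risk factors. Examining their joint effect with standard
regression means estimating a combinatorial number of interaction terms,
with collinearity and selection instability on top. Profile regression
sidesteps this by changing the unit of inference: instead of per-covariate
coefficients, it clusters subjects by their whole *exposure profile*
x_i = (x_i1, …, x_iP) and links each cluster to the outcome, fitting both
parts jointly so disease status and covariate patterns inform each other.

The model, for subject i in latent cluster z_i = k:

- assignment submodel: P(x_ip = x | z_i = k) = φ_k^p(x), with a Dirichlet
  prior for nominal covariates and an ordered-probit construction
  φ_k^p(j) = Φ(λ_{j+1}) − Φ(λ_j) (ordered cutpoints on a latent standard
  normal) for ordinal covariates;
- disease submodel: P(y_i = 1) = θ_k, or with confounders
  logit P(y_i = 1) = β·w_i + θ_k;
- cluster weights from a truncated stick-breaking Dirichlet process, so the
  number of occupied clusters is random and adapts to the data;
- missing covariate entries imputed stochastically inside the Gibbs
  sampler.

The clustering posterior is condensed through the n×n similarity matrix
S_ij (the fraction of MCMC iterations co-clustering subjects i and j) into
a deterministic **best partition**, and each group g is reported with its
posterior risk distribution, the exceedance probability P(θ_g > θ̄) against
the sample-average risk (values above 0.9 flag high-risk groups), and the
posterior odds ratio OR(θ_g, θ_ref) = [θ_g(1 − θ_ref)]/[θ_ref(1 − θ_g)]
against the lowest-risk group, with 95% credible intervals throughout.
See `docs/methods.md` for the full model, priors, algorithms and
limitations.

Audience: biostatisticians and epidemiologists analysing case-control data
with a moderate number of coded exposures, and methodologists who want a
tested, reproducible reference implementation.

## Worked example

Fit the shipped three-cluster recovery scenario (900 subjects, nine coded
covariates, planted cluster risks 0.25/0.10/0.05):

```python
import numpy as np
import profilereg as pr

data, labels, truth = pr.generate_preset("separable", seed=41)
est = pr.ProfileRegression(n_iter=14_000, burn_in=4_000, thin=5,
                           truncation=25, random_state=42)
est.fit(data)
print(est.group_summary_.head(3).round(3).to_string(index=False))
```

which prints (main groups; a handful of 2–3-subject groups of genuinely
ambiguous profiles follow):

```
 group  size  theta_mean  theta_lo  theta_hi  p_above_avg  or_vs_ref  or_lo  or_hi risk_class
     0   299       0.056     0.033     0.082          0.0      1.000  1.000  1.000        low
     1   298       0.072     0.046     0.103          0.0      1.398  0.695  2.535        low
     2   286       0.301     0.248     0.357          1.0      7.805  4.423 13.107       high
```

Reading: group 2 is flagged high-risk — the posterior probability that its
risk exceeds the sample average is 1.0, its 95% credible interval
(0.248, 0.357) covers the planted risk 0.25, and its posterior odds ratio
against the lowest-risk reference group is 7.8 (95% CI 4.4–13.1), covering
the planted odds ratio of 6.3. The recovered partition matches the planted
labels with adjusted Rand index 0.939. `est.profile_deviations_` lists, per
group, covariate and category, the 95% interval of the group-minus-
population category-probability difference with a positive / negative /
null classification (the red/blue/green convention of profile plots;
`profilereg.plotting.plot_profile_deviations` draws them).

The same machinery is available as functions (`run_mcmc`,
`build_similarity`, `best_partition`, `summarize_groups`, …) and as a CLI:

```bash
profilereg simulate --preset paper_shape --seed 1 --out study.csv
profilereg fit --data study.csv --config study.config.json --seed 2 --out trace/
profilereg summarize --trace trace/ --data study.csv --config study.config.json --out summary/
profilereg mdr --data study.csv --config study.config.json --max-order 2
```

The MDR comparator (`pr.MDRScan` / `pr.mdr_scan`) performs the exhaustive
factor-subset scan with 10-fold cross-validated prediction accuracy and
cross-validation consistency.

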