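# Null scenario: a single generating cluster with no risk structure
# (prevalence 0.10) over the nine-covariate shape.
n: 600
cluster_weights: [1.0]
theta: [0.10]
covariates:
  - {name: c1, kind: nominal, n_categories: 2, phi: [[0.5, 0.5]]}
  - {name: c2, kind: ordinal, n_categories: 4, phi: [[0.25, 0.25, 0.25, 0.25]]}
  - {name: c3, kind: ordinal, n_categories: 3, phi: [[0.4, 0.3, 0.3]]}
  - {name: c4, kind: ordinal, n_categories: 4, phi: [[0.4, 0.3, 0.2, 0.1]]}
  - {name: c5, kind: ordinal, n_categories: 3, phi: [[0.3, 0.4, 0.3]]}
  - {name: c6, kind: ordinal, n_categories: 3, phi: [[0.5, 0.3, 0.2]]}
  - {name: c7, kind: nominal, n_categories: 2, phi: [[0.6, 0.4]]}
  - {name: c8, kind: nominal, n_categories: 2, phi: [[0.7, 0.3]]}
  - {name: c9, kind: ordinal, n_categories: 3, phi: [[0.3, 0.35, 0.35]]}
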