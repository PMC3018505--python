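# Study-shaped scenario: 829 subjects, nine coded exposures (three binary,
# four 3-level, two 4-level), three clusters of expected sizes 96/112/621
# with risks 0.15/0.12/0.09, ~30% MCAR missingness on the 4-level pm10
# covariate. Air-pollution covariates separate the clusters (the high-risk
# cluster anchors on the high-exposure categories); the genetic covariates
# are uninformative.
n: 829
cluster_weights: [0.11580217, 0.13510253, 0.74909530]
theta: [0.15, 0.12, 0.09]
anchor_mass: 0.6
missing_rate: [0.0, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
covariates:
  - {name: mainroad, kind: nominal, n_categories: 2, anchors: [1, 1, 0]}
  - {name: pm10, kind: ordinal, n_categories: 4, anchors: [3, 1, 0]}
  - {name: no2, kind: ordinal, n_categories: 3, anchors: [2, 1, 0]}
  - {name: pawork, kind: ordinal, n_categories: 4, anchors: [2, 2, 0]}
  - {name: paleis, kind: ordinal, n_categories: 3, anchors: [1, 1, 1]}
  - {name: bmi, kind: ordinal, n_categories: 3,
     phi: [[0.4, 0.4, 0.2], [0.4, 0.4, 0.2], [0.4, 0.4, 0.2]]}
  - {name: gstm1, kind: nominal, n_categories: 2,
     phi: [[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]]}
  - {name: xrcc1, kind: nominal, n_categories: 2,
     phi: [[0.7, 0.3], [0.7, 0.3], [0.7, 0.3]]}
  - {name: ralc, kind: ordinal, n_categories: 3,
     phi: [[0.3, 0.35, 0.35], [0.3, 0.35, 0.35], [0.3, 0.35, 0.35]]}
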