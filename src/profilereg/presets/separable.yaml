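# End-to-end recovery scenario: 900 subjects, three equally weighted,
# well-separated clusters with risks 0.25/0.10/0.05 over the same nine-
# covariate shape. Each cluster anchors on a distinct category pattern with
# 80% mass, so profiles are nearly unambiguous.
n: 900
cluster_weights: [0.3333333333333333, 0.3333333333333333, 0.3333333333333334]
theta: [0.25, 0.10, 0.05]
anchor_mass: 0.8
covariates:
  - {name: c1, kind: nominal, n_categories: 2, anchors: [1, 0, 1]}
  - {name: c2, kind: ordinal, n_categories: 4, anchors: [3, 1, 0]}
  - {name: c3, kind: ordinal, n_categories: 3, anchors: [2, 1, 0]}
  - {name: c4, kind: ordinal, n_categories: 4, anchors: [0, 2, 3]}
  - {name: c5, kind: ordinal, n_categories: 3, anchors: [0, 2, 1]}
  - {name: c6, kind: ordinal, n_categories: 3, anchors: [2, 0, 1]}
  - {name: c7, kind: nominal, n_categories: 2, anchors: [0, 1, 0]}
  - {name: c8, kind: nominal, n_categories: 2, anchors: [1, 1, 0]}
  - {name: c9, kind: ordinal, n_categories: 3, anchors: [1, 0, 2]}
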