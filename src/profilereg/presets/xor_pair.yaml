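# Pure two-factor interaction for MDR recovery: six iid binary factors,
# outcome risk 0.15 when f0 XOR f1 = 0 and 0.65 when it is 1; every
# single-factor marginal is null, and the elevated cells exceed the
# cases-greater-than-controls labelling threshold.
kind: mdr_xor
n: 400
n_factors: 6
base_risk: 0.15
effect: 0.50
pair: [0, 1]
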