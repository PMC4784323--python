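# Base scenario, single household-level predictor, K=5 villages,
# sigma_v sweep over log(1.05)..log(5).
# Run: crvecov coverage --config configs/single_predictor_k5.yaml --out results/
alpha0: -2.1972245773362196   # log(0.1/0.9)
alpha1: 0.6931471805599453    # log(2)
sigma_h: 0.6931471805599453   # log(2)
sigma_v: [0.04879016416943205, 0.4054651081081644, 0.6931471805599453,
          1.0986122886681098, 1.6094379124341003]
I: 5
J: 20
K: 5
predictors: [x1, x2, x3, x4]
reps: 2000
seed: 1
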