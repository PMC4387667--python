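"""Shrinkage behaviour of the group (B A) and individual (C) components.

Reproduces the seven-predictor toy: two groups of predictors with
coefficients 5 and -3, one individual predictor with coefficient 2, two
nulls. Sweeping the L1 penalty from strong to weak shows the grouped
predictors entering through the low-rank product B A before the individual
predictor enters C.
"""

import numpy as np

import groupeqtl as gq

X, z, truth = gq.shrinkage_toy(100, seed=0)
data = gq.EQTLDataset(X=X, Z=z, validate_genotypes=False)
lam_max = gq.penalty_path_max(data)
print("truth:", truth)
print(f"{'penalty':>10} {'|B A| (x1..x7)':^38} {'|C| (x1..x7)':^30}")
for frac in (0.5, 0.2, 0.1, 0.05, 0.01, 1e-6):
    pen = frac * lam_max
    hyper = gq.ModelHyper(M=2, H=0, lambda_A=pen, gamma_B=pen, alpha_C=pen)
    params, _ = gq.fit_model(
        data, hyper,
        gq.FitOptions(seed=0, max_outer=30, init_strategy="random"))
    group = np.abs(params.B @ params.A).ravel()
    indiv = np.abs(params.C).ravel()
    print(f"{frac:>10.0e} {np.array2string(group, precision=2):^38} "
          f"{np.array2string(indiv, precision=2):^30}")
print("\nAt strong penalties everything is zero; the grouped predictors "
      "(x1..x4) appear in B A first, and the individual predictor (x5) "
      "only enters C once the penalty is nearly released.")
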