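"""High/low infiltration classification with RFE + gradient boosting.

Uses the direct planted-feature construction (5 informative features at
Cohen's d = 2 among 95 noise features, n = 60) to show selection,
leave-one-out evaluation, and the permutation null.
"""

import numpy as np

import radiotme as rt
from radiotme.synthetic import make_planted_classification

X, y = make_planted_classification(
    n_samples=60, n_informative=5, n_noise=95, effect_d=2.0, seed=9)

selected = rt.rfe_select(X, y, seed=0)
hits = sum(name.startswith("inf") for name in selected)
print(f"RFE selected {len(selected)} features, "
      f"{hits}/5 of the informative ones: {selected}")

res = rt.loocv_eval(X[selected], y, seed=0)
print(f"pooled LOOCV AUC: {res['auc']:.3f} over {len(res['scores'])} folds")

rng = np.random.default_rng(1)
null = [rt.loocv_eval(X[selected].iloc[:30], rng.permutation(y[:30]),
                      seed=0)["auc"] for _ in range(20)]
print(f"permuted-label AUC (20 draws, n=30): mean {np.mean(null):.2f}")
# A planted d=2 effect is strongly learnable (AUC near 1); destroying the
# labels collapses performance to chance (0.5), confirming the evaluation
# does not leak.
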