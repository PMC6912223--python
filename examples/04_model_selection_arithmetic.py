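"""Akaike weights, support categories and model averaging on their own.

These are the pure model-selection operations: given a delta-AIC column they
return weights, degree-of-support labels, and a weighted average of per-model
occupancy estimates (used when several models have substantial support).
"""

import occuwatch as ow

deltas = [0.00, 1.79]  # a two-model single-season block
weights = ow.akaike_weights(deltas)
for d, w in zip(deltas, weights):
    print(f"delta-AIC {d:5.2f} -> weight {w:.2f} ({ow.support_category(d).value})")

estimates = [
    ow.EstimateWithCI(0.31, 0.22, 0.42),  # top model's occupancy
    ow.EstimateWithCI(0.26, 0.19, 0.35),  # runner-up's occupancy
]
avg = ow.model_average(estimates, weights)
print(f"\nModel-averaged occupancy: {avg.estimate:.3f} "
      f"(95% CI {avg.lo:.3f}-{avg.hi:.3f})")
print("The averaged interval uses the unconditional variance, so it is wider "
      "than either model's own interval when the models disagree.")
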