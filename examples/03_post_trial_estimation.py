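"""Post-trial regime-value estimation with normal-theory inference.

Runs one uniformly randomized trial, then estimates every embedded
regime's value with the IPW, weighted IPW, AIPW, and weighted AIPW
estimators and prints 95% confidence intervals from the martingale
M-estimation standard errors.  Under nonadaptive randomization the
stabilizing weights are identically 1, so the weighted and unweighted
estimators coincide exactly.
"""

import numpy as np

import smartrar as sr

params = sr.calibrated()
truth = sr.true_regime_values(params)
ledger = sr.run_trial(params, sr.sr_method(), seed=11)
report = sr.post_trial_report(ledger)

for est in ("ipw", "waipw"):
    table = report[est]
    print(f"\n{est.upper()} estimates (true value in brackets):")
    for j in range(8):
        print(
            f"  regime {j + 1}: {table.theta[j]:+.3f} "
            f"[{truth.theta[j]:+.3f}]  "
            f"95% CI ({table.ci_low[j]:+.3f}, {table.ci_high[j]:+.3f})  "
            f"n_consistent={table.n_consistent[j]}"
        )
    best = table.optimal_regime(minimize=True)
    print(f"  estimated optimal regime: {best} (truth: {truth.optimal_regime})")

print("\nEach subject contributes to the two regimes matching their realized")
print("treatment path; the intervals for regimes 5-8 are narrower per unit of")
print("information because the full-program arm has a 93% response rate.")
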