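"""Covert-bound model comparison and group-level Bayesian model selection.

Simulates replay-task behaviour from an observer with an absorbing covert
bound on Type-I accumulation (and unbounded Type-II accumulation), then
asks five-fold cross-validation which architecture the data support, and
demonstrates exceedance probabilities on a toy evidence matrix.
"""

import numpy as np
import pandas as pd

from metabound import (
    ModelVariant,
    SyntheticObserver,
    Type1Params,
    Type2Params,
    compare_covert_bound_models,
    exceedance_prob,
    generate_trial_bank,
    simulate_replay_trial,
)

bank = generate_trial_bank(seed=2)
t1 = Type1Params(sigma=0.5, alpha=1.0, a=0.15, b=0.8, lam=3.0)
t2 = Type2Params(sigma_c=0.5, alpha_c=1.0, a_c=0.15, b_c=0.8,
                 lam1=2.0, lam2=4.0, lam3=7.0)
obs = SyntheticObserver(type1=t1, type2=t2, variant=ModelVariant(), seed=42)

rng = np.random.default_rng(42)
rows = []
for i in range(bank.n_trials):
    for ns in rng.integers(2, 26, size=3):
        ch, cf = simulate_replay_trial(obs, bank.orientations[i], int(ns),
                                       rng, cat=bank.cat_params)
        rows.append({"trial_id": i, "condition": "same", "n_shown": int(ns),
                     "choice": ch, "confidence": cf})
behaviour = pd.DataFrame(rows)

print("Five-fold cross-validated covert-bound comparison "
      "(held-out log-likelihood per trial, bounded minus unbounded):")
report = compare_covert_bound_models(behaviour, bank, t1, t2,
                                     k=5, n_mc=200, seed=0)
print(report.to_string(index=False))
print("\nA positive delta_ll for 'type1_bound' recovers the generating")
print("architecture; the Type-II bounds (absent from the generator) should")
print("not improve the held-out fit.")

print("\nGroup Bayesian model selection on a toy evidence matrix")
print("(8 subjects, model B better by 3 log-units each):")
lme = np.zeros((8, 2))
lme[:, 1] = 3.0
xp = exceedance_prob(lme, seed=1)
print(f"exceedance probabilities: A = {xp[0]:.3f}, B = {xp[1]:.3f}")
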