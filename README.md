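# metabound

Confidence-controlled evidence accumulation: observer models with covert
decision bounds, simulation-based likelihoods, and metacognitive metrics.

## The problem

In sequential categorisation tasks an observer watches a stream of noisy
samples (here: oriented patches drawn from one of two overlapping von Mises
distributions, means ±45°, concentration κ = 0.5) and decides which source
generated them — and, on some trials, how confident they are.  Two
questions drive the analysis this package implements:

1. **When does the observer stop accumulating?**  A collapsing decision
   bound `Λ_n = n·(a + b·e^(−n/λ))` on the accumulated evidence explains
   both *what* observers choose and *when* they respond — and a *covert*
   version of that bound explains why forced extra evidence often fails to
   improve accuracy: accumulation stops internally even while stimuli keep
   arriving.
2. **What evidence feeds confidence?**  Confidence ratings are modelled as
   a second accumulator that shares the noisy evidence stream but incurs
   additional noise `σ_c` and its own leak `α_c` (partial coupling), read
   out against three ordered collapsing criteria.

The observer model corrupts ideal Bayesian accumulation
`z_N = α·z_{N−1} + (ℓ_N + ε_N)`, `ε_N ~ N(0, σ²)`, where
`ℓ(θ) = κ[cos 2(θ−μ₁) − cos 2(θ−μ₂)]` is the per-sample log-probability
difference; a Gaussian non-decision lag (μ_U, σ_U, in sample units)
separates the covert decision from the overt response.  Because the bounded
leaky accumulator has no closed-form first-passage distribution, trial
likelihoods are estimated by seeded Monte-Carlo simulation and fitted by
derivative-free search; models are compared with BIC, five-fold
cross-validation, and random-effects group Bayesian model selection
(exceedance probabilities).  A synthetic-observer module generates the full
three-task protocol (Stopping / Free / Replay), so the whole pipeline runs
without any experimental data.

Who it is for: computational cognitive scientists and psychophysicists who
want a tested, reusable implementation of this model family — to simulate
protocols, validate fitting code by parameter recovery, or measure
metacognitive (meta-d′/d′) and bound efficiency on their own data.

## Worked example

```python
import numpy as np
from metabound import (Type1Params, Type2Params, SyntheticObserver,
                       ModelVariant, generate_trial_bank, run_protocol)

bank = generate_trial_bank(n_trials=100, max_samples=40, seed=1)
obs = SyntheticObserver(
    type1=Type1Params(sigma=0.6, alpha=1.0, a=0.1, b=1.2,
                      lam={"70": 1.5, "85": 4.0, "90": 8.0, "free": 4.0},
                      mu_U=1.0, sigma_U=0.5),
    type2=Type2Params(sigma_c=0.4, a_c=0.1, b_c=0.6,
                      lam1=2.0, lam2=4.0, lam3=7.0),
    variant=ModelVariant(),   # absorbing covert bound, partial coupling
    seed=8)

stopping = run_protocol(obs, bank, "stopping")
print(stopping.groupby("condition")
      .agg(acc=("correct", "mean"), med=("response_sample", "median")))
```

prints

```
             acc  med
condition
70         0.785  3.0
85         0.830  4.5
90         0.895  8.5
```

Read: with a slower bound collapse for stricter targets (λ 1.5 → 4 → 8)
the simulated observer waits for more samples (median 3 → 4.5 → 8.5) and
gains accuracy (0.79 → 0.90), the signature behaviour of an adjustable
collapsing bound.  The `examples/` scripts walk through the other capabilities:
fitting the seven-parameter model to simulated behaviour
(`fit_stopping_model.py`), covert-bound model comparison by five-fold
cross-validation (`model_comparison.py`), and the metacognitive measurement
layer (`metacognition_metrics.py`).

A thin CLI wraps the same pipeline:
`metabound simulate|fit|recover|compare|report --config cfg.yaml`.

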