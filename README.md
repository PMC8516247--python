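# tokensim

Simulation, model fitting and behavioral analysis for the **tokens task**, a
perceptual decision paradigm with dynamically changing evidence, built to
contrast two accounts of decision formation:

- the **evidence accumulation model (EAM)** — noisy integration of the
  momentary evidence between two fixed bounds, and
- the **urgency gating model (UGM)** — low-pass-filtered momentary evidence
  multiplied by an urgency signal that grows with elapsed time.

It is aimed at computational cognitive scientists who want a tested,
reproducible pipeline for this family of models: task and trial generation
with the analytic success probability, vectorized model simulation, quantile
maximum products estimation (QMPE) with differential evolution, the standard
behavioral statistics (paired *t*, Shapiro–Wilk, Kolmogorov–Smirnov, JZS
Bayes factors), and a synthetic-study generator with recorded ground truth
for parameter-recovery work.

## The task and the models

Fifteen tokens jump one-by-one (every 200 ms) from a central circle toward a
left or right target; the subject must guess which target will end with the
majority, any time before the last jump. With `N1`, `N2` tokens in the
targets and `Nr` remaining, the probability that target one wins is

    P(C | N1, N2, Nr) = (Nr! / 2^Nr) · Σ_{k=0}^{min(Nr, 7−N2)} 1 / (k!(Nr−k)!)

In *all-stay* blocks jumped tokens stay visible; in *all-away* blocks they
vanish 200 ms after jumping, so the count difference must be held in a
working memory that loses a fraction `L_e` of its content at each jump:

    e_leak[n] = (1 − L_e) · e_leak[n−1] + j_n,      j_n ∈ {+1, −1}

Both decision models step every Δt = 10 ms with drift rate ν (per-step
variability η) applied to the evidence `e`, diffusion scale s = 0.1:

    EAM:  x ← x + ν·e·Δt′ + s·ξ·√Δt′             decide when x > θ or x < 0
    UGM:  x ← [τ/(τ+Δt)]·x + [Δt/(τ+Δt)]·(ν·e·Δt′ + s·ξ·√Δt′)
                                                  decide when |x·u| > θ

with τ = 100 ms, Δt′ the step in seconds, and urgency `u` proportional to
elapsed time. The decision time is t − Δt/2 at the crossing step.

The discriminating trials are **bias-for** (first three jumps toward the
correct target, next three away) and **bias-against** (mirrored): with fully
visible evidence the accumulator predicts much slower correct responses on
bias-against trials while the urgency model predicts no difference; with
leaky memory the urgency model — and only it — predicts *faster* responses
on bias-against trials, because the remembered evidence entering the second
half of the trial has already forgotten the early tokens.

## Worked example

```python
import numpy as np
from tokensim import REFERENCE_PARAMS, generate_trial, simulate_dataset

rng = np.random.default_rng(0)
params = REFERENCE_PARAMS[("ugm", "all_away_leak")]   # ν=5.06, θ=17661, L_e=0.214
trials = {
    t: [generate_trial(t, "all_away", rng) for _ in range(2000)]
    for t in ("bias_for", "bias_against")
}
for name, ts in trials.items():
    d = simulate_dataset(ts, "ugm", params, n_reps=1, rng=rng)
    d = d[d["correct"]]
    print(f"{name:13s} mean DT {d['dt_ms'].mean():7.1f} ms   "
          f"mean SP {d['sp_at_dt'].mean():.3f}   n={len(d)}")
```

prints

```
bias_for      mean DT  1859.6 ms   mean SP 0.884   n=1591
bias_against  mean DT  1655.4 ms   mean SP 0.665   n=1678
```

— the leaky-memory urgency model answers ~210 ms *faster* and at lower
success probability on bias-against trials, the reversed dissociation that
separates it from an evidence accumulator (which predicts the opposite
ordering) when the stimulus disappears.

The same pipeline is scriptable from the shell:

```bash
tokensim generate-study --out study/ --seed 1
tokensim analyze --decisions study/decisions.csv --baseline study/baseline.csv --out report.json
tokensim fit --model ugm --condition all_away --leak free \
    --data decisions.csv --trials trials.csv --out fit.json --seed 1
```

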