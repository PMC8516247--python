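# Methods

This note documents the modeling conventions of `tokensim`: the generative
task model, the two decision models and their numerical conventions, the
fitting machinery, the synthetic-study generator, and the design choices
made where the problem was genuinely open.

## Task model

A trial is a sequence of `n_tokens` (15, odd so no ties) jump directions,
encoded relative to the designated correct target (+1 toward, −1 away); the
left/right assignment is an independent uniform draw, which decouples the
model mathematics from screen geometry. Jumps occur every 200 ms starting at
t = 200 ms; the response deadline is the final jump at t = 3000 ms.

The success probability of a target given counts `(N1, N2, Nr)` is computed
in exact integer arithmetic as the fraction of the `2^Nr` equiprobable
completions in which the target reaches `floor(n_tokens/2) + 1` tokens; the
printed closed form with the constant 7 is the 15-token case. The
implementation is verified against exhaustive enumeration for every
reachable state and satisfies the complementarity identity
`P₁(N1,N2,Nr) + P₂(N2,N1,Nr) = 1`.

Predefined trial types:

- **easy** — each jump is toward the correct target with probability 0.85;
  sequences are rejection-sampled so the correct target's success
  probability stays ≥ 0.60 from the third jump on.
- **ambiguous** — jumps 1–10 strictly alternate (random starting side),
  pinning the success probability to [0.34, 0.66] (the exact attainable
  envelope of an alternating 15-token profile — the bound is reached at
  jump nine with values 22/64 and 42/64); jumps 11–15 favor the correct
  target at 0.85, and sequences are re-drawn until the correct target wins.
- **bias-for / bias-against** — the first six jumps are +,+,+,−,−,− or the
  mirror; exactly 7 of the 9 remaining jumps are toward the correct target
  in random order, so the final count is always 10 vs 5.
- **random** — fair coin flips, unconstrained; the realized majority (not
  the nominal label) defines correctness downstream.

Blocks mix the types 50/15/15/10/10 % (random/easy/ambiguous/bias-for/
bias-against), apportioned by the largest-remainder rule and shuffled.

## Evidence and working memory

The momentary evidence `e` is the running count difference toward the
correct target: piecewise constant, updated exactly at jump onsets. With a
memory leak `L_e ∈ [0,1]` the stored value decays only at jump onsets:
`e_leak[n] = (1−L_e)·e_leak[n−1] + j_n`. `L_e = 0` reproduces the veridical
count (the all-stay condition, and the "all-away without leak" variant is
the same machinery run on all-away trials); `L_e = 1` retains only the most
recent token.

## Decision models and unit conventions

Both models advance in Δt = 10 ms steps. Inside the stochastic update the
step enters in seconds (Δt′ = 0.01) and the diffusion scale is fixed at
s = 0.1, so the per-step input is `ν·e·Δt′ + s·ξ·√Δt′` with ξ standard
normal.

- **EAM**: `x ← x + input`, starting at θ/2, absorbing at θ (choice toward
  positive evidence) and 0 (opposite).
- **UGM**: `x ← a·x + (1−a)·input` with `a = τ/(τ+Δt)`, τ = 100 ms; the
  decision variable is `x·u` compared against ±θ, with the urgency signal
  `u = 100·t` (t in ms; equivalently u grows by 1000 per step).

The urgency unit is a free convention absorbed by ν and θ. This particular
scale was chosen so that parameter sets with θ in the 10⁴ range and ν of a
few units — the magnitudes reported by fits of the urgency model to this
task — produce decision times in the behavioral range (crossings near
`e·t ≈ θ/ν` ms): easy trials ≈ 1.2 s, bias trials ≈ 1.7–2.0 s. A smaller
urgency slope pushes ambiguous trials past the deadline; a larger one makes
the model commit inside the bias-trial manipulation window, which erases
the all-stay equivalence of bias-for and bias-against.

**Drift variability.** The drift rate is redrawn from Normal(ν, η) at every
step by default (`drift_resampling="per_step"`), making η an
evidence-scaled diffusion around a stable gain ν. The classic per-trial
draw is available (`"per_trial"`) but is not the default: at the reference
parameter scale η ≳ 2ν, and a per-trial draw then flips the drift sign on a
third of the trials, decoupling errors from the momentary evidence
(easy-trial accuracy collapses to ~0.65 and the all-away bias dissociation
reverses under correct-trials-only analysis) — behavior incompatible with
what these models are meant to capture, and with the near-unidentifiability
of η that fitted-parameter dispersions suggest. Under per-step resampling
errors arise from committing at low success probability, as in human data.

**Decision time and censoring.** A crossing at step time t yields
DT = t − Δt/2. Trials with no crossing before the deadline are *censored*:
a choice is forced from the sign of the decision variable (ties resolved by
a fair coin), DT is set to the deadline, and the flag is retained so
analyses can treat forced responses explicitly.

Correctness compares the choice with the realized final majority, and the
success probability at decision time uses the true token counts at the last
jump onset ≤ DT (states are piecewise constant, so no interpolation
exists).

## Fitting (QMPE + differential evolution)

Observed decision times are split into correct and error responses and
binned by their own quantiles (default probabilities 0.1/0.3/0.5/0.7/0.9,
six bins per outcome, outer bins open; fewer than 5 observed errors
collapse the error distribution into a single bin). A candidate parameter
set is scored by `Σ n_obs(bin)·log p_pred(bin)` where `p_pred` is the
fraction of a 2,000-trial Monte-Carlo sample landing in the bin (jointly
across outcomes, flooring at 1e−10). Candidate simulations reuse one fixed
set of drift/noise draws (common random numbers), so the objective is
deterministic; final predictions use 10,000 replicates.

The search is differential evolution (best/1/bin, F = 0.8, CR = 0.9),
100 particles × 500 iterations × 5 restarts by default (a scaled-down
20 × 100 × 2 configuration is used for the recovery exercises, sized for a
single desktop core). ν, η and θ are searched on a log10 scale within wide
bounds (ν ∈ [1e−3, 20], η ∈ [~0, 50], θ ∈ [1e−3, 5] for the accumulator and
[1, 1e5] for the urgency model, leak ∈ [0, 1] linear): their plausible
ranges span decades, and on a linear scale the small-η regime occupies a
sliver of the search volume that the population never finds, drifting
instead into a mimic basin where evidence-scaled η-noise at ~20× parameter
scale imitates the fixed diffusion noise. All-stay fits hold the leak at 0;
all-away fits may free it. Random trials are excluded from fitting; correct
and error trials of the four structured types are pooled.

**Identifiability.** The accumulator is fully identifiable: the fixed s
pins the overall scale (recovery at 400 trials: median relative error ~7%
for ν, ~3% for θ). The urgency model's decision variable is *exactly*
invariant under (ν, η, θ) → (cν, cη, cθ) apart from the s-term, which at
θ ≈ 2×10⁴ contributes ~0.2% of the decision-variable variance; the QMPE
objective is flat along that ray to within binning noise (< 0.4 units over
c ∈ [0.25, 3]). Consequently only the ratios θ/ν and η/ν and the leak are
estimable for the urgency model (θ/ν recovered to a few percent, leak to
±0.05); point estimates of ν and θ individually are reported but
meaningless, and recovery exercises should assess the ratio.

## Behavioral statistics

Decision times are raw reaction times minus the subject's baseline reaction
time (mean of the single-token calibration trials); non-positive results
are flagged invalid and excluded. Summaries (mean ± SEM of DT and of SP at
decision time per subject × condition × trial type) use correct trials only
by default, with an explicit flag for the correct+error pooling that
fitting uses. Group contrasts are two-sided paired-samples t-tests on
per-subject means with JZS Bayes factors: a Cauchy prior on the
standardized effect size with scale 3 for DT contrasts (large effects
expected) and 0.707 for SP contrasts, computed by adaptive quadrature of
the noncentral-t likelihood over the prior (verified against dense-grid
integration to 4 significant digits). Shapiro–Wilk covers normality checks
and the two-sample Kolmogorov–Smirnov test within-subject distribution
comparisons. No multiple-testing correction is applied.

## Synthetic studies

`generate_study` emulates the full study design: 15 subjects, two
conditions, 6 blocks per condition, each block running until it contains
70 correct decisions (capped at 20× the quota, aborting with a diagnostic
for near-zero-accuracy parameter sets), the 50/15/15/10/10 trial-type mix
maintained in rolling chunks, and reported reaction times equal to model
decision time plus the subject's baseline (mean 0.347 s, between-subject
SD 0.009·√15 s), so downstream analysis must perform baseline subtraction.
The default truth is the urgency model with leak-free evidence in all-stay
and leaky memory (L_e ≈ 0.214) in all-away, at the reference parameter
sets in `REFERENCE_PARAMS`.

Between-subject variability is a multiplicative log-normal jitter
(σ = 0.15) applied as one shared factor on the (ν, η, θ) scale plus
independent factors on the identifiable coordinates η/ν, θ/ν and leak
(clipped to the fitting bounds). Jittering all parameters independently
would inflate the behavioral timescale θ/ν by σ√2 ≈ 0.21 — enough to push
a third of synthetic subjects across the regime boundary where the
correct-trials-only bias dissociation changes sign, a heterogeneity real
cohorts (between-subject DT spread ≈ ±13%) do not show.

What the generator does *not* emulate: motor/mouse kinematics, learning or
fatigue across blocks, block-order effects, non-decision-time variability
beyond the constant baseline, or any deviation of real subjects from the
generative model family. Passing end-to-end tests therefore demonstrates
pipeline correctness and the models' qualitative signatures, not that human
data follow either model.

## Problem sizes used by the test and acceptance runs

Signature checks use 10,000 independently generated trials per trial type
(one decision each, so token-sequence and diffusion variability are both
i.i.d.). Parameter-recovery exercises use 5 synthetic subjects per model
with 400 structured trials each and the scaled-down 20 × 100 × 2 search on
2,000-trial candidate simulations. The end-to-end study check runs 15
subjects at the full block design. These sizes keep the whole suite at
desk scale while leaving every comparison decisively powered (or, where a
check is not attainable, documented below).

## Known limitations

- **Ambiguous-trial timing.** With `u = 100·t` and the reference all-stay
  ratio θ/ν ≈ 6.1×10³, the urgency model commits on ambiguous trials only
  once the count difference grows late in the trial (~2.7 s), where the
  outcome is nearly resolved; its correct-trial SP at decision time there
  (0.946) slightly *exceeds* the easy-trial value (0.920), whereas humans
  commit near SP 0.57. No linear (or affine) urgency unit can produce both
  easy ≈ 1.2 s and ambiguous ≈ 1.6 s commits at these ratios, so this
  divergence is inherent to the reconstruction and is flagged in the
  acceptance suite rather than hidden.
- **Urgency-model scale.** ν and θ point values are conventions, not
  measurements (see Identifiability); only their ratio travels across
  implementations.
- **Cohort-level bias dissociation in DT.** Under correct-trials-only
  analysis the dissociation magnitude depends on each subject's θ/ν and
  leak; with the study's own trial counts the paired t-test across 15
  synthetic subjects has moderate power for DT (the SP dissociation is the
  decisively powered signature), so cohort DT checks assert direction, not
  significance.
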