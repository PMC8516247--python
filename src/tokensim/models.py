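"""Evidence signals and the two decision models (accumulation vs urgency gating).

Evidence
--------
The momentary sensory evidence ``e`` is the running token-count difference in
favor of the designated correct target: it changes by ±1 at each jump onset
and is frozen between jumps.  When the stimulus disappears (all-away blocks)
the remembered evidence decays: at each jump onset the stored value loses a
fraction ``L_e`` before the new token is added,

    e_leak[n] = (1 - L_e) * e_leak[n-1] + j_n,       j_n in {+1, -1},

and is likewise frozen between jumps.  ``L_e = 0`` recovers the veridical
count, ``L_e = 1`` remembers only the newest token.

Models
------
Both models step every ``dt`` = 10 ms with a drift rate drawn from
Normal(nu, eta) and i.i.d. standard-normal noise ``xi``.  By default the
drift draw is refreshed at every step (``drift_resampling="per_step"``), so
``eta`` acts as evidence-scaled diffusion around the mean gain ``nu``;
``"per_trial"`` freezes one draw for the whole trial (the classic
inter-trial drift variability of diffusion models).  At the parameter scale
this package targets (``eta`` comparable to or larger than ``nu``) the
per-trial variant makes the drift sign flip on a third of the trials and
decouples accuracy from the momentary evidence, which contradicts the
behavior the models are meant to capture; per-step resampling keeps errors
tied to committing at low success probability.  The update rules are:

* Evidence accumulation (EAM): a bounded random walk started midway between
  the bounds,

      x <- x + drift * e * dt' + s * xi * sqrt(dt'),

  deciding when ``x > theta`` (toward the positive-evidence target) or
  ``x < 0`` (opposite).  ``dt'`` is the step in seconds (0.01) and ``s`` is
  the fixed diffusion scale 0.1.

* Urgency gating (UGM): the same stochastic input low-pass filtered with time
  constant ``tau`` = 100 ms and multiplied by a linearly growing urgency
  signal,

      x <- [tau/(tau+dt)] x + [dt/(tau+dt)] (drift * e * dt' + s * xi * sqrt(dt')),

  deciding when ``x * u > theta`` or ``x * u < -theta``.  The urgency ``u``
  is elapsed time measured in units of 10 microseconds (``u = 100 t`` with
  ``t`` in ms, i.e. it grows by 1000 per step).  Any linear unit for ``u`` is
  absorbed by the free parameters; this scale places the fitted ``theta`` of
  the urgency model in the 1e4 range typical of published fits to this task
  while keeping the stochastic term identical to the accumulator's.

In both models the decision time is ``t - dt/2`` for a crossing detected at
step time ``t`` (midpoint correction for the discrete step).  Trials that
never cross before the deadline (the last token's jump) are censored: a
choice is forced from the sign of the decision variable and the decision time
is set to the deadline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task import TaskConfig, TokenTrial, _sp

__all__ = [
    "ModelParams",
    "EvidenceTrace",
    "SimulatedDecision",
    "URGENCY_PER_MS",
    "evidence_from_trial",
    "leaky_filter",
    "simulate_eam",
    "simulate_ugm",
    "simulate_dataset",
]

#: Urgency-signal units per millisecond of elapsed time.
URGENCY_PER_MS = 100.0


@dataclass(frozen=True)
class ModelParams:
    """Free and fixed parameters shared by both decision models.

    nu, eta
        Mean and standard deviation of the per-trial drift rate.
    theta
        Boundary separation (EAM, start point ``theta/2``) or urgency
        threshold (UGM, symmetric at ``±theta``).
    leak
        Working-memory leak fraction ``L_e`` applied at each jump onset;
        0 for veridical (all-stay) evidence.
    s, dt_ms, tau_ms
        Fixed constants: diffusion scale 0.1, step 10 ms, and the UGM
        low-pass time constant 100 ms.
    drift_resampling
        ``"per_step"`` (default) redraws the drift every step; ``"per_trial"``
        draws once per trial.
    """

    nu: float
    eta: float
    theta: float
    leak: float = 0.0
    s: float = 0.1
    dt_ms: float = 10.0
    tau_ms: float = 100.0
    drift_resampling: str = "per_step"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must lie in [0, 1]")
        if self.dt_ms <= 0 or self.tau_ms <= 0:
            raise ValueError("dt_ms and tau_ms must be positive")
        if self.drift_resampling not in ("per_step", "per_trial"):
            raise ValueError("drift_resampling must be 'per_step' or 'per_trial'")


@dataclass(frozen=True)
class EvidenceTrace:
    """Piecewise-constant evidence signal locked to the token jumps.

    ``e`` is the raw count difference after each jump, ``e_leak`` the
    leak-filtered version (equal to ``e`` when the leak is zero).  Both hold
    their value between jumps; before the first jump the evidence is zero.
    """

    times_ms: np.ndarray
    e: np.ndarray
    e_leak: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times_ms", "e", "e_leak"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times_ms) == len(self.e) == len(self.e_leak)):
            raise ValueError("times_ms, e and e_leak must have equal length")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("jump times must be strictly increasing")

    def value_at(self, t_ms: float, leaky: bool = True) -> float:
        """Evidence in effect at time ``t_ms`` (jumps take effect at onset)."""
        j = int(np.searchsorted(self.times_ms, t_ms, side="right"))
        if j == 0:
            return 0.0
        return float((self.e_leak if leaky else self.e)[j - 1])


def leaky_filter(jumps: np.ndarray, leak: float) -> np.ndarray:
    """Apply the per-jump working-memory leak along the last axis.

    ``jumps`` holds the ±1 jump directions; returns the remembered evidence
    after each jump.
    """
    if not 0.0 <= leak <= 1.0:
        raise ValueError("leak must lie in [0, 1]")
    jumps = np.asarray(jumps, dtype=float)
    out = np.empty_like(jumps)
    keep = 1.0 - leak
    acc = np.zeros(jumps.shape[:-1])
    for n in range(jumps.shape[-1]):
        acc = keep * acc + jumps[..., n]
        out[..., n] = acc
    return out


def evidence_from_trial(trial: TokenTrial, leak: float = 0.0) -> EvidenceTrace:
    """Build the raw and leak-filtered evidence trace for one trial."""
    directions = np.asarray(trial.directions, dtype=float)
    e = np.cumsum(directions)
    e_leak = e if leak == 0.0 else leaky_filter(directions, leak)
    return EvidenceTrace(trial.config.jump_onsets_ms, e, e_leak)


@dataclass(frozen=True)
class SimulatedDecision:
    """Outcome of one simulated trial.

    ``choice`` is +1 for the designated correct target's side, -1 for the
    other; ``correct`` compares the choice with the realized final majority.
    ``sp_at_dt`` is the success probability of the *chosen* target given the
    token counts in effect at the decision time.
    """

    choice: int
    dt_ms: float
    correct: bool
    sp_at_dt: float
    censored: bool


# ---------------------------------------------------------------------------
# Vectorized simulation core


def _draw_drift(
    params: ModelParams, n: int, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Drift-rate draws: (n, 1) per trial or (n, n_steps) per step."""
    shape = (n, n_steps) if params.drift_resampling == "per_step" else (n, 1)
    return params.nu + params.eta * rng.standard_normal(shape)


def _step_indices(n_steps: int, dt_ms: float, times_ms: np.ndarray) -> np.ndarray:
    """Number of jumps in effect at the start of each step (length n_steps)."""
    t_pre = dt_ms * np.arange(n_steps)  # step k updates from time (k-1)*dt
    return np.searchsorted(times_ms, t_pre, side="right")


def _simulate_core(
    model: str,
    e_step: np.ndarray,
    drift: np.ndarray,
    noise: np.ndarray,
    params: ModelParams,
    deadline_ms: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate many trials at once.

    ``e_step`` (n, K): evidence in effect at the start of each step;
    ``drift``: drift rate, shape (n, 1) for per-trial draws or (n, K) for
    per-step draws; ``noise`` (n, K): standard normals.
    Returns (choice ±1, dt_ms, censored).
    """
    n, n_steps = e_step.shape
    dt = params.dt_ms
    dt_s = dt / 1000.0
    inc = (drift * e_step) * dt_s + (params.s * np.sqrt(dt_s)) * noise

    if model == "eam":
        x = np.cumsum(inc, axis=1)
        x += params.theta / 2.0
        up = x > params.theta
        lo = x < 0.0
        hit = up | lo
        first = hit.argmax(axis=1)
        rows = np.arange(n)
        has_hit = hit[rows, first]
        choice = np.where(up[rows, first], 1, -1).astype(np.int8)
        dt_out = (first + 1) * dt - dt / 2.0
        final = x[:, -1] - params.theta / 2.0
    elif model == "ugm":
        a = params.tau_ms / (params.tau_ms + dt)
        b = 1.0 - a
        x = np.zeros(n)
        choice = np.zeros(n, dtype=np.int8)
        first = np.zeros(n, dtype=np.int64)
        has_hit = np.zeros(n, dtype=bool)
        active = np.ones(n, dtype=bool)
        for k in range(n_steps):
            x = a * x + b * inc[:, k]
            u = URGENCY_PER_MS * (k + 1) * dt
            bound = params.theta / u
            cross_up = active & (x > bound)
            cross_lo = active & (x < -bound)
            if cross_up.any() or cross_lo.any():
                choice[cross_up] = 1
                choice[cross_lo] = -1
                newly = cross_up | cross_lo
                first[newly] = k
                has_hit |= newly
                active &= ~newly
                if not active.any():
                    # every trial has decided; the filter state no longer matters
                    break
        dt_out = (first + 1) * dt - dt / 2.0
        final = x
    else:
        raise ValueError(f"unknown model {model!r}; expected 'eam' or 'ugm'")

    censored = ~has_hit
    if censored.any():
        forced = np.sign(final[censored]).astype(np.int8)
        ties = forced == 0
        if ties.any():
            forced[ties] = np.where(rng.random(int(ties.sum())) < 0.5, 1, -1)
        choice = choice.copy()
        choice[censored] = forced
        dt_out = dt_out.astype(float)
        dt_out[censored] = deadline_ms
    return choice, np.asarray(dt_out, dtype=float), censored


def _sp_of_choice(
    trial: TokenTrial, choice: int, dt_ms: float
) -> float:
    """Success probability of the chosen target at the decision time."""
    cfg = trial.config
    n_jumps = int(
        np.searchsorted(cfg.jump_onsets_ms, dt_ms, side="right")
    )
    state = trial.state_after(n_jumps)
    if choice == 1:
        return _sp(state.n1, state.n2, state.nr, cfg.n_tokens)
    return _sp(state.n2, state.n1, state.nr, cfg.n_tokens)


def _simulate_trace(
    model: str,
    trace: EvidenceTrace,
    params: ModelParams,
    rng: np.random.Generator | int | None,
    deadline_ms: float | None,
) -> tuple[int, float, bool]:
    rng = np.random.default_rng(rng)
    if deadline_ms is None:
        deadline_ms = float(trace.times_ms[-1])
    n_steps = int(round(deadline_ms / params.dt_ms))
    if n_steps < 1:
        raise ValueError("deadline shorter than one simulation step")
    idx = _step_indices(n_steps, params.dt_ms, trace.times_ms)
    e_pad = np.concatenate([[0.0], trace.e_leak])
    e_step = e_pad[idx][None, :]
    drift = _draw_drift(params, 1, n_steps, rng)
    noise = rng.standard_normal((1, n_steps))
    choice, dt_out, censored = _simulate_core(
        model, e_step, drift, noise, params, deadline_ms, rng
    )
    return int(choice[0]), float(dt_out[0]), bool(censored[0])


def _decision_from_trial(
    model: str,
    trial: TokenTrial,
    params: ModelParams,
    rng: np.random.Generator | int | None,
) -> SimulatedDecision:
    trace = evidence_from_trial(trial, params.leak)
    choice, dt_ms, censored = _simulate_trace(
        model, trace, params, rng, trial.config.deadline_ms
    )
    return SimulatedDecision(
        choice=choice,
        dt_ms=dt_ms,
        correct=choice == trial.majority,
        sp_at_dt=_sp_of_choice(trial, choice, dt_ms),
        censored=censored,
    )


def simulate_eam(
    trace_or_trial: EvidenceTrace | TokenTrial,
    params: ModelParams,
    rng: np.random.Generator | int | None = None,
    deadline_ms: float | None = None,
) -> SimulatedDecision:
    """Simulate one trial of the evidence-accumulation model.

    When given a bare :class:`EvidenceTrace` the correctness and success
    probability are evaluated against the sign of the final evidence.
    """
    return _simulate_one("eam", trace_or_trial, params, rng, deadline_ms)


def simulate_ugm(
    trace_or_trial: EvidenceTrace | TokenTrial,
    params: ModelParams,
    rng: np.random.Generator | int | None = None,
    deadline_ms: float | None = None,
) -> SimulatedDecision:
    """Simulate one trial of the urgency-gating model."""
    return _simulate_one("ugm", trace_or_trial, params, rng, deadline_ms)


def _simulate_one(model, trace_or_trial, params, rng, deadline_ms):
    if isinstance(trace_or_trial, TokenTrial):
        return _decision_from_trial(model, trace_or_trial, params, rng)
    trace = trace_or_trial
    choice, dt_ms, censored = _simulate_trace(model, trace, params, rng, deadline_ms)
    final_sign = 1 if trace.e[-1] > 0 else -1
    return SimulatedDecision(
        choice=choice,
        dt_ms=dt_ms,
        correct=choice == final_sign,
        sp_at_dt=float("nan"),
        censored=censored,
    )


def simulate_dataset(
    trials: Sequence[TokenTrial],
    model: str,
    params: ModelParams,
    n_reps: int = 1,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate ``n_reps`` independent decisions for every trial.

    Returns a decision log with one row per (trial, rep): columns
    ``trial_index, rep, trial_type, condition, model, choice, dt_ms,
    correct, sp_at_dt, censored``.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)
    cfg = trials[0].config
    n_trials = len(trials)
    directions = np.array([t.directions for t in trials], dtype=float)
    e_jump = leaky_filter(directions, params.leak) if params.leak else np.cumsum(
        directions, axis=1
    )
    deadline = cfg.deadline_ms
    n_steps = int(round(deadline / params.dt_ms))
    idx = _step_indices(n_steps, params.dt_ms, cfg.jump_onsets_ms)
    e_pad = np.concatenate([np.zeros((n_trials, 1)), e_jump], axis=1)
    e_step_base = e_pad[:, idx]
    majority = np.array([t.majority for t in trials], dtype=np.int8)

    # token counts at each step, for the success probability of the choice
    raw = np.cumsum(directions, axis=1)
    raw_pad = np.concatenate([np.zeros((n_trials, 1)), raw], axis=1)

    frames = []
    for rep in range(n_reps):
        drift = _draw_drift(params, n_trials, n_steps, rng)
        noise = rng.standard_normal((n_trials, n_steps))
        choice, dt_out, censored = _simulate_core(
            model, e_step_base, drift, noise, params, deadline, rng
        )
        n_jumps = np.searchsorted(cfg.jump_onsets_ms, dt_out, side="right")
        diff = raw_pad[np.arange(n_trials), n_jumps]
        n1 = ((n_jumps + diff) / 2).astype(int)
        n2 = n_jumps - n1
        nr = cfg.n_tokens - n_jumps
        sp = np.array(
            [
                _sp(a, b, r, cfg.n_tokens) if c == 1 else _sp(b, a, r, cfg.n_tokens)
                for a, b, r, c in zip(n1, n2, nr, choice)
            ]
        )
        frames.append(
            pd.DataFrame(
                {
                    "trial_index": np.arange(n_trials),
                    "rep": rep,
                    "trial_type": [t.trial_type for t in trials],
                    "condition": [t.condition for t in trials],
                    "model": model,
                    "choice": choice.astype(int),
                    "dt_ms": dt_out,
                    "correct": choice == majority,
                    "sp_at_dt": sp,
                    "censored": censored,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
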