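"""Synthetic studies: complete trial and decision logs with known ground truth.

A synthetic study emulates the structure of a human tokens-task session:
each subject runs blocks of trials in both stimulus conditions, a block ends
once it contains the required number of correct decisions, the trial-type mix
follows the standard proportions, and every reported reaction time is the
model's decision time plus the subject's baseline reaction time — so the
analysis stage must perform baseline subtraction, exactly as with real logs.

Ground-truth generative parameters are recorded next to the data, which makes
the bundle directly usable for parameter-recovery exercises: fit the logs,
compare against the truth.

The default parameter sets (:data:`REFERENCE_PARAMS`) are at the scale of
published fits of these models to tokens-task data: the accumulator operates
on a ~0.3 bound with drift ~0.045 per token per second, the urgency model on
a ~2e4 threshold with drift ~4-5, and the all-away working memory leaks
~0.2 per jump under the urgency model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .models import ModelParams, _simulate_core, _step_indices, leaky_filter
from .task import (
    DEFAULT_TRIAL_MIX,
    TaskConfig,
    TokenTrial,
    generate_trial,
    largest_remainder_counts,
    _sp,
)

__all__ = [
    "REFERENCE_PARAMS",
    "SyntheticStudyConfig",
    "StudyBundle",
    "generate_subject",
    "generate_study",
    "simulate_trials_once",
]

#: Generative parameter sets at the scale of published fits, keyed by
#: (model, regime).  Regimes: "all_stay" (veridical evidence), "all_away"
#: (removed stimulus, no memory leak) and "all_away_leak" (leaky memory).
REFERENCE_PARAMS: Mapping[tuple[str, str], ModelParams] = {
    ("eam", "all_stay"): ModelParams(nu=0.04456, eta=0.00478, theta=0.29062),
    ("ugm", "all_stay"): ModelParams(nu=3.76432, eta=7.65377, theta=23022.92488),
    ("eam", "all_away"): ModelParams(nu=0.03915, eta=0.01345, theta=0.25270),
    ("ugm", "all_away"): ModelParams(nu=4.12036, eta=12.84759, theta=18791.13380),
    ("eam", "all_away_leak"): ModelParams(
        nu=0.06918, eta=0.01751, theta=0.26127, leak=0.12341
    ),
    ("ugm", "all_away_leak"): ModelParams(
        nu=5.05699, eta=13.03403, theta=17660.64882, leak=0.21371
    ),
}


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study design and generative truth for a synthetic cohort.

    The defaults mirror the reference study design: 15 subjects, six blocks
    per condition of 70 correct trials each, baseline reaction time
    0.347 s with a between-subject spread matching a SEM of 0.009 s over 15
    subjects.  The generative model is the urgency-gating model with leak-free
    evidence in all-stay blocks and leaky working memory in all-away blocks.
    """

    n_subjects: int = 15
    model: str = "ugm"
    params_all_stay: ModelParams = field(
        default_factory=lambda: REFERENCE_PARAMS[("ugm", "all_stay")]
    )
    params_all_away: ModelParams = field(
        default_factory=lambda: REFERENCE_PARAMS[("ugm", "all_away_leak")]
    )
    blocks_per_condition: int = 6
    trial_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRIAL_MIX)
    )
    baseline_rt_mean_s: float = 0.347
    baseline_rt_sd_s: float = 0.009 * math.sqrt(15)
    #: multiplicative log-normal jitter (sigma, log scale) on nu, eta, theta
    #: per subject; leak is jittered the same way then clipped to [0, 1].
    param_jitter_sigma: float = 0.15
    task: TaskConfig = field(default_factory=TaskConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.model not in ("eam", "ugm"):
            raise ValueError("model must be 'eam' or 'ugm'")
        if self.blocks_per_condition < 1:
            raise ValueError("blocks_per_condition must be >= 1")


@dataclass
class StudyBundle:
    """All logs of a synthetic study plus the generative truth."""

    trials: pd.DataFrame
    decisions: pd.DataFrame
    baseline: pd.DataFrame
    truth: dict
    config: SyntheticStudyConfig


def _jitter_params(
    params: ModelParams, sigma: float, rng: np.random.Generator
) -> ModelParams:
    """Multiplicative log-normal between-subject jitter.

    The decision models are (nearly, for the accumulator; exactly, for the
    urgency model) invariant under a joint rescaling of (nu, eta, theta), so
    the behaviorally identifiable coordinates are the ratios eta/nu and
    theta/nu plus the leak.  The jitter therefore applies one shared
    log-normal factor to the overall scale and independent ``sigma`` factors
    to each identifiable coordinate; every marginal parameter remains
    log-normal with spread ~``sigma`` around its configured mean while the
    behavioral timescale theta/nu spreads by exactly ``sigma``.
    """
    if sigma == 0:
        return params
    scale, f_eta, f_theta, f_leak = np.exp(sigma * rng.standard_normal(4))
    leak = params.leak * f_leak
    return replace(
        params,
        nu=params.nu * scale,
        eta=params.eta * scale * f_eta,
        theta=params.theta * scale * f_theta,
        leak=float(np.clip(leak, 0.0, 1.0)),
    )


def simulate_trials_once(
    trials: list[TokenTrial],
    model: str,
    params: ModelParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One decision per trial, vectorized; same columns as a decision log."""
    from .models import simulate_dataset

    return simulate_dataset(trials, model, params, n_reps=1, rng=rng)


def _mix_chunk(
    counts: dict[str, int], chunk: int, mix: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    """Next ``chunk`` trial types keeping the running stream at the target mix."""
    total = sum(counts.values()) + chunk
    target = largest_remainder_counts(total, mix)
    out: list[str] = []
    for name, tgt in target.items():
        out.extend([name] * max(0, tgt - counts[name]))
    # rounding drift can over/under-shoot by a trial; trim or pad deterministically
    while len(out) > chunk:
        out.pop()
    names = list(mix)
    while len(out) < chunk:
        out.append(names[int(rng.integers(len(names)))])
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def _generate_block(
    condition: str,
    model: str,
    params: ModelParams,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> tuple[list[TokenTrial], pd.DataFrame]:
    """Trials and decisions of one block, ending at the correct-answer quota."""
    quota = config.task.correct_per_block
    cap = 20 * quota  # ~10x the expected length at typical accuracy
    counts = {t: 0 for t in config.trial_mix}
    trials: list[TokenTrial] = []
    decisions: list[pd.DataFrame] = []
    n_correct = 0
    chunk = 10
    while n_correct < quota:
        if len(trials) >= cap:
            raise RuntimeError(
                f"block did not reach {quota} correct decisions within "
                f"{cap} trials; generative parameters may be at chance level"
            )
        types = _mix_chunk(counts, chunk, config.trial_mix, rng)
        batch = [generate_trial(t, condition, rng, config.task) for t in types]
        sim = simulate_trials_once(batch, model, params, rng)
        cum = sim["correct"].cumsum() + n_correct
        if cum.iloc[-1] >= quota:
            stop = int(np.searchsorted(cum.to_numpy(), quota) + 1)
            batch, sim = batch[:stop], sim.iloc[:stop]
        for t in batch:
            counts[t.trial_type] += 1
        sim = sim.copy()
        sim["trial_index"] = np.arange(len(trials), len(trials) + len(batch))
        trials.extend(batch)
        decisions.append(sim)
        n_correct = int(cum.iloc[min(len(sim), len(cum)) - 1])
    return trials, pd.concat(decisions, ignore_index=True)


def generate_subject(
    config: SyntheticStudyConfig, subject_index: int
) -> tuple[pd.DataFrame, pd.DataFrame, float, dict[str, ModelParams]]:
    """Trial log, decision log, baseline RT and truth for one subject.

    Deterministic in ``(config, subject_index)``: the subject's stream is
    spawned from the master seed.
    """
    ss = np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(subject_index,)
    )
    rng = np.random.default_rng(ss)
    baseline = float(
        config.baseline_rt_mean_s + config.baseline_rt_sd_s * rng.standard_normal()
    )
    baseline = max(baseline, 0.05)
    truth = {
        "all_stay": _jitter_params(config.params_all_stay, config.param_jitter_sigma, rng),
        "all_away": _jitter_params(config.params_all_away, config.param_jitter_sigma, rng),
    }
    trial_rows = []
    decision_frames = []
    for condition in ("all_stay", "all_away"):
        params = truth[condition]
        for block in range(config.blocks_per_condition):
            trials, sim = _generate_block(condition, config.model, params, config, rng)
            for i, t in enumerate(trials):
                trial_rows.append(
                    {
                        "subject_id": subject_index,
                        "condition": condition,
                        "block": block,
                        "trial_index": i,
                        "trial_type": t.trial_type,
                        "directions": "".join("+" if d == 1 else "-" for d in t.directions),
                        "correct_target": t.correct_target,
                    }
                )
            sim = sim.copy()
            sim["subject_id"] = subject_index
            sim["block"] = block
            sim["raw_rt_s"] = sim["dt_ms"] / 1000.0 + baseline
            decision_frames.append(sim)
    trials_df = pd.DataFrame(trial_rows)
    decisions_df = pd.concat(decision_frames, ignore_index=True)
    return trials_df, decisions_df, baseline, truth


def generate_study(config: SyntheticStudyConfig | None = None) -> StudyBundle:
    """Generate the full cohort; deterministic in the config's master seed."""
    config = config or SyntheticStudyConfig()
    all_trials, all_decisions, base_rows = [], [], []
    truth: dict = {}
    for i in range(config.n_subjects):
        trials, decisions, baseline, subject_truth = generate_subject(config, i)
        all_trials.append(trials)
        all_decisions.append(decisions)
        base_rows.append({"subject_id": i, "baseline_rt_s": baseline})
        truth[i] = {
            "model": config.model,
            "params": {k: vars(v).copy() for k, v in subject_truth.items()},
        }
    return StudyBundle(
        trials=pd.concat(all_trials, ignore_index=True),
        decisions=pd.concat(all_decisions, ignore_index=True),
        baseline=pd.DataFrame(base_rows),
        truth=truth,
        config=config,
    )
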