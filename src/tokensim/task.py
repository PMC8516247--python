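"""Tokens-task structures: trials, token states and the analytic success probability.

The tokens task presents ``n_tokens`` (15 by default, always odd) tokens in a
central circle.  Every ``jump_interval_ms`` one token jumps to the left or the
right target; the subject must guess which target will hold the majority when
all tokens have jumped.  Two conditions differ only in stimulus persistence:
in *all-stay* blocks jumped tokens remain visible, in *all-away* blocks they
disappear shortly after jumping, so the running counts must be held in working
memory.

Directions are encoded relative to the trial's designated correct target:
``+1`` means the token jumped toward it, ``-1`` away from it.  Which physical
side (left/right) plays the role of the correct target is an independent
uniform draw, so the model mathematics never touches screen geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TRIAL_TYPES",
    "CONDITIONS",
    "DEFAULT_TRIAL_MIX",
    "TaskConfig",
    "TokenState",
    "TokenTrial",
    "success_probability",
    "sp_profile",
    "generate_trial",
    "generate_block",
    "largest_remainder_counts",
]

TRIAL_TYPES = ("random", "easy", "ambiguous", "bias_for", "bias_against")
CONDITIONS = ("all_stay", "all_away")

#: Fraction of each trial type within a block (random trials fill half the
#: block so subjects cannot learn the predefined profiles).
DEFAULT_TRIAL_MIX: Mapping[str, float] = {
    "random": 0.50,
    "easy": 0.15,
    "ambiguous": 0.15,
    "bias_for": 0.10,
    "bias_against": 0.10,
}


@dataclass(frozen=True)
class TaskConfig:
    """Timing and block structure of the task.

    Durations are in milliseconds.  ``n_tokens`` must be odd so a strict
    majority always exists and no trial can end in a tie.
    """

    n_tokens: int = 15
    jump_interval_ms: float = 200.0
    post_decision_interval_ms: float = 20.0
    visibility_after_jump_ms: float = 200.0  # all-away condition only
    inter_trial_interval_ms: float = 500.0
    correct_per_block: int = 70
    n_blocks: int = 12

    def __post_init__(self) -> None:
        if self.n_tokens < 1 or self.n_tokens % 2 == 0:
            raise ValueError("n_tokens must be a positive odd integer")
        for name in (
            "jump_interval_ms",
            "post_decision_interval_ms",
            "visibility_after_jump_ms",
            "inter_trial_interval_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.correct_per_block < 1 or self.n_blocks < 1:
            raise ValueError("correct_per_block and n_blocks must be >= 1")

    @property
    def jump_onsets_ms(self) -> np.ndarray:
        """Onset time of each jump; the first token jumps one interval in."""
        return self.jump_interval_ms * np.arange(1, self.n_tokens + 1)

    @property
    def deadline_ms(self) -> float:
        """Subjects must commit before the last token jumps."""
        return self.jump_interval_ms * self.n_tokens


@dataclass(frozen=True)
class TokenState:
    """Token counts at some point within a trial (target one, target two, center)."""

    n1: int
    n2: int
    nr: int

    def validate(self, n_tokens: int = 15) -> None:
        if min(self.n1, self.n2, self.nr) < 0:
            raise ValueError("token counts must be non-negative")
        if self.n1 + self.n2 + self.nr != n_tokens:
            raise ValueError(
                f"token counts must sum to n_tokens={n_tokens}, "
                f"got {self.n1}+{self.n2}+{self.nr}"
            )


@lru_cache(maxsize=None)
def _sp(n1: int, n2: int, nr: int, n_tokens: int) -> float:
    # P(target one ends with the majority | n1, n2, nr).  Each remaining token
    # is a fair coin; target one wins iff at most floor(n/2) - n2 of the
    # remaining nr tokens go to target two, i.e.
    #   P = (nr! / 2^nr) * sum_{k=0}^{min(nr, floor(n/2)-n2)} 1 / (k! (nr-k)!)
    # The constant floor(n/2) is 7 for the standard 15-token task.
    kmax = min(nr, n_tokens // 2 - n2)
    if kmax < 0:
        return 0.0
    total = sum(comb(nr, k) for k in range(kmax + 1))
    return total / 2**nr


def success_probability(
    n1: int | TokenState, n2: int | None = None, nr: int | None = None,
    *, n_tokens: int = 15,
) -> float:
    """Probability that target one ends with the token majority.

    Accepts either a :class:`TokenState` or three counts ``(n1, n2, nr)``.
    Exact (rational arithmetic over the ``2**nr`` equiprobable completions).
    """
    if isinstance(n1, TokenState):
        state = n1
    else:
        if n2 is None or nr is None:
            raise TypeError("provide a TokenState or all three counts")
        state = TokenState(int(n1), int(n2), int(nr))
    state.validate(n_tokens)
    return _sp(state.n1, state.n2, state.nr, n_tokens)


@dataclass(frozen=True)
class TokenTrial:
    """One trial: the full jump sequence plus its labels.

    ``directions`` holds one entry per token, ``+1`` toward the designated
    correct target and ``-1`` toward the other.  For the four predefined
    types the designated target always wins the final majority; for random
    trials the coin flips are unconstrained and the realized majority (the
    side that is actually rewarded) is ``majority``.
    """

    directions: tuple[int, ...]
    trial_type: str
    condition: str = "all_stay"
    correct_target: str = "right"
    config: TaskConfig = field(default_factory=TaskConfig, repr=False)

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.correct_target not in ("left", "right"):
            raise ValueError("correct_target must be 'left' or 'right'")
        if len(self.directions) != self.config.n_tokens:
            raise ValueError("directions must have one entry per token")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError("directions must be +1 or -1")
        if self.trial_type != "random" and sum(self.directions) <= 0:
            raise ValueError(
                "the designated correct target must hold the final majority "
                "for non-random trial types"
            )

    @property
    def majority(self) -> int:
        """Sign of the realized final majority (+1 = designated target wins)."""
        return 1 if sum(self.directions) > 0 else -1

    def state_after(self, n_jumps: int) -> TokenState:
        """Token counts (toward-correct, away, remaining) after ``n_jumps``."""
        head = self.directions[:n_jumps]
        n1 = sum(1 for d in head if d == 1)
        return TokenState(n1, n_jumps - n1, self.config.n_tokens - n_jumps)


def sp_profile(trial: TokenTrial) -> np.ndarray:
    """Success probability of the designated correct target after each jump."""
    n = trial.config.n_tokens
    out = np.empty(n)
    n1 = 0
    for j, d in enumerate(trial.directions, start=1):
        if d == 1:
            n1 += 1
        out[j - 1] = _sp(n1, j - n1, n - j, n)
    return out


# ---------------------------------------------------------------------------
# Trial generation


def _bias_directions(rng: np.random.Generator, against: bool, n: int) -> tuple[int, ...]:
    # First six jumps: 3 toward / 3 away (order depending on the bias type);
    # of the remaining n - 6 jumps, n//2 minus 3 plus ... we fix 7 of the 9
    # remaining toward the correct target (15-token task) so the designated
    # target always finishes 10 vs 5.
    head = [-1, -1, -1, 1, 1, 1] if against else [1, 1, 1, -1, -1, -1]
    n_tail = n - 6
    n_toward = n_tail - 2  # 7 of 9 for the standard task
    tail = np.full(n_tail, -1, dtype=int)
    tail[rng.choice(n_tail, size=n_toward, replace=False)] = 1
    return tuple(head) + tuple(int(t) for t in tail)


def _easy_directions(rng: np.random.Generator, config: TaskConfig) -> tuple[int, ...]:
    # Rejection sampling: per-jump probability 0.85 toward the correct target,
    # accepted when the SP profile stays >= 0.60 from the third jump onward
    # (which also forces the designated target to win).
    n = config.n_tokens
    for _ in range(10_000):
        d = tuple(int(x) for x in np.where(rng.random(n) < 0.85, 1, -1))
        trial = TokenTrial(d, "random", config=config)
        prof = sp_profile(trial)
        if np.all(prof[2:] >= 0.60):
            return d
    raise RuntimeError("easy-trial rejection sampling failed to converge")


def _ambiguous_directions(rng: np.random.Generator, config: TaskConfig) -> tuple[int, ...]:
    # First ten jumps strictly alternate (random starting side), keeping the
    # SP pinned near 0.5; the last five favor the correct target (p = 0.85).
    # Accepted when SP stays within [0.34, 0.66] through jump ten and the
    # correct target wins.  (0.34/0.66 is the exact range an alternating
    # 15-token profile reaches at jump nine: 22/64 and 42/64.)
    n = config.n_tokens
    n_alt = min(10, n - 1)
    for _ in range(10_000):
        start = 1 if rng.random() < 0.5 else -1
        head = [start * (-1) ** i for i in range(n_alt)]
        tail = [int(x) for x in np.where(rng.random(n - n_alt) < 0.85, 1, -1)]
        d = tuple(head) + tuple(tail)
        if sum(d) <= 0:
            continue
        trial = TokenTrial(d, "random", config=config)
        prof = sp_profile(trial)
        if np.all((prof[:n_alt] >= 0.34) & (prof[:n_alt] <= 0.66)):
            return d
    raise RuntimeError("ambiguous-trial rejection sampling failed to converge")


def generate_trial(
    trial_type: str,
    condition: str = "all_stay",
    rng: np.random.Generator | int | None = None,
    config: TaskConfig | None = None,
) -> TokenTrial:
    """Draw one trial of the requested type.

    ``rng`` may be a :class:`numpy.random.Generator`, a seed, or ``None``.
    """
    rng = np.random.default_rng(rng)
    config = config or TaskConfig()
    n = config.n_tokens
    if trial_type == "random":
        directions = tuple(int(x) for x in np.where(rng.random(n) < 0.5, 1, -1))
    elif trial_type == "easy":
        directions = _easy_directions(rng, config)
    elif trial_type == "ambiguous":
        directions = _ambiguous_directions(rng, config)
    elif trial_type == "bias_for":
        directions = _bias_directions(rng, against=False, n=n)
    elif trial_type == "bias_against":
        directions = _bias_directions(rng, against=True, n=n)
    else:
        raise ValueError(f"unknown trial_type {trial_type!r}")
    correct_target = "right" if rng.random() < 0.5 else "left"
    return TokenTrial(directions, trial_type, condition, correct_target, config)


def largest_remainder_counts(
    n: int, proportions: Mapping[str, float]
) -> dict[str, int]:
    """Apportion ``n`` items to categories by the largest-remainder method.

    Deterministic: ties in the fractional part are broken by the iteration
    order of ``proportions``.
    """
    total = float(sum(proportions.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {total}")
    names = list(proportions)
    quotas = np.array([n * proportions[k] for k in names])
    counts = np.floor(quotas).astype(int)
    remainder = n - int(counts.sum())
    if remainder:
        order = np.argsort(-(quotas - counts), kind="stable")
        for i in order[:remainder]:
            counts[i] += 1
    return dict(zip(names, (int(c) for c in counts)))


def generate_block(
    n_trials: int,
    condition: str = "all_stay",
    rng: np.random.Generator | int | None = None,
    mix: Mapping[str, float] | None = None,
    config: TaskConfig | None = None,
) -> list[TokenTrial]:
    """Generate a shuffled block whose type counts match ``mix`` up to rounding."""
    rng = np.random.default_rng(rng)
    mix = dict(mix or DEFAULT_TRIAL_MIX)
    unknown = set(mix) - set(TRIAL_TYPES)
    if unknown:
        raise ValueError(f"unknown trial types in mix: {sorted(unknown)}")
    counts = largest_remainder_counts(n_trials, mix)
    trials = [
        generate_trial(t, condition, rng, config)
        for t, c in counts.items()
        for _ in range(c)
    ]
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]
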