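"""Quantile maximum products estimation (QMPE) with a differential-evolution search.

The fit objective sorts the observed decision times into inter-quantile bins,
separately for correct and error responses, and scores a candidate parameter
set by the log product of the model-predicted bin probabilities raised to the
observed counts:

    statistic = sum_bins  n_obs(bin) * log p_pred(bin),

where ``p_pred(bin)`` is the fraction of a large Monte-Carlo sample of
simulated decisions that lands in the bin (jointly over outcome and bin, so
outcomes are weighted by their observed frequencies through the counts), and
is floored at 1e-10 so empty bins stay finite.  When fewer than
``min_error_count`` error responses were observed, all errors collapse into a
single bin.

Candidate parameter sets are evaluated with common random numbers — one fixed
set of drift/noise draws per fit — so the objective is deterministic and the
search well behaved.  The search itself is differential evolution (best/1/bin,
F = 0.8, CR = 0.9), restarted from independent initial populations to avoid
local maxima; ``nu``, ``eta`` and ``theta`` are searched on a log10 scale
because their plausible ranges span several decades (a linear scale buries
the small-``eta`` regime in a sliver of the search space and the population
never reaches it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .models import ModelParams, _simulate_core, _step_indices, leaky_filter
from .task import TaskConfig, TokenTrial

__all__ = [
    "QuantileSpec",
    "SearchConfig",
    "FitResult",
    "DEFAULT_BOUNDS",
    "FITTED_TRIAL_TYPES",
    "qmpe_statistic",
    "fit_model",
    "model_predictions",
]

#: Trial types entering the fit; random trials are excluded.
FITTED_TRIAL_TYPES = ("easy", "ambiguous", "bias_for", "bias_against")

_EPS = 1e-10

#: Wide search bounds bracketing typical fitted values by well over 5x on
#: each side.  Lower bounds of log-searched parameters are small positive
#: floors rather than zero.
DEFAULT_BOUNDS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "eam": {"nu": (1e-3, 20.0), "eta": (1e-4, 50.0), "theta": (1e-3, 5.0)},
    "ugm": {"nu": (1e-2, 20.0), "eta": (1e-3, 50.0), "theta": (1.0, 1e5)},
    "leak": {"leak": (0.0, 1.0)},
}


@dataclass(frozen=True)
class QuantileSpec:
    """Quantile probabilities defining the QMPE bins (six bins per outcome)."""

    probs: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    min_error_count: int = 5

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if p.ndim != 1 or len(p) == 0 or np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("probs must lie strictly inside (0, 1)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("probs must be strictly increasing")


@dataclass(frozen=True)
class SearchConfig:
    """Differential-evolution settings and the per-candidate simulation size."""

    particles: int = 100
    iterations: int = 500
    restarts: int = 5
    n_sim_trials: int = 2000
    mutation: float = 0.8
    recombination: float = 0.9
    tol: float = 0.01
    prediction_reps: int = 10_000


@dataclass
class FitResult:
    """Best-fitting parameters and search diagnostics."""

    params: ModelParams
    objective: float
    model: str
    condition: str
    per_restart_objectives: list[float]
    bounds: dict[str, tuple[float, float]]
    search_config: SearchConfig
    seed: int | None = None

    @property
    def n_restarts(self) -> int:
        return len(self.per_restart_objectives)


class _QmpeBinner:
    """Observed-data binning, precomputed once per fit."""

    def __init__(self, observed: Mapping[str, np.ndarray], spec: QuantileSpec):
        self.spec = spec
        self.outcomes: dict[str, dict] = {}
        total_obs = 0
        for outcome in ("correct", "error"):
            values = np.asarray(observed.get(outcome, ()), dtype=float)
            if values.size == 0:
                continue
            total_obs += values.size
            if outcome == "error" and values.size < spec.min_error_count:
                # too few errors to resolve a distribution shape
                self.outcomes[outcome] = {"collapsed": True, "n": values.size}
                continue
            edges = np.quantile(values, spec.probs)
            counts = np.bincount(
                np.searchsorted(edges, values, side="left"),
                minlength=len(edges) + 1,
            )
            self.outcomes[outcome] = {
                "collapsed": False,
                "edges": edges,
                "counts": counts,
            }
        if total_obs == 0:
            raise ValueError("observed decision set is empty")

    def statistic(self, predicted: Mapping[str, np.ndarray]) -> float:
        total_pred = sum(
            np.asarray(predicted.get(o, ())).size for o in ("correct", "error")
        )
        if total_pred == 0:
            raise ValueError("predicted decision set is empty")
        stat = 0.0
        for outcome, info in self.outcomes.items():
            pred = np.asarray(predicted.get(outcome, ()), dtype=float)
            if info["collapsed"]:
                p = max(pred.size / total_pred, _EPS)
                stat += info["n"] * math.log(p)
                continue
            p_bin = (
                np.bincount(
                    np.searchsorted(info["edges"], pred, side="left"),
                    minlength=len(info["edges"]) + 1,
                )
                / total_pred
            )
            stat += float(info["counts"] @ np.log(np.maximum(p_bin, _EPS)))
        return stat


def qmpe_statistic(
    observed: Mapping[str, Sequence[float]],
    predicted: Mapping[str, Sequence[float]],
    spec: QuantileSpec | None = None,
) -> float:
    """QMPE log statistic of a predicted sample against observed quantile bins.

    ``observed`` and ``predicted`` map outcome (``"correct"``/``"error"``) to
    decision times.  Larger is better; the maximum value 0 is reached when
    every observed bin has predicted probability 1 (degenerate concentration).
    """
    return _QmpeBinner(observed, spec or QuantileSpec()).statistic(predicted)


# ---------------------------------------------------------------------------
# Model fitting


def _split_by_outcome(decisions: pd.DataFrame) -> dict[str, np.ndarray]:
    correct = decisions["correct"].to_numpy(dtype=bool)
    dts = decisions["dt_ms"].to_numpy(dtype=float)
    return {"correct": dts[correct], "error": dts[~correct]}


def _bounds_for(model: str, fit_leak: bool, overrides=None):
    bounds = dict(DEFAULT_BOUNDS[model])
    if fit_leak:
        bounds["leak"] = DEFAULT_BOUNDS["leak"]["leak"]
    if overrides:
        bounds.update(overrides)
    for name, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"inverted bounds for {name}: ({lo}, {hi})")
    return bounds


def _fitted_trials(trials: Sequence[TokenTrial]) -> list[TokenTrial]:
    kept = [t for t in trials if t.trial_type in FITTED_TRIAL_TYPES]
    return kept if kept else list(trials)


def fit_model(
    trials: Sequence[TokenTrial],
    observed: pd.DataFrame | Mapping[str, Sequence[float]],
    model: str,
    condition: str = "all_stay",
    fit_leak: bool = False,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    search: SearchConfig | None = None,
    quantiles: QuantileSpec | None = None,
    drift_resampling: str = "per_step",
    seed: int | None = None,
) -> FitResult:
    """Fit ``nu``, ``eta``, ``theta`` (and optionally ``leak``) by QMPE + DE.

    ``trials`` supplies the token sequences used to generate the candidate
    predictions (random trials are dropped, mirroring the fitted trial set);
    ``observed`` is a decision log with ``dt_ms`` and ``correct`` columns, or
    an outcome→decision-times mapping.  The order of the observed decisions
    is irrelevant — only their quantiles enter the statistic.
    """
    if model not in ("eam", "ugm"):
        raise ValueError(f"unknown model {model!r}")
    search = search or SearchConfig()
    qspec = quantiles or QuantileSpec()
    bounds_map = _bounds_for(model, fit_leak, bounds)

    if isinstance(observed, pd.DataFrame):
        observed_split = _split_by_outcome(observed)
    else:
        observed_split = {
            k: np.asarray(v, dtype=float) for k, v in observed.items()
        }
    binner = _QmpeBinner(observed_split, qspec)

    trials = _fitted_trials(trials)
    cfg = trials[0].config
    n_trials = len(trials)
    reps = max(1, math.ceil(search.n_sim_trials / n_trials))
    directions = np.array([t.directions for t in trials], dtype=float)
    directions = np.tile(directions, (reps, 1))
    majority = np.tile(
        np.array([t.majority for t in trials], dtype=np.int8), reps
    )
    n_sim = directions.shape[0]

    deadline = cfg.deadline_ms
    base = ModelParams(nu=1.0, eta=0.0, theta=1.0)
    n_steps = int(round(deadline / base.dt_ms))
    idx = _step_indices(n_steps, base.dt_ms, cfg.jump_onsets_ms)

    ss = np.random.SeedSequence(seed)
    crn_rng = np.random.default_rng(ss.spawn(1)[0])
    drift_shape = (n_sim, n_steps) if drift_resampling == "per_step" else (n_sim, 1)
    drift_z = crn_rng.standard_normal(drift_shape)
    noise = crn_rng.standard_normal((n_sim, n_steps))
    tie_rng = np.random.default_rng(12345)  # censoring tie-break, rarely used

    names = ["nu", "eta", "theta"] + (["leak"] if fit_leak else [])
    log_scaled = {"nu", "eta", "theta"}

    def to_params(v: np.ndarray) -> ModelParams:
        vals = {}
        for name, value in zip(names, v):
            vals[name] = 10.0**value if name in log_scaled else float(value)
        if not fit_leak:
            vals["leak"] = 0.0
        return ModelParams(drift_resampling=drift_resampling, **vals)

    e_step_cache: dict[float, np.ndarray] = {}

    def e_step_for(leak: float) -> np.ndarray:
        key = round(leak, 12)
        if key not in e_step_cache:
            if len(e_step_cache) > 64:
                e_step_cache.clear()
            e_jump = (
                leaky_filter(directions, leak) if leak else np.cumsum(directions, axis=1)
            )
            e_pad = np.concatenate([np.zeros((n_sim, 1)), e_jump], axis=1)
            e_step_cache[key] = e_pad[:, idx]
        return e_step_cache[key]

    def negative_statistic(v: np.ndarray) -> float:
        params = to_params(v)
        drift = params.nu + params.eta * drift_z
        choice, dt_out, _ = _simulate_core(
            model, e_step_for(params.leak), drift, noise, params, deadline, tie_rng
        )
        correct = choice == majority
        predicted = {"correct": dt_out[correct], "error": dt_out[~correct]}
        return -binner.statistic(predicted)

    de_bounds = [
        (math.log10(lo), math.log10(hi)) if name in log_scaled else (lo, hi)
        for name, (lo, hi) in ((n, bounds_map[n]) for n in names)
    ]

    best_v, best_obj = None, -np.inf
    per_restart: list[float] = []
    for child in ss.spawn(search.restarts):
        rng = np.random.default_rng(child)
        init = rng.uniform(
            [lo for lo, _ in de_bounds],
            [hi for _, hi in de_bounds],
            size=(max(search.particles, 5), len(de_bounds)),
        )
        result = differential_evolution(
            negative_statistic,
            de_bounds,
            strategy="best1bin",
            maxiter=search.iterations,
            init=init,
            mutation=search.mutation,
            recombination=search.recombination,
            tol=search.tol,
            seed=int(rng.integers(2**31 - 1)),
            polish=False,
        )
        per_restart.append(-float(result.fun))
        if -result.fun > best_obj:
            best_obj = -float(result.fun)
            best_v = result.x

    return FitResult(
        params=to_params(best_v),
        objective=best_obj,
        model=model,
        condition=condition,
        per_restart_objectives=per_restart,
        bounds={k: tuple(v) for k, v in bounds_map.items()},
        search_config=search,
        seed=seed,
    )


def model_predictions(
    fit: FitResult,
    trials: Sequence[TokenTrial],
    n_reps: int | None = None,
    rng: np.random.Generator | int | None = None,
    observed: pd.DataFrame | None = None,
) -> dict:
    """Monte-Carlo predictions at the best-fitting parameters.

    Simulates roughly ``n_reps`` decisions (default 10,000) over the fitted
    trial set, plus a resample matched in size and outcome composition to the
    observed data for side-by-side distribution comparison.  When ``observed``
    is given, reports the absolute difference between observed and predicted
    mean decision times separately for correct and error responses (ms).
    """
    from .models import simulate_dataset

    rng = np.random.default_rng(rng)
    trials = _fitted_trials(trials)
    total = n_reps if n_reps is not None else fit.search_config.prediction_reps
    reps = max(1, math.ceil(total / len(trials)))
    predicted = simulate_dataset(trials, fit.model, fit.params, reps, rng)

    out: dict = {"decisions": predicted}
    if observed is not None:
        obs = _split_by_outcome(observed)
        pred = _split_by_outcome(predicted)
        discrepancy = {}
        matched_parts = []
        for outcome in ("correct", "error"):
            if obs[outcome].size and pred[outcome].size:
                discrepancy[outcome] = abs(
                    float(np.mean(obs[outcome])) - float(np.mean(pred[outcome]))
                )
                pool = predicted[predicted["correct"] == (outcome == "correct")]
                take = rng.choice(len(pool), size=obs[outcome].size, replace=True)
                matched_parts.append(pool.iloc[take])
        out["mean_dt_discrepancy_ms"] = discrepancy
        if matched_parts:
            out["matched"] = pd.concat(matched_parts, ignore_index=True)
    return out
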