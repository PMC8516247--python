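"""Reading and writing trial logs, decision logs and parameter files.

Trial logs are CSV with one row per trial; the jump sequence is stored as a
string of ``R``/``L`` characters (the physical jump directions after the
correct target has been assigned a side), so a log is self-contained even
without the relative ±1 encoding.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .fitting import FitResult, SearchConfig
from .models import ModelParams
from .synthetic import StudyBundle, SyntheticStudyConfig
from .task import TaskConfig, TokenTrial

__all__ = [
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "write_params",
    "read_params",
    "write_fit",
    "save_study",
    "load_study",
]


def _to_sides(directions, correct_target: str) -> str:
    toward = "R" if correct_target == "right" else "L"
    away = "L" if toward == "R" else "R"
    return "".join(toward if d == 1 else away for d in directions)


def _from_sides(sides: str, correct_target: str) -> tuple[int, ...]:
    toward = "R" if correct_target == "right" else "L"
    return tuple(1 if c == toward else -1 for c in sides)


def trials_to_frame(trials, subject_id=0, block=0) -> pd.DataFrame:
    rows = [
        {
            "subject_id": subject_id,
            "condition": t.condition,
            "block": block,
            "trial_index": i,
            "trial_type": t.trial_type,
            "directions": _to_sides(t.directions, t.correct_target),
            "correct_target": t.correct_target,
        }
        for i, t in enumerate(trials)
    ]
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame, config: TaskConfig | None = None):
    config = config or TaskConfig()
    trials = []
    for row in frame.itertuples(index=False):
        d = row.directions
        directions = (
            _from_sides(d, row.correct_target)
            if set(d) <= {"R", "L"}
            else tuple(1 if c == "+" else -1 for c in d)
        )
        trials.append(
            TokenTrial(directions, row.trial_type, row.condition, row.correct_target, config)
        )
    return trials


def write_trials(trials, path, subject_id=0, block=0) -> None:
    trials_to_frame(trials, subject_id, block).to_csv(path, index=False)


def read_trials(path, config: TaskConfig | None = None):
    return frame_to_trials(pd.read_csv(path), config)


def write_params(params: ModelParams, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(params), indent=2) + "\n")


def read_params(path) -> ModelParams:
    return ModelParams(**json.loads(Path(path).read_text()))


def write_fit(fit: FitResult, path) -> None:
    payload = {
        "model": fit.model,
        "condition": fit.condition,
        "params": dataclasses.asdict(fit.params),
        "objective": fit.objective,
        "per_restart_objectives": fit.per_restart_objectives,
        "bounds": {k: list(v) for k, v in fit.bounds.items()},
        "search_config": dataclasses.asdict(fit.search_config),
        "seed": fit.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def save_study(bundle: StudyBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(out / "trials.csv", index=False)
    bundle.decisions.to_csv(out / "decisions.csv", index=False)
    bundle.baseline.to_csv(out / "baseline.csv", index=False)
    truth = {
        str(k): {"model": v["model"], "params": {c: p for c, p in v["params"].items()}}
        for k, v in bundle.truth.items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    cfg = dataclasses.asdict(bundle.config)
    cfg["trial_mix"] = dict(cfg["trial_mix"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_study(in_dir) -> dict:
    src = Path(in_dir)
    return {
        "trials": pd.read_csv(src / "trials.csv"),
        "decisions": pd.read_csv(src / "decisions.csv"),
        "baseline": pd.read_csv(src / "baseline.csv"),
        "truth": json.loads((src / "truth.json").read_text()),
        "config": yaml.safe_load((src / "config.yaml").read_text()),
    }
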