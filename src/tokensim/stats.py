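"""Behavioral summaries and statistical tests for tokens-task decision logs.

Decision times (DTs) are reaction times minus the subject's baseline reaction
time, estimated from single-token calibration trials.  Summaries (mean ± SEM
of DT and of the success probability at decision time, per subject x
condition x trial type) use correct trials only by default, with an explicit
flag to pool correct and error trials (the pooling the fitting stage uses).

Group-level comparisons are paired-samples t-tests on per-subject means,
complemented by JZS Bayes factors: the standardized effect size gets a
Cauchy prior (scale 3 for DT contrasts, where large effects are expected;
0.707 for SP contrasts) and BF10 is the ratio of the marginal likelihood of
the observed t statistic under that prior to its likelihood under the point
null, computed by adaptive quadrature over the noncentrality parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

__all__ = [
    "decision_time",
    "decision_times",
    "attach_decision_times",
    "paired_comparison",
    "bayes_factor_ttest",
    "bayes_factor_paired",
    "normality_check",
    "two_sample_distribution_test",
    "summarize_subjects",
    "compare_trial_types",
    "analyze_study",
]

#: Cauchy prior scales used for the two families of contrasts.
DT_BF_SCALE = 3.0
SP_BF_SCALE = 0.707


def decision_time(raw_rt_s: float, baseline_rt_s: float) -> float:
    """Baseline-corrected decision time in seconds; invalid if non-positive."""
    dt = raw_rt_s - baseline_rt_s
    if dt <= 0:
        raise ValueError(
            f"non-positive decision time ({raw_rt_s} - {baseline_rt_s}); "
            "trial must be excluded"
        )
    return dt


def decision_times(raw_rt_s, baseline_rt_s) -> np.ndarray:
    """Vectorized baseline subtraction; invalid trials become NaN."""
    dt = np.asarray(raw_rt_s, dtype=float) - np.asarray(baseline_rt_s, dtype=float)
    return np.where(dt > 0, dt, np.nan)


def attach_decision_times(
    decisions: pd.DataFrame, baseline: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Add a ``dt_s`` column from raw RTs and per-subject baselines.

    ``baseline`` maps ``subject_id`` to ``baseline_rt_s``.  Without raw RTs
    (pure simulation logs) ``dt_ms`` is converted directly.  Invalid
    (non-positive) decision times are dropped.
    """
    decisions = decisions.copy()
    if baseline is not None and "raw_rt_s" in decisions:
        base = baseline.set_index("subject_id")["baseline_rt_s"]
        decisions["dt_s"] = decision_times(
            decisions["raw_rt_s"], decisions["subject_id"].map(base)
        )
    elif "dt_ms" in decisions:
        decisions["dt_s"] = decisions["dt_ms"] / 1000.0
    else:
        raise ValueError("decision log needs raw_rt_s + baseline, or dt_ms")
    return decisions.dropna(subset=["dt_s"])


def paired_comparison(values_a, values_b) -> tuple[float, float]:
    """Paired-samples t-test on equal-length vectors; returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def bayes_factor_ttest(t: float, n: int, scale: float = 0.707) -> float:
    """JZS Bayes factor (BF10) for a one-sample/paired t statistic.

    Marginalizes the likelihood of ``t`` over a Cauchy(0, scale) prior on the
    standardized effect size delta, using the noncentral-t density with
    noncentrality ``delta * sqrt(n)``:

        BF10 = [ integral f_nct(t; n-1, delta sqrt(n)) dCauchy(delta) ]
               / f_t(t; n-1).
    """
    if n < 2:
        raise ValueError("need at least two observations")
    if scale <= 0:
        raise ValueError("scale must be positive")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(phi: float) -> float:
        # delta = scale * tan(phi) maps the Cauchy prior to Uniform(-pi/2, pi/2)
        delta = scale * np.tan(phi)
        return sps.nct.pdf(t, df, delta * sqrt_n) / np.pi

    marginal, _ = integrate.quad(
        integrand, -np.pi / 2, np.pi / 2, epsabs=1e-12, epsrel=1e-10, limit=400
    )
    return float(marginal / sps.t.pdf(t, df))


def bayes_factor_paired(differences, scale: float = 0.707) -> float:
    """JZS Bayes factor for paired differences (BF10 > 1 favors an effect)."""
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need a 1-d vector of at least two differences")
    sd = d.std(ddof=1)
    if np.allclose(d, d[0]):
        raise ValueError("zero-variance differences")
    t = d.mean() / (sd / np.sqrt(len(d)))
    return bayes_factor_ttest(float(t), len(d), scale)


def normality_check(values) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, p).  Requires 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant sample")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def two_sample_distribution_test(values_a, values_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test; returns (D, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    d, p = sps.ks_2samp(a, b)
    return float(d), float(p)


# ---------------------------------------------------------------------------
# Study-level summaries


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def summarize_subjects(
    decisions: pd.DataFrame, correct_only: bool = True
) -> pd.DataFrame:
    """Per subject x condition x trial type mean ± SEM of DT (s) and SP.

    ``decisions`` must carry ``dt_s`` (see :func:`attach_decision_times`),
    ``sp_at_dt``, ``correct``, ``condition``, ``trial_type`` and
    ``subject_id``.  Trial order is irrelevant.
    """
    d = decisions
    if correct_only:
        d = d[d["correct"]]
    if "subject_id" not in d:
        d = d.assign(subject_id=0)
    rows = []
    for (subject, condition, ttype), grp in d.groupby(
        ["subject_id", "condition", "trial_type"], sort=True
    ):
        dt = grp["dt_s"].to_numpy()
        sp = grp["sp_at_dt"].to_numpy()
        rows.append(
            {
                "subject_id": subject,
                "condition": condition,
                "trial_type": ttype,
                "n_trials": len(grp),
                "mean_dt_s": float(dt.mean()),
                "sem_dt_s": _sem(dt),
                "mean_sp": float(sp.mean()),
                "sem_sp": _sem(sp),
            }
        )
    return pd.DataFrame(rows)


def compare_trial_types(
    summary: pd.DataFrame,
    condition: str,
    type_a: str,
    type_b: str,
    measure: str = "mean_dt_s",
    bf_scale: float | None = None,
) -> dict:
    """Paired comparison of per-subject means between two trial types.

    Returns the t statistic, two-sided p value, JZS Bayes factor and the
    group means of ``measure`` (a summary column) for ``type_a`` and
    ``type_b``.  The Bayes-factor prior scale defaults to 3 for DT measures
    and 0.707 for SP measures.
    """
    if bf_scale is None:
        bf_scale = SP_BF_SCALE if "sp" in measure else DT_BF_SCALE
    sub = summary[summary["condition"] == condition]
    pivot = sub.pivot_table(
        index="subject_id", columns="trial_type", values=measure
    )[[type_a, type_b]].dropna()
    a = pivot[type_a].to_numpy()
    b = pivot[type_b].to_numpy()
    t, p = paired_comparison(a, b)
    try:
        bf = bayes_factor_paired(a - b, bf_scale)
    except ValueError:
        bf = float("nan")
    return {
        "condition": condition,
        "measure": measure,
        "type_a": type_a,
        "type_b": type_b,
        "n_subjects": len(pivot),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": t,
        "p": p,
        "bf10": bf,
    }


def analyze_study(
    decisions: pd.DataFrame,
    baseline: pd.DataFrame | None = None,
    correct_only: bool = True,
) -> dict:
    """The standard analysis battery for a full study.

    Produces, per condition: the easy-vs-ambiguous and bias_against-vs-
    bias_for contrasts of decision time and of success probability at DT
    (paired t, p, BF10), plus the summary table and overall accuracy.
    """
    withdt = attach_decision_times(decisions, baseline)
    if "subject_id" not in withdt:
        withdt = withdt.assign(subject_id=0)
    summary = summarize_subjects(withdt, correct_only=correct_only)
    contrasts = []
    for condition in sorted(withdt["condition"].unique()):
        for type_a, type_b in (("easy", "ambiguous"), ("bias_against", "bias_for")):
            for measure in ("mean_dt_s", "mean_sp"):
                try:
                    contrasts.append(
                        compare_trial_types(summary, condition, type_a, type_b, measure)
                    )
                except (KeyError, ValueError):
                    continue
    accuracy = (
        withdt.groupby(["subject_id", "condition"])["correct"]
        .mean()
        .groupby("condition")
        .agg(["mean", "sem"])
        .rename(columns={"mean": "accuracy", "sem": "sem_accuracy"})
        .reset_index()
    )
    return {"summary": summary, "contrasts": contrasts, "accuracy": accuracy}
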