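"""Evidence traces and the two decision models."""

import dataclasses

import numpy as np
import pytest

from tokensim.models import (
    URGENCY_PER_MS,
    EvidenceTrace,
    ModelParams,
    evidence_from_trial,
    leaky_filter,
    simulate_dataset,
    simulate_eam,
    simulate_ugm,
)
from tokensim.task import generate_trial

from conftest import make_trial


def flat_trace(value=1.0, n=30, spacing=200.0, start=0.0):
    """Trace holding ``value`` from time ``start`` onward (constant evidence)."""
    times = start + spacing * np.arange(n)
    if start == 0.0:
        times = np.concatenate([[0.0], times[1:]]) if n > 1 else np.array([0.0])
    e = np.full(n, value)
    return EvidenceTrace(times, e, e)


class TestEvidence:
    def test_pure_counting_without_leak(self):
        t = make_trial([1, 1, 1] + [1, -1] * 6)
        trace = evidence_from_trial(t, leak=0.0)
        assert list(trace.e[:3]) == [1, 2, 3]
        assert np.array_equal(trace.e, trace.e_leak)
        assert np.all(np.abs(np.diff(trace.e)) == 1)

    def test_full_leak_remembers_only_newest_token(self):
        assert list(leaky_filter(np.array([1.0, 1.0]), 1.0)) == [1.0, 1.0]

    def test_half_leak_one_step(self):
        assert list(leaky_filter(np.array([1.0, 1.0]), 0.5)) == [1.0, 1.5]

    def test_leak_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            leaky_filter(np.array([1.0]), 1.5)

    def test_trace_value_frozen_between_jumps(self):
        t = make_trial([1] * 15)
        trace = evidence_from_trial(t)
        assert trace.value_at(199.9) == 0.0  # before the first jump
        assert trace.value_at(200.0) == 1.0  # update exactly at onset
        assert trace.value_at(399.9) == 1.0
        assert trace.value_at(400.0) == 2.0


class TestClosedForms:
    """Noise-free simulations must match the analytic crossing step."""

    # theta values chosen off the step grid so the crossing step is
    # unambiguous under floating-point accumulation
    @pytest.mark.parametrize("nu, theta", [(2.0, 0.31), (0.05, 0.2931), (1.0, 0.043)])
    def test_eam_crossing_time(self, nu, theta):
        params = ModelParams(nu=nu, eta=0.0, theta=theta, s=0.0)
        trace = flat_trace(1.0)
        dec = simulate_eam(trace, params, rng=0, deadline_ms=6000.0)
        dt_s = params.dt_ms / 1000.0
        n = int(np.ceil(theta / 2.0 / (nu * dt_s)))
        assert dec.dt_ms == pytest.approx(n * params.dt_ms - params.dt_ms / 2)
        assert dec.choice == 1 and not dec.censored

    def test_eam_negative_evidence_hits_lower_bound(self):
        params = ModelParams(nu=1.0, eta=0.0, theta=0.1, s=0.0)
        dec = simulate_eam(flat_trace(-1.0), params, rng=0, deadline_ms=3000.0)
        assert dec.choice == -1

    @pytest.mark.parametrize("nu, theta", [(4.0, 20000.0), (1.0, 2000.0)])
    def test_ugm_crossing_time(self, nu, theta):
        params = ModelParams(nu=nu, eta=0.0, theta=theta, s=0.0)
        dec = simulate_ugm(flat_trace(1.0), params, rng=0, deadline_ms=6000.0)
        # independent recursion of the stated low-pass dynamics
        a = params.tau_ms / (params.tau_ms + params.dt_ms)
        x, k = 0.0, 0
        while True:
            k += 1
            x = a * x + (1 - a) * nu * 1.0 * (params.dt_ms / 1000.0)
            if x * URGENCY_PER_MS * k * params.dt_ms > theta:
                break
        assert dec.dt_ms == pytest.approx(k * params.dt_ms - params.dt_ms / 2)

    def test_dt_lies_on_half_step_grid(self, rng):
        params = ModelParams(nu=0.05, eta=0.02, theta=0.3)
        trial = generate_trial("random", rng=rng)
        for model in (simulate_eam, simulate_ugm):
            dec = model(trial, params, rng=rng)
            if not dec.censored:
                steps = (dec.dt_ms + params.dt_ms / 2) / params.dt_ms
                assert steps == pytest.approx(round(steps))
                assert 0 < dec.dt_ms <= trial.config.deadline_ms


class TestSymmetryAndLimits:
    def test_zero_evidence_choices_are_fair(self):
        params = ModelParams(nu=0.05, eta=0.0, theta=0.12, s=0.1)
        trace = EvidenceTrace([3000.0], [0.0], [0.0])
        rng = np.random.default_rng(99)
        choices = [simulate_eam(trace, params, rng=rng).choice for _ in range(4000)]
        # binomial 99% interval around 0.5 at n=4000
        assert abs(np.mean(np.array(choices) == 1) - 0.5) < 2.58 * 0.5 / np.sqrt(4000)

    def test_tiny_boundary_decides_first_step(self):
        params = ModelParams(nu=0.0, eta=0.0, theta=1e-12, s=0.1)
        dec = simulate_eam(flat_trace(0.0), params, rng=1, deadline_ms=3000.0)
        assert dec.dt_ms == pytest.approx(params.dt_ms / 2)

    def test_ugm_scale_invariance(self):
        # scaling (nu, eta, s, theta) jointly leaves every decision unchanged
        trial = generate_trial("ambiguous", rng=11)
        p = ModelParams(nu=4.0, eta=8.0, theta=18000.0)
        c = 3.7
        scaled = dataclasses.replace(
            p, nu=c * p.nu, eta=c * p.eta, s=c * p.s, theta=c * p.theta
        )
        for seed in range(5):
            d1 = simulate_ugm(trial, p, rng=seed)
            d2 = simulate_ugm(trial, scaled, rng=seed)
            assert d1 == d2

    def test_leak_zero_trace_equals_raw_trace(self):
        trial = generate_trial("bias_against", rng=3)
        t0 = evidence_from_trial(trial, leak=0.0)
        assert np.array_equal(t0.e, t0.e_leak)

    def test_per_trial_variant_is_available(self):
        params = ModelParams(nu=0.05, eta=0.02, theta=0.3, drift_resampling="per_trial")
        trial = generate_trial("easy", rng=2)
        dec = simulate_eam(trial, params, rng=2)
        assert dec.dt_ms > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(nu=1.0, eta=-0.1, theta=1.0)
        with pytest.raises(ValueError):
            ModelParams(nu=1.0, eta=0.0, theta=0.0)
        with pytest.raises(ValueError):
            ModelParams(nu=1.0, eta=0.0, theta=1.0, leak=1.2)
        with pytest.raises(ValueError):
            ModelParams(nu=1.0, eta=0.0, theta=1.0, drift_resampling="sometimes")


class TestSimulateDataset:
    def test_reproducible_and_shaped(self):
        trials = [generate_trial("easy", rng=s) for s in range(3)]
        params = ModelParams(nu=4.0, eta=8.0, theta=20000.0)
        a = simulate_dataset(trials, "ugm", params, n_reps=3, rng=42)
        b = simulate_dataset(trials, "ugm", params, n_reps=3, rng=42)
        assert len(a) == 9
        assert a.equals(b)

    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_dataset([], "eam", ModelParams(nu=1, eta=0, theta=1))

    def test_easy_faster_than_ambiguous_both_models(self):
        rng = np.random.default_rng(8)
        easy = [generate_trial("easy", rng=rng) for _ in range(60)]
        amb = [generate_trial("ambiguous", rng=rng) for _ in range(60)]
        for model, params in (
            ("eam", ModelParams(nu=0.04456, eta=0.00478, theta=0.29062)),
            ("ugm", ModelParams(nu=3.76432, eta=7.65377, theta=23022.92488)),
        ):
            de = simulate_dataset(easy, model, params, 5, rng)
            da = simulate_dataset(amb, model, params, 5, rng)
            assert de["dt_ms"].mean() < da["dt_ms"].mean()

    def test_sp_at_dt_is_valid_probability(self, rng):
        trials = [generate_trial("random", rng=rng) for _ in range(20)]
        d = simulate_dataset(trials, "eam", ModelParams(nu=0.05, eta=0.0, theta=0.3), 2, rng)
        assert d["sp_at_dt"].between(0, 1).all()
        # accuracy equals mean success probability of the chosen target in
        # expectation on coin-flip trials; loose 5-sigma check
        n = len(d)
        assert abs(d["correct"].mean() - d["sp_at_dt"].mean()) < 5 * 0.5 / np.sqrt(n)
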