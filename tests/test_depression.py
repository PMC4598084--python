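"""Synaptic depression: event-exact simulation, closed forms, matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatloop.depression import (
    DepressionParams,
    match_constituent,
    relative_strength_before_spike,
    simulate_depressing_synapse,
    slow_scale_summary,
)
from repeatloop.fixtures import generate_poisson_train

MODEL = DepressionParams(alpha=0.006, tau_R=3.25, g0=1.0)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": -0.1, "tau_R": 1.0},
            {"alpha": 1.0, "tau_R": 1.0},
            {"alpha": 0.5, "tau_R": 0.0},
            {"alpha": 0.5, "tau_R": 1.0, "g0": -1.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DepressionParams(**kwargs)


class TestEventExactSimulation:
    def test_single_spike_closed_form(self):
        # one spike at t=0 with alpha=0.5: g(t) = 1 - 0.5 exp(-t/tau_R)
        p = DepressionParams(alpha=0.5, tau_R=2.0, g0=1.0)
        t = np.array([0.0, 2.0 * math.log(2.0), 10.0])
        g = simulate_depressing_synapse(p, [0.0], t)
        assert g[0] == pytest.approx(0.5)
        assert g[1] == pytest.approx(0.75)
        assert g[2] == pytest.approx(1.0 - 0.5 * math.exp(-5.0))

    def test_empty_train_constant(self):
        g = simulate_depressing_synapse(MODEL, [], np.linspace(0, 5, 7))
        assert np.all(g == MODEL.g0)

    def test_strength_bounds(self):
        p = DepressionParams(alpha=0.3, tau_R=0.5, g0=2.0)
        spikes = np.linspace(0.01, 1.0, 50)
        g = simulate_depressing_synapse(p, spikes, np.linspace(0, 1, 200))
        assert np.all(g <= p.g0 + 1e-12)
        assert np.all(g >= 0.0)

    def test_unsorted_and_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_depressing_synapse(MODEL, [0.2, 0.1], [0.0])
        with pytest.raises(ValueError):
            simulate_depressing_synapse(MODEL, [-0.1, 0.2], [0.0])

    def test_regular_train_matches_closed_form(self):
        # oracle: the closed-form pre-spike strengths A_n
        f = 1340.0
        n = np.arange(1, 3001)
        spikes = (n - 1) / f
        queries = np.maximum(spikes - 1e-12, 0.0)
        g = simulate_depressing_synapse(MODEL, spikes, queries)
        a_n = relative_strength_before_spike(MODEL, f, n)
        # first query is at t=0 (post-spike); compare from n=2 onward
        rel = np.abs(g[1:] - a_n[1:]) / a_n[1:]
        assert rel.max() < 1e-9


class TestClosedForms:
    def test_first_spike_is_undepressed(self):
        assert relative_strength_before_spike(MODEL, 100.0, 1) == pytest.approx(1.0)

    def test_no_depression_stays_at_one(self):
        p = DepressionParams(alpha=0.0, tau_R=1.0)
        assert np.allclose(relative_strength_before_spike(p, 50.0, np.arange(1, 100)), 1.0)

    def test_fast_drive_limit_is_pure_geometric(self):
        # negligible recovery between spikes: A_n ~ (1-alpha)^(n-1)
        p = DepressionParams(alpha=0.5, tau_R=1e4)
        a = relative_strength_before_spike(p, 1000.0, np.arange(1, 10))
        assert np.allclose(a, 0.5 ** np.arange(9), rtol=1e-3)

    def test_monotone_nonincreasing(self):
        a = relative_strength_before_spike(MODEL, 1340.0, np.arange(1, 500))
        assert np.all(np.diff(a) <= 1e-15)

    def test_limit_is_steady_state(self):
        s = slow_scale_summary(MODEL, 1340.0)
        a_inf = relative_strength_before_spike(MODEL, 1340.0, 10_000_000)
        assert a_inf == pytest.approx(s.map_offset / (1.0 - s.map_ratio), rel=1e-12)
        assert a_inf == pytest.approx(s.g_inf_rel, rel=1e-12)

    def test_printed_model_synapse_values(self):
        s = slow_scale_summary(MODEL, 1340.0)
        assert s.g_inf_rel == pytest.approx(0.0369, abs=2e-4)
        assert s.tau_decay == pytest.approx(0.1194, abs=2e-4)

    def test_slow_drive_recovers_fully(self):
        s = slow_scale_summary(MODEL, 1e-4)
        assert s.g_inf_rel == pytest.approx(1.0, abs=1e-9)

    def test_total_depression_limit(self):
        p = DepressionParams(alpha=1.0 - 1e-12, tau_R=1.0)
        s = slow_scale_summary(p, 10.0)
        assert s.g_inf_rel == pytest.approx(1.0 - math.exp(-1.0 / 10.0), rel=1e-6)

    def test_alpha_zero_flagged_degenerate(self):
        s = slow_scale_summary(DepressionParams(alpha=0.0, tau_R=1.0), 10.0)
        assert s.degenerate
        assert s.g_inf_rel == 1.0

    @settings(max_examples=40, deadline=None)
    @given(
        alpha=st.floats(0.001, 0.9),
        tau_r=st.floats(0.01, 10.0),
        f=st.floats(1.0, 5000.0),
    )
    def test_tau_decay_monotone_in_rate_and_alpha(self, alpha, tau_r, f):
        p = DepressionParams(alpha=alpha, tau_R=tau_r)
        s = slow_scale_summary(p, f)
        assert s.tau_decay > 0
        assert slow_scale_summary(p, f * 1.5).tau_decay < s.tau_decay
        p2 = DepressionParams(alpha=min(alpha * 1.5, 0.95), tau_R=tau_r)
        assert slow_scale_summary(p2, f).tau_decay < s.tau_decay


class TestPoissonSlowScale:
    def test_mean_pre_spike_strength_matches_steady_state(self):
        # the regular-train steady state also fits Poisson drive at the same
        # mean rate: block-averaged pre-spike strengths vs g_inf_rel
        f = 1340.0
        spikes = generate_poisson_train(f, 80.0, seed=42)
        assert spikes.size > 100_000
        queries = spikes - 1e-12
        g = simulate_depressing_synapse(MODEL, spikes, queries)
        s = slow_scale_summary(MODEL, f)
        warm = spikes > 5.0 * s.tau_decay
        vals = g[warm]
        blocks = np.array_split(vals, 50)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(vals.mean() - s.g_inf_rel) < 3.0 * se


class TestConstituentMatching:
    def test_identity_for_single_constituent(self):
        m = match_constituent(MODEL, 1340.0, 1)
        assert (m.alpha_prime, m.tau_R_prime) == (MODEL.alpha, MODEL.tau_R)

    def test_reference_fifty_constituent_values(self):
        m = match_constituent(MODEL, 1340.0, 50)
        assert m.alpha_prime == pytest.approx(0.26, rel=0.02)
        assert m.tau_R_prime == pytest.approx(3.75, rel=0.02)

    @pytest.mark.parametrize("n", [2, 10, 50, 200])
    def test_round_trip_reproduces_slow_scale(self, n):
        # substitute the matched parameters back into the closed forms
        m = match_constituent(MODEL, 1340.0, n)
        target = slow_scale_summary(MODEL, 1340.0)
        sub = slow_scale_summary(
            DepressionParams(alpha=m.alpha_prime, tau_R=m.tau_R_prime), 1340.0 / n
        )
        assert abs(sub.g_inf_rel - target.g_inf_rel) < 1e-8
        assert abs(sub.tau_decay - target.tau_decay) / target.tau_decay < 1e-8
        assert m.residual < 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            match_constituent(MODEL, 1340.0, 0)
        with pytest.raises(ValueError):
            match_constituent(DepressionParams(alpha=0.0, tau_R=1.0), 100.0, 5)
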