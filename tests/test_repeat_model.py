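"""Sigmoidal adaptation model: forward law, distributions, fitting, comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatloop.repeat_model import (
    ChainState,
    RepeatHistogram,
    SigmoidalParams,
    StateChainModel,
    benchmark_error,
    distribution_distance,
    feedback_at_repeat,
    fit_sigmoidal,
    fit_state_chain,
    peak_repeat_number,
    phase_diagram,
    repeat_distribution,
    repeat_prob_at,
    repeat_prob_vs_feedback,
    simulate_bouts,
    state_chain_distribution,
)
from tests.conftest import simulate_bouts_mc


class TestSigmoidOfFeedback:
    def test_zero_feedback_gives_exit_bias(self):
        assert repeat_prob_vs_feedback(0.0, eta=2.0, nu=1.5, c=0.9) == pytest.approx(0.1)

    def test_large_feedback_approaches_one(self):
        assert repeat_prob_vs_feedback(1e12, eta=1.0, nu=1.0, c=0.9) == pytest.approx(1.0, abs=1e-9)

    def test_hand_value(self):
        assert repeat_prob_vs_feedback(1.0, eta=1.0, nu=1.0, c=0.5) == pytest.approx(0.75)

    def test_monotone_increasing_in_feedback(self):
        A = np.linspace(0, 10, 100)
        p = repeat_prob_vs_feedback(A, eta=3.0, nu=2.0, c=0.8)
        assert np.all(np.diff(p) >= 0)

    def test_negative_feedback_rejected(self):
        with pytest.raises(ValueError):
            repeat_prob_vs_feedback(-1.0, eta=1.0, nu=1.0, c=0.5)


class TestFeedbackDecay:
    def test_zero_repeats_returns_initial(self):
        assert feedback_at_repeat(0, a0=2.5, tau=0.1, T=0.1) == pytest.approx(2.5)

    def test_unit_exponent(self):
        assert feedback_at_repeat(1, a0=1.0, tau=0.2, T=0.2) == pytest.approx(1.0 / np.e)

    def test_network_parameter_value(self):
        # a0 = 1.9, tau = 148 ms, T = 100 ms, n = 3
        assert feedback_at_repeat(3, a0=1.9, tau=0.148, T=0.1) == pytest.approx(0.2503, abs=2e-4)


class TestRepeatProbability:
    def test_markov_limit_constant(self):
        p = SigmoidalParams(a=5.0, b=1.0, c=0.7)
        vals = repeat_prob_at(np.arange(1, 50), p)
        assert np.allclose(vals, 1.0 - 0.7 / 6.0)

    def test_hand_value(self):
        p = SigmoidalParams(a=10.0, b=0.5, c=1.0)
        assert repeat_prob_at(1, p) == pytest.approx(1.0 - 1.0 / 6.0)

    def test_geometric_adaptation_limit(self):
        # c=1 and a b^n << 1: p_r(n) ~ a b^n within 1%
        p = SigmoidalParams(a=0.01, b=0.5, c=1.0)
        n = np.arange(1, 8)
        assert np.allclose(repeat_prob_at(n, p), 0.01 * 0.5**n, rtol=0.01)

    def test_monotone_nonincreasing_with_limit(self):
        p = SigmoidalParams(a=50.0, b=0.6, c=0.9)
        vals = repeat_prob_at(np.arange(1, 200), p)
        assert np.all(np.diff(vals) <= 1e-15)
        assert vals[-1] == pytest.approx(1.0 - p.c, abs=1e-9)


class TestRepeatDistribution:
    def test_no_feedback_is_geometric(self):
        d = repeat_distribution(SigmoidalParams(a=0.0, b=0.5, c=0.4), 30)
        n = np.arange(1, 31)
        assert np.allclose(d.probs, 0.4 * 0.6 ** (n - 1), rtol=1e-12)

    def test_worked_example_peak_and_mass(self, worked_params):
        d = repeat_distribution(worked_params, 50)
        assert peak_repeat_number(d) == 6
        assert d.probs[5] == pytest.approx(0.21795, abs=1e-4)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(0.0, 1e6),
        b=st.floats(0.01, 1.0),
        c=st.floats(0.05, 1.0),
    )
    def test_probability_conservation(self, a, b, c):
        d = repeat_distribution(SigmoidalParams(a=a, b=b, c=c), 200)
        assert d.probs.sum() + d.tail_mass == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_oracle_agreement(self, worked_params):
        # independent sequential-sampling oracle at modest n
        n_bouts = 200_000
        draws = simulate_bouts_mc(worked_params, n_bouts, seed=9)
        d = repeat_distribution(worked_params, 60)
        emp = np.bincount(draws, minlength=61)[1:61] / n_bouts
        se = np.sqrt(d.probs * (1 - d.probs) / n_bouts)
        assert np.all(np.abs(emp - d.probs) <= 3 * se + 1e-9)


class TestSimulateBouts:
    def test_deterministic_under_seed(self):
        h1 = simulate_bouts(0.5, 0.006, n_bouts=500, seed=5)
        h2 = simulate_bouts(0.5, 0.006, n_bouts=500, seed=5)
        assert h1.counts == h2.counts

    def test_no_feedback_matches_geometric(self):
        # a0 = 0 reduces to a Markov chain with exit probability c
        from scipy.stats import chisquare

        c = 0.633  # packaged default exit bias
        hist = simulate_bouts(0.0, 0.006, n_bouts=10_000, seed=3)
        n_max = hist.n_max
        expected = c * (1 - c) ** (np.arange(1, n_max + 1) - 1)
        expected = np.append(expected, 1.0 - expected.sum())  # tail bin
        obs = np.append(hist.probabilities(n_max) * hist.total, 0.0)
        # merge sparse tail bins for a valid chi-square
        keep = expected * hist.total >= 5
        obs_m = np.append(obs[keep], obs[~keep].sum())
        exp_m = np.append(expected[keep], expected[~keep].sum()) * hist.total
        stat, p = chisquare(obs_m, exp_m * obs_m.sum() / exp_m.sum())
        assert p > 0.01

    def test_small_alpha_clamped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="repeatloop.repeat_model"):
            simulate_bouts(0.5, 1e-6, n_bouts=10, seed=0)
        assert any("clamped" in r.message for r in caplog.records)


class TestFitSigmoidal:
    def test_parameter_recovery_on_large_sample(self, worked_params):
        draws = simulate_bouts_mc(worked_params, 100_000, seed=21)
        hist = RepeatHistogram.from_bouts(draws)
        fit = fit_sigmoidal(hist, seed=2)
        n = np.arange(1, hist.n_max + 1)
        obs = hist.probabilities()
        mask = obs > 0.01
        true_pr = repeat_prob_at(n, worked_params)
        fit_pr = repeat_prob_at(n, fit.params)
        assert np.max(np.abs(true_pr - fit_pr)[mask]) < 0.02

    def test_geometric_data_fits_constant_repeat_probability(self):
        rng = np.random.default_rng(4)
        draws = rng.geometric(0.4, size=50_000)
        fit = fit_sigmoidal(RepeatHistogram.from_bouts(draws), seed=1)
        pr = repeat_prob_at(np.arange(1, 10), fit.params)
        assert np.all(np.abs(pr - 0.6) < 0.02)

    def test_deterministic_under_seed(self, worked_params):
        draws = simulate_bouts_mc(worked_params, 5000, seed=8)
        hist = RepeatHistogram.from_bouts(draws)
        f1 = fit_sigmoidal(hist, seed=7)
        f2 = fit_sigmoidal(hist, seed=7)
        assert f1.params == f2.params
        assert f1.sse == f2.sse

    def test_single_support_point_rejected(self):
        with pytest.raises(ValueError, match="single support point"):
            fit_sigmoidal(RepeatHistogram(counts={3: 100}))


class TestStateChains:
    def test_single_nonrepeating_state(self):
        d = state_chain_distribution(StateChainModel((ChainState(False),)), 10)
        assert d.probs[0] == pytest.approx(1.0)
        assert d.probs[1:].sum() == 0.0

    def test_single_markov_state_is_geometric(self):
        d = state_chain_distribution(
            StateChainModel((ChainState(True, 0.7, 1.0),)), 50
        )
        n = np.arange(1, 51)
        assert np.allclose(d.probs, 0.3 * 0.7 ** (n - 1), rtol=1e-12)

    def test_two_state_matches_monte_carlo(self):
        model = StateChainModel(
            (ChainState(True, 0.8, 0.85), ChainState(True, 0.6, 0.9))
        )
        rng = np.random.default_rng(12)
        n_mc = 200_000
        totals = np.zeros(n_mc, dtype=int)
        for state in model.states:
            k = np.ones(n_mc, dtype=int)
            alive = np.full(n_mc, True)
            step = 0
            while alive.any():
                p_stay = state.p_init * state.adapt_factor**step
                stay = rng.random(n_mc) < p_stay
                k += stay & alive
                alive &= stay
                step += 1
            totals += k
        d = state_chain_distribution(model, 60)
        emp = np.bincount(totals, minlength=61)[1:61] / n_mc
        se = np.sqrt(d.probs * (1 - d.probs) / n_mc)
        assert np.all(np.abs(emp - d.probs) <= 3 * se + 1e-9)

    def test_prefix_states_force_minimum_repeats(self):
        draws = np.random.default_rng(3).geometric(0.5, size=2000) + 2
        hist = RepeatHistogram.from_bouts(draws)
        fit = fit_state_chain(hist, "prefix_then_repeating", n_prefix=2, seed=1)
        d = state_chain_distribution(fit.params, 10)
        assert np.all(d.probs[:2] == 0.0)

    def test_single_state_nests_within_markov_data(self):
        rng = np.random.default_rng(5)
        hist = RepeatHistogram.from_bouts(rng.geometric(0.5, size=20_000))
        f1 = fit_state_chain(hist, "single", seed=3)
        f2 = fit_state_chain(hist, "two_repeating", seed=3)
        assert f1.sse <= f2.sse + 1e-6

    def test_sigmoidal_beats_geometric_single_state_on_peaked_data(self, worked_params):
        draws = simulate_bouts_mc(worked_params, 50_000, seed=30)
        hist = RepeatHistogram.from_bouts(draws)
        sig = fit_sigmoidal(hist, seed=3)
        geo = fit_state_chain(hist, "single", seed=3)
        assert sig.sse < geo.sse


class TestDistributionDistance:
    def test_identical_is_zero(self):
        assert distribution_distance([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_support_is_one(self):
        assert distribution_distance([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_hand_value(self):
        assert distribution_distance([0.5, 0.5], [0.9, 0.1]) == pytest.approx(4.0 / 9.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10))
    def test_symmetric_and_bounded(self, weights):
        p = np.asarray(weights)
        if p.sum() == 0:
            p[0] = 1.0
        p = p / p.sum()
        q = np.roll(p, 1)
        d1 = distribution_distance(p, q)
        assert d1 == distribution_distance(q, p)
        assert 0.0 <= d1 <= 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            distribution_distance([0.0, 0.0], [0.0, 0.0])


class TestBenchmarkError:
    def test_degenerate_data_has_zero_benchmark(self):
        hist = RepeatHistogram.from_bouts(np.full(100, 3))
        assert benchmark_error(hist, seed=0) == 0.0

    def test_deterministic_under_seed(self, worked_params):
        hist = RepeatHistogram.from_bouts(simulate_bouts_mc(worked_params, 400, seed=2))
        assert benchmark_error(hist, seed=5) == benchmark_error(hist, seed=5)

    def test_more_data_shrinks_benchmark(self, worked_params):
        small = [
            benchmark_error(
                RepeatHistogram.from_bouts(simulate_bouts_mc(worked_params, 200, seed=s)),
                n_resamples=200, seed=s,
            )
            for s in range(6)
        ]
        large = [
            benchmark_error(
                RepeatHistogram.from_bouts(simulate_bouts_mc(worked_params, 2000, seed=s)),
                n_resamples=200, seed=s,
            )
            for s in range(6)
        ]
        assert np.mean(large) < np.mean(small)

    def test_histogram_without_bouts_rejected(self):
        with pytest.raises(ValueError, match="bout-level"):
            benchmark_error(RepeatHistogram(counts={1: 5, 2: 3}))


class TestPeakRepeatNumber:
    def test_geometric_peaks_at_one(self):
        d = repeat_distribution(SigmoidalParams(a=0.0, b=1.0, c=0.3), 40)
        assert peak_repeat_number(d) == 1

    def test_tie_breaks_to_smallest(self):
        assert peak_repeat_number(RepeatHistogram(counts={1: 5, 2: 5})) == 1


class TestPhaseDiagram:
    def test_markov_column_and_monotonicity(self):
        a0 = np.array([0.0, 0.3, 0.6, 1.0])
        alpha = np.array([0.002, 0.006, 0.015])
        pd = phase_diagram(a0, alpha, n_bouts=4000, seed=2)
        assert np.all(pd.peak[0, :] == 1)  # no feedback: Markov everywhere
        # non-decreasing in a0 (columns), non-increasing in alpha (rows),
        # allowing one unit of Monte-Carlo jitter
        assert np.all(np.diff(pd.peak, axis=0) >= -1)
        assert np.all(np.diff(pd.peak, axis=1) <= 1)

    def test_alpha_below_floor_rejected(self):
        with pytest.raises(ValueError):
            phase_diagram([0.5], [1e-5], n_bouts=10, seed=0)
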