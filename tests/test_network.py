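"""Branched-chain network: construction, dynamics, winner-take-all, feedback."""

import numpy as np
import pytest

from repeatloop.depression import DepressionParams, slow_scale_summary
from repeatloop.network import (
    NetworkConfig,
    build_network,
    collect_transitions,
    mean_feedback_strength_trace,
    paper_config,
    reduced_config,
    transition_analysis,
    wilson_interval,
)
from repeatloop.repeat_model import peak_repeat_number


class TestBuildNetwork:
    def test_full_scale_neuron_count(self):
        cfg = paper_config()
        assert cfg.n_excitatory == 3600

    def test_same_seed_gives_identical_weights(self):
        cfg = reduced_config()
        n1 = build_network(cfg, seed=3)
        n2 = build_network(cfg, seed=3)
        assert np.array_equal(n1.w_ee, n2.w_ee)
        assert np.array_equal(n1.w_ie, n2.w_ie)
        assert np.array_equal(n1.fb_g0, n2.fb_g0)

    def test_feedback_matrix_sparsity(self):
        net = build_network(reduced_config(), seed=1)
        # only the b -> b pathway is nonzero by default: every feedback
        # synapse originates from chain b and lands on chain b
        assert np.all(net.fb_src == 1)
        assert np.all(net.chain_of[net.fb_tgt] == 1)

    def test_chain_connectivity_structure(self):
        cfg = reduced_config()
        net = build_network(cfg, seed=2)
        a_last = net.neurons_of("a", cfg.pools_per_chain - 1)
        b_first = net.neurons_of("b", 0)
        c_first = net.neurons_of("c", 0)
        a_first = net.neurons_of("a", 0)
        assert np.all(net.w_ee[np.ix_(a_last, b_first)] > 0)  # a -> b branch
        assert np.all(net.w_ee[np.ix_(a_last, c_first)] == 0)  # no a -> c
        assert np.all(net.w_ee[np.ix_(a_last, a_first)] == 0)  # no a self-loop
        b_last = net.neurons_of("b", cfg.pools_per_chain - 1)
        assert np.all(net.w_ee[np.ix_(b_last, b_first)] > 0)  # self-connection
        assert np.all(net.w_ee[np.ix_(b_last, c_first)] > 0)  # exit branch

    def test_unknown_chain_in_topology_rejected(self):
        with pytest.raises(ValueError, match="unknown chain"):
            NetworkConfig(topology={"a": ("z",)})

    def test_config_round_trip(self, tmp_path):
        cfg = reduced_config()
        cfg.save(tmp_path / "cfg.json")
        loaded = NetworkConfig.load(tmp_path / "cfg.json")
        assert loaded == cfg
        cfg.save(tmp_path / "cfg.yaml")
        assert NetworkConfig.load(tmp_path / "cfg.yaml") == cfg


class TestWilsonInterval:
    def test_contains_proportion(self):
        lo, hi = wilson_interval(8, 10)
        assert lo < 0.8 < hi

    def test_extremes(self):
        assert wilson_interval(0, 20)[0] == 0.0
        assert wilson_interval(20, 20)[1] == 1.0

    def test_shrinks_with_n(self):
        lo1, hi1 = wilson_interval(5, 10)
        lo2, hi2 = wilson_interval(50, 100)
        assert hi2 - lo2 < hi1 - lo1


class TestRepeatDichotomy:
    def test_no_feedback_histogram_peaks_at_one(self, network_conditions):
        _, hist = network_conditions["off"]
        assert peak_repeat_number(hist) == 1

    def test_depressing_feedback_gives_peaked_distribution(self, network_conditions):
        _, hist = network_conditions["on"]
        assert peak_repeat_number(hist) > 1

    def test_nondepressing_feedback_perseverates(self, network_conditions):
        trials, _ = network_conditions["nodep"]
        frac_capped = np.mean([t.hit_cap for t in trials])
        assert frac_capped >= 0.95

    def test_winner_take_all_sibling_overlap_bounded(self, network_conditions):
        # sibling chains (b vs c) may briefly co-propagate while the
        # competition resolves; the overlap of their activation intervals
        # must stay within the ~20 ms competition window in the vast
        # majority of trials and never exceed one full traversal
        syllable_ms = 8 * 4.7  # pools x pool-to-pool latency
        for key in ("off", "on"):
            trials, _ = network_conditions[key]
            overlaps = []
            for t in trials:
                seq = t.end_chains
                b_ends = t.end_times_ms[seq == t.repeat_chain]
                if not t.terminated or b_ends.size == 0:
                    continue
                gap = t.end_times_ms[-1] - b_ends[-1]
                overlaps.append(max(0.0, syllable_ms - gap))
            overlaps = np.asarray(overlaps)
            assert np.all(overlaps <= syllable_ms + 1e-9)
            assert np.mean(overlaps <= 20.0) >= 0.8, f"contested transitions in {key}"


class TestFeedbackDynamics:
    def test_feedback_strength_declines_across_transitions(self, network_conditions):
        trials, _ = network_conditions["on"]
        declining = 0
        used = 0
        for t in trials:
            fb = t.transition_fb_strength
            if fb.size >= 3:
                used += 1
                declining += bool(fb[0] > fb[-1])
        assert used >= 20
        assert declining / used > 0.95

    def test_trace_decay_matches_depression_closed_form(self, network_conditions):
        # mean feedback-synapse strength decays with the time constant
        # predicted by the depression model at the feedback spike rate
        trials, _ = network_conditions["on"]
        cfg_dep = DepressionParams(alpha=0.006, tau_R=3.25)
        tau_pred_ms = slow_scale_summary(cfg_dep, 1340.0).tau_decay * 1000.0
        taus = []
        for t in trials:
            _, _, tau = mean_feedback_strength_trace(t)
            if tau is not None:
                taus.append(tau)
        assert len(taus) >= 20
        assert abs(np.median(taus) - tau_pred_ms) / tau_pred_ms < 0.3

    def test_repeat_probability_declines_with_repeat_index(self, network_conditions):
        trials, _ = network_conditions["on"]
        ta = transition_analysis(trials, min_transitions=50)
        probs = ta.repeat_prob_by_index.set_index("repeat_index")["p"]
        early = probs.loc[probs.index <= 3].mean()
        late = probs.loc[probs.index >= probs.index.max() - 2].mean()
        assert early > late

    def test_sigmoid_fit_is_increasing_in_feedback(self, network_conditions):
        trials, _ = network_conditions["on"]
        ta = transition_analysis(trials, min_transitions=50)
        assert not ta.degenerate
        A = np.linspace(0.01, 0.6, 50)
        p = 1.0 - ta.c / (1.0 + ta.eta * A**ta.nu)
        assert np.all(np.diff(p) >= 0)

    def test_too_few_transitions_refused(self, network_conditions):
        trials, _ = network_conditions["on"]
        with pytest.raises(ValueError, match="transitions"):
            transition_analysis(trials[:1], min_transitions=1000)

    def test_transition_table_contents(self, network_conditions):
        trials, _ = network_conditions["on"]
        df = collect_transitions(trials)
        assert {"trial", "repeat_index", "fb_strength", "repeated"} <= set(df.columns)
        assert df["fb_strength"].notna().all()
        assert df["repeat_index"].min() == 1
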