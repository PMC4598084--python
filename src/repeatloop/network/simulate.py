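"""Trial execution and online/offline syllable-onset detection."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..repeat_model import RepeatHistogram
from .build import Network, build_network
from .config import NetworkConfig, OnsetDetector
from .engine import build_rate_tables, run_trial_kernel

__all__ = [
    "SpikeRaster",
    "TrialResult",
    "run_trial",
    "run_repeat_experiment",
    "detect_syllable_onsets",
]

_RATE_TAB = build_rate_tables()


@dataclass
class SpikeRaster:
    """Spike times (ms) and neuron ids; excitatory ids precede inhibitory."""

    times_ms: np.ndarray
    neuron_ids: np.ndarray
    n_excitatory: int
    n_inhibitory: int

    def __post_init__(self) -> None:
        if self.times_ms.shape != self.neuron_ids.shape:
            raise ValueError("times and ids must have equal length")


@dataclass
class TrialResult:
    """Outcome of one network trial.

    ``syllable_sequence`` is the chain index of each completed chain
    traversal (in order); ``repeat_count`` counts the longest initial run of
    the repeating chain within it.  ``transition_fb_strength`` records the
    mean feedback-synapse strength onto the repeating chain at each of its
    chain-end (branch-transition) times.  ``terminated`` is True when the
    activity reached the end of the terminal chain; False means the trial
    hit the duration cap.
    """

    onset_times_ms: np.ndarray
    onset_chains: np.ndarray
    end_times_ms: np.ndarray
    end_chains: np.ndarray
    end_fb_strength: np.ndarray
    trace_times_ms: np.ndarray
    trace_fb_strength: np.ndarray
    terminated: bool
    #: True when the trial ran to the duration cap still active (as opposed
    #: to reaching the terminal chain or activity going extinct)
    hit_cap: bool
    duration_ms: float
    repeat_chain: int
    raster: SpikeRaster | None = None
    #: calibration traces: soma/dendrite voltage of excitatory neuron 0 and
    #: voltage of inhibitory neuron 0, sampled with the feedback trace
    trace_vs: np.ndarray | None = None
    trace_vi: np.ndarray | None = None
    trace_vd: np.ndarray | None = None

    @property
    def syllable_sequence(self) -> np.ndarray:
        return self.end_chains

    @property
    def repeat_count(self) -> int:
        """Number of consecutive renditions of the repeating chain."""
        seq = self.end_chains
        count = 0
        started = False
        for c in seq:
            if c == self.repeat_chain:
                count += 1
                started = True
            elif started:
                break
        return count

    @property
    def transition_fb_strength(self) -> np.ndarray:
        return self.end_fb_strength[self.end_chains == self.repeat_chain]


def _repeating_chain_index(config: NetworkConfig) -> int:
    for name, succ in config.topology.items():
        if name in succ:
            return config.chains.index(name)
    return -1


def _terminal_chain_index(config: NetworkConfig) -> int:
    for ci, name in enumerate(config.chains):
        if not config.topology.get(name, ()):
            return ci
    return -1


def run_trial(
    network: Network,
    seed: int = 0,
    max_duration_ms: float | None = None,
    keep_raster: bool = True,
    trace_dt_ms: float = 1.0,
    trace_neuron: int = 0,
) -> TrialResult:
    """Integrate one trial of the branched-chain network.

    Activity is initiated by a suprathreshold current step to the first pool
    of the first chain; the trial ends when the last pool of the terminal
    chain fires (terminated=True) or at the duration cap.
    """
    cfg = network.config
    dt = cfg.dt_ms
    max_ms = cfg.max_duration_ms if max_duration_ms is None else max_duration_ms
    n_steps = int(round(max_ms / dt))
    det = cfg.detector
    window_steps = max(1, int(round(det.window_ms / dt)))
    n_chains = len(cfg.chains)

    order = np.argsort(network.fb_src, kind="stable")
    fb_src = network.fb_src[order]
    fb_tgt = network.fb_tgt[order]
    fb_g0 = network.fb_g0[order]
    fb_src_ptr = np.searchsorted(fb_src, np.arange(n_chains + 1)).astype(np.int64)
    fb_tgt_chain = network.chain_of[fb_tgt] if fb_tgt.size else np.empty(0, dtype=np.int64)

    init_mask = np.zeros(network.n_excitatory, dtype=np.bool_)
    init_mask[(network.chain_of == 0) & (network.pool_of == 0)] = True

    max_spikes = 4_000_000
    spikes_t = np.empty(max_spikes)
    spikes_id = np.empty(max_spikes, dtype=np.int64)
    max_events = 4000
    onset_t = np.empty(max_events)
    onset_chain = np.empty(max_events, dtype=np.int64)
    end_t = np.empty(max_events)
    end_chain = np.empty(max_events, dtype=np.int64)
    end_fbmean = np.empty(max_events)
    trace_every = max(1, int(round(trace_dt_ms / dt)))
    n_trace_cap = n_steps // trace_every + 2
    trace_t = np.empty(n_trace_cap)
    trace_g = np.empty(n_trace_cap)
    trace_vs = np.empty(n_trace_cap)
    trace_vi = np.empty(n_trace_cap)
    trace_vd = np.empty(n_trace_cap)

    terminal = _terminal_chain_index(cfg)
    repeat_chain = _repeating_chain_index(cfg)

    n_spk, n_on, n_end, n_tr, status, stop_step = run_trial_kernel(
        _RATE_TAB,
        dt,
        n_steps,
        network.w_ee,
        network.w_ei,
        network.w_ie,
        network.chain_of,
        network.pool_of,
        n_chains,
        cfg.pools_per_chain,
        fb_src_ptr,
        fb_tgt,
        fb_tgt_chain,
        fb_g0,
        cfg.depression.alpha,
        cfg.depression.tau_R * 1000.0,
        cfg.f_fdbk * dt / 1000.0,
        det.feedback_delay_ms,
        cfg.feedback_duration_ms,
        cfg.noise_rate * dt / 1000.0,
        cfg.g_noise_soma,
        cfg.g_noise_dend,
        cfg.g_noise_inh,
        cfg.drive_rate * dt / 1000.0,
        cfg.g_drive_max,
        math.exp(-dt / cfg.tau_syn_e_ms),
        math.exp(-dt / cfg.tau_syn_i_ms),
        max(1, int(round(cfg.syn_delay_ms / dt))),
        det.monitored_pool_index,
        cfg.pools_per_chain - 1,
        window_steps,
        det.spike_threshold(cfg.pool_size),
        max(1, int(round(det.refractory_ms / dt))),
        init_mask,
        cfg.init_current,
        int(round(cfg.init_duration_ms / dt)),
        cfg.silence_timeout_ms,
        terminal,
        repeat_chain,
        trace_every,
        int(trace_neuron),
        int(seed) & 0x7FFFFFFF,
        spikes_t,
        spikes_id,
        onset_t,
        onset_chain,
        end_t,
        end_chain,
        end_fbmean,
        trace_t,
        trace_g,
        trace_vs,
        trace_vi,
        trace_vd,
    )
    if status == 2:
        raise RuntimeError(
            f"numerical blow-up (voltage out of bounds) at t = {stop_step * dt:.3f} ms"
        )
    raster = None
    if keep_raster:
        raster = SpikeRaster(
            times_ms=spikes_t[:n_spk].copy(),
            neuron_ids=spikes_id[:n_spk].copy(),
            n_excitatory=network.n_excitatory,
            n_inhibitory=network.n_inhibitory,
        )
    terminated = bool(n_end and np.any(end_chain[:n_end] == terminal))
    hit_cap = stop_step >= n_steps
    return TrialResult(
        onset_times_ms=onset_t[:n_on].copy(),
        onset_chains=onset_chain[:n_on].copy(),
        end_times_ms=end_t[:n_end].copy(),
        end_chains=end_chain[:n_end].copy(),
        end_fb_strength=end_fbmean[:n_end].copy(),
        trace_times_ms=trace_t[:n_tr].copy(),
        trace_fb_strength=trace_g[:n_tr].copy(),
        terminated=terminated,
        hit_cap=hit_cap,
        duration_ms=min(stop_step * dt, max_ms),
        repeat_chain=repeat_chain,
        raster=raster,
        trace_vs=trace_vs[:n_tr].copy(),
        trace_vi=trace_vi[:n_tr].copy(),
        trace_vd=trace_vd[:n_tr].copy(),
    )


def run_repeat_experiment(
    config: NetworkConfig,
    n_trials: int,
    seed: int = 0,
    keep_rasters: bool = False,
    rebuild_each_trial: bool = False,
) -> tuple[list[TrialResult], RepeatHistogram]:
    """Run many trials and collect the repeat-number histogram.

    One network instance is built from the seed and shared across trials
    (each trial gets an independent noise stream) unless
    ``rebuild_each_trial`` is set.
    """
    rng = np.random.default_rng(seed)
    net = build_network(config, seed=int(rng.integers(2**31 - 1)))
    trials = []
    for k in range(n_trials):
        if rebuild_each_trial and k > 0:
            net = build_network(config, seed=int(rng.integers(2**31 - 1)))
        res = run_trial(net, seed=int(rng.integers(2**31 - 1)), keep_raster=keep_rasters)
        trials.append(res)
    counts = [t.repeat_count for t in trials if t.repeat_count >= 1]
    if not counts:
        raise RuntimeError("no trial entered the repeating chain")
    return trials, RepeatHistogram.from_bouts(counts)


def detect_syllable_onsets(
    times_ms: np.ndarray,
    neuron_ids: np.ndarray,
    pool_members: np.ndarray,
    detector: OnsetDetector,
    pool_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Offline syllable-onset detection on a spike raster.

    ``pool_members`` lists the neuron ids of the monitored pool.  An onset is
    declared when the trailing ``window_ms`` spike count of that pool reaches
    ``ceil(threshold_rate * pool_size * window)``; re-triggering is
    suppressed for ``refractory_ms``.  Returns onset times and the feedback
    activation start times (onset + feedback delay).
    """
    times_ms = np.asarray(times_ms, dtype=float)
    neuron_ids = np.asarray(neuron_ids)
    pool_members = np.asarray(pool_members)
    if pool_size is None:
        pool_size = pool_members.size
    thresh = detector.spike_threshold(pool_size)
    mask = np.isin(neuron_ids, pool_members)
    t = np.sort(times_ms[mask])
    onsets = []
    lo = 0
    next_ok = -np.inf
    for hi in range(t.size):
        while t[hi] - t[lo] > detector.window_ms:
            lo += 1
        if hi - lo + 1 >= thresh and t[hi] >= next_ok:
            onsets.append(t[hi])
            next_ok = t[hi] + detector.refractory_ms
    onsets = np.asarray(onsets)
    return onsets, onsets + detector.feedback_delay_ms
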