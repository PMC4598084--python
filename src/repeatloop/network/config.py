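"""Configuration of the branched synfire-chain network.

The default full-scale configuration encodes the reference network constants
verbatim: pools of 60 HVC_RA neurons, 20 pools per chain, 1000 HVC_I
interneurons, the printed connection probabilities and conductance ceilings,
500 Hz noise, 1000 Hz excitatory drive, 1340 Hz feedback drive with
depression parameters alpha = 0.006 and tau_R = 3.25 s, and the
syllable-onset detector (4th pool, 5 ms window, 43 Hz/neuron threshold,
40 ms feedback delay).

A reduced configuration (pool_size 20, 8 pools per chain, 200 interneurons)
preserves the expected summed pool-to-pool input per neuron and retunes the
inhibitory loop for sharp winner-take-all competition at the smaller scale;
it is the routinely simulated tier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from ..depression import DepressionParams

__all__ = ["OnsetDetector", "NetworkConfig", "paper_config", "reduced_config"]


@dataclass(frozen=True)
class OnsetDetector:
    """Online syllable-onset detection on the activity of one pool per chain.

    An onset is declared when the spike count of the monitored pool over the
    trailing ``window_ms`` reaches ``ceil(threshold_rate * pool_size *
    window)``; feedback from that chain's syllable begins ``feedback_delay_ms``
    later.
    """

    monitored_pool_index: int = 3  # 4th pool
    window_ms: float = 5.0
    threshold_rate_hz: float = 43.0
    feedback_delay_ms: float = 40.0
    refractory_ms: float = 20.0  # suppress retriggering within one rendition

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.threshold_rate_hz <= 0:
            raise ValueError("window and threshold must be positive")

    def spike_threshold(self, pool_size: int) -> int:
        import math

        return math.ceil(self.threshold_rate_hz * (self.window_ms / 1000.0) * pool_size)


@dataclass(frozen=True)
class NetworkConfig:
    """Full specification of a branched-chain network simulation."""

    # architecture
    pool_size: int = 60
    pools_per_chain: int = 20
    chains: tuple[str, ...] = ("a", "b", "c")
    #: successors of each chain (branch topology); chain-ends feed the listed
    #: chain-starts, including self-connections
    topology: dict = field(
        default_factory=lambda: {"a": ("b",), "b": ("b", "c"), "c": ()}
    )
    # chain excitation
    g_ee_max: float = 0.09  # mS/cm^2
    #: per-branch multipliers on the chain-end -> chain-start connection
    #: ceiling; the relative strengths at a branch point set the baseline
    #: (no-feedback) transition probabilities
    branch_strength: dict = field(default_factory=dict)
    # inhibitory loop
    n_inhibitory: int = 1000
    p_ei: float = 0.05
    g_ei_max: float = 0.5
    p_ie: float = 0.1
    g_ie_max: float = 0.7
    # background noise (Poisson, half excitatory / half inhibitory)
    noise_rate: float = 500.0  # Hz per compartment
    g_noise_soma: float = 0.045
    g_noise_dend: float = 0.035
    g_noise_inh: float = 0.45
    # external excitatory drive to every HVC_RA neuron
    drive_rate: float = 1000.0  # Hz
    g_drive_max: float = 0.05
    # auditory feedback
    feedback_matrix: dict = field(default_factory=lambda: {("b", "b"): 1.9})
    #: number of leading pools per chain that receive feedback synapses
    #: (None = every pool, as in the full-scale configuration)
    feedback_pools: int | None = None
    f_fdbk: float = 1340.0  # Hz on each feedback synapse while active
    depression: DepressionParams = field(
        default_factory=lambda: DepressionParams(alpha=0.006, tau_R=3.25, g0=1.0)
    )
    #: how long feedback from one heard rendition stays on (ms); the default
    #: approximates the chain traversal time of the configuration
    feedback_duration_ms: float = 100.0
    detector: OnsetDetector = field(default_factory=OnsetDetector)
    # integration
    dt_ms: float = 0.01
    max_duration_ms: float = 5000.0
    #: abandon a trial after this long with no spike anywhere (propagation
    #: extinct; the calibrated network does not reignite spontaneously)
    silence_timeout_ms: float = 150.0
    # synaptic kinetics (kick-and-decay time constants, ms)
    tau_syn_e_ms: float = 2.0
    tau_syn_i_ms: float = 3.0
    #: conduction + synaptic delay on recurrent connections (sets, together
    #: with the burst dynamics, the pool-to-pool propagation latency)
    syn_delay_ms: float = 3.5
    # trial initiation: suprathreshold dendritic current step to the first
    # pool of the first chain
    init_current: float = 30.0  # uA/cm^2
    init_duration_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1 or self.pools_per_chain < 1:
            raise ValueError("pool_size and pools_per_chain must be >= 1")
        for p in (self.p_ei, self.p_ie):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must lie in [0, 1]")
        for g in (
            self.g_ee_max, self.g_ei_max, self.g_ie_max, self.g_noise_soma,
            self.g_noise_dend, self.g_noise_inh, self.g_drive_max,
        ):
            if g < 0:
                raise ValueError("conductance ceilings must be >= 0")
        for name, succs in self.topology.items():
            if name not in self.chains:
                raise ValueError(f"topology references unknown chain {name!r}")
            for s in succs:
                if s not in self.chains:
                    raise ValueError(f"topology references unknown chain {s!r}")
        for (i, j), g in self.feedback_matrix.items():
            if i not in self.chains or j not in self.chains:
                raise ValueError(f"feedback matrix references unknown chain {(i, j)}")
            if g < 0:
                raise ValueError("feedback ceilings must be >= 0")

    @property
    def n_excitatory(self) -> int:
        return self.pool_size * self.pools_per_chain * len(self.chains)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["topology"] = {k: list(v) for k, v in self.topology.items()}
        d["feedback_matrix"] = {f"{i}->{j}": g for (i, j), g in self.feedback_matrix.items()}
        d["branch_strength"] = {f"{i}->{j}": m for (i, j), m in self.branch_strength.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "topology" in d:
            d["topology"] = {k: tuple(v) for k, v in d["topology"].items()}
        for mat in ("feedback_matrix", "branch_strength"):
            if mat in d:
                fm = {}
                for key, g in d[mat].items():
                    i, j = key.split("->")
                    fm[(i, j)] = g
                d[mat] = fm
        if "chains" in d:
            d["chains"] = tuple(d["chains"])
        if "depression" in d and isinstance(d["depression"], dict):
            d["depression"] = DepressionParams(**d["depression"])
        if "detector" in d and isinstance(d["detector"], dict):
            d["detector"] = OnsetDetector(**d["detector"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "NetworkConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(d)


def paper_config(**overrides) -> NetworkConfig:
    """The full-scale configuration with the reference constants."""
    return replace(NetworkConfig(), **overrides) if overrides else NetworkConfig()


def reduced_config(**overrides) -> NetworkConfig:
    """Reduced network for routine simulation and testing.

    Conductance ceilings are rescaled so the expected summed input per neuron
    matches the full-scale network:

    * pool-to-pool: pool_size * g_ee_max / 2 preserved,
    * E->I: p_ei * pool_size * g_ei_max / 2 preserved,
    * I->E: p_ie * n_inhibitory * g_ie_max / 2 preserved.
    """
    base = NetworkConfig()
    pool, pools, n_inh = 20, 8, 200
    cfg = NetworkConfig(
        pool_size=pool,
        pools_per_chain=pools,
        # preserve the expected summed pool-to-pool input per neuron
        g_ee_max=base.g_ee_max * base.pool_size / pool,
        branch_strength={("b", "b"): 1.5},
        n_inhibitory=n_inh,
        # the excitatory -> inhibitory synapses are deliberately kept below
        # saturation so the interneuron response grows superlinearly when two
        # chains are co-active: that is what lets the winner-take-all
        # competition discriminate one active chain from two
        p_ei=0.15,
        g_ei_max=0.1,
        p_ie=0.25,
        g_ie_max=0.25,
        feedback_matrix={("b", "b"): 1.0},
        dt_ms=0.02,
        max_duration_ms=2000.0,
        feedback_duration_ms=40.0,
        detector=OnsetDetector(feedback_delay_ms=15.0),
        init_current=60.0,
    )
    return replace(cfg, **overrides) if overrides else cfg
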