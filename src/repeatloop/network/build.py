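"""Network construction: weight matrices, membership maps, feedback synapses.

Excitatory neurons are ordered chain-by-chain, pool-by-pool.  Within a chain
every neuron of pool p connects to every neuron of pool p+1 with strength
drawn uniformly from (0, g_ee_max); the final pool of a chain connects to
the first pool of each successor chain in the branch topology the same way.
Excitatory-to-inhibitory and inhibitory-to-excitatory connections are
Bernoulli-sparse with uniformly drawn strengths.  Each ordered chain pair
(i, j) with a nonzero feedback ceiling G_ij contributes one depressing
feedback synapse per neuron of chain j, with base strength uniform on
(0, G_ij).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig

__all__ = ["Network", "build_network"]


@dataclass
class Network:
    """A built network instance ready for simulation."""

    config: NetworkConfig
    w_ee: np.ndarray  # (Ne, Ne) chain weights
    w_ei: np.ndarray  # (Ne, Ni)
    w_ie: np.ndarray  # (Ni, Ne)
    chain_of: np.ndarray  # (Ne,) chain index per excitatory neuron
    pool_of: np.ndarray  # (Ne,) pool index within the chain
    fb_src: np.ndarray  # (n_fb,) source chain index per feedback synapse
    fb_tgt: np.ndarray  # (n_fb,) target excitatory neuron
    fb_g0: np.ndarray  # (n_fb,) base strengths
    seed: int

    @property
    def n_excitatory(self) -> int:
        return self.w_ee.shape[0]

    @property
    def n_inhibitory(self) -> int:
        return self.w_ie.shape[0]

    def neurons_of(self, chain: str, pool: int | None = None) -> np.ndarray:
        """Indices of the excitatory neurons of a chain (optionally one pool)."""
        ci = self.config.chains.index(chain)
        mask = self.chain_of == ci
        if pool is not None:
            mask &= self.pool_of == pool
        return np.flatnonzero(mask)

    def id_map(self) -> dict[int, tuple[str, int] | str]:
        """Neuron id -> (chain, pool) for excitatory, 'inh' for inhibitory."""
        out: dict[int, tuple[str, int] | str] = {}
        for i in range(self.n_excitatory):
            out[i] = (self.config.chains[self.chain_of[i]], int(self.pool_of[i]))
        for i in range(self.n_inhibitory):
            out[self.n_excitatory + i] = "inh"
        return out


def build_network(config: NetworkConfig, seed: int | None = None) -> Network:
    """Draw all random connectivity for ``config`` (reproducible under seed)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_chains = len(config.chains)
    per_chain = config.pool_size * config.pools_per_chain
    ne = per_chain * n_chains
    ni = config.n_inhibitory

    chain_of = np.repeat(np.arange(n_chains), per_chain)
    pool_of = np.tile(
        np.repeat(np.arange(config.pools_per_chain), config.pool_size), n_chains
    )

    w_ee = np.zeros((ne, ne))
    for ci, name in enumerate(config.chains):
        base = ci * per_chain
        for p in range(config.pools_per_chain - 1):
            src = slice(base + p * config.pool_size, base + (p + 1) * config.pool_size)
            tgt = slice(
                base + (p + 1) * config.pool_size, base + (p + 2) * config.pool_size
            )
            w_ee[src, tgt] = rng.uniform(
                0.0, config.g_ee_max, size=(config.pool_size, config.pool_size)
            )
        # branch connections from the final pool
        last = slice(base + per_chain - config.pool_size, base + per_chain)
        for succ in config.topology.get(name, ()):
            sj = config.chains.index(succ)
            first = slice(sj * per_chain, sj * per_chain + config.pool_size)
            scale = config.branch_strength.get((name, succ), 1.0)
            w_ee[last, first] = rng.uniform(
                0.0, scale * config.g_ee_max, size=(config.pool_size, config.pool_size)
            )

    w_ei = np.where(
        rng.random((ne, ni)) < config.p_ei,
        rng.uniform(0.0, config.g_ei_max, size=(ne, ni)),
        0.0,
    )
    w_ie = np.where(
        rng.random((ni, ne)) < config.p_ie,
        rng.uniform(0.0, config.g_ie_max, size=(ni, ne)),
        0.0,
    )

    fb_src, fb_tgt, fb_g0 = [], [], []
    for (src_name, tgt_name), g_max in sorted(config.feedback_matrix.items()):
        if g_max <= 0.0:
            continue
        si = config.chains.index(src_name)
        tj = config.chains.index(tgt_name)
        tgt_mask = chain_of == tj
        if config.feedback_pools is not None:
            tgt_mask &= pool_of < config.feedback_pools
        targets = np.flatnonzero(tgt_mask)
        fb_src.append(np.full(targets.size, si))
        fb_tgt.append(targets)
        fb_g0.append(rng.uniform(0.0, g_max, size=targets.size))
    if fb_src:
        fb_src = np.concatenate(fb_src).astype(np.int64)
        fb_tgt = np.concatenate(fb_tgt).astype(np.int64)
        fb_g0 = np.concatenate(fb_g0)
    else:
        fb_src = np.empty(0, dtype=np.int64)
        fb_tgt = np.empty(0, dtype=np.int64)
        fb_g0 = np.empty(0)

    return Network(
        config=config,
        w_ee=w_ee,
        w_ei=w_ei,
        w_ie=w_ie,
        chain_of=chain_of.astype(np.int64),
        pool_of=pool_of.astype(np.int64),
        fb_src=fb_src,
        fb_tgt=fb_tgt,
        fb_g0=fb_g0,
        seed=seed,
    )
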