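"""Shared fixtures.

The spiking-network trials are expensive, so the three experimental
conditions (feedback off, depressing feedback, non-depressing feedback) are
simulated once per session and shared by every test that needs them.
"""

from __future__ import annotations

import numpy as np
import pytest

from repeatloop.depression import DepressionParams
from repeatloop.repeat_model import SigmoidalParams, repeat_prob_at


@pytest.fixture(scope="session")
def worked_params() -> SigmoidalParams:
    """The peaked worked example used throughout: a=100, b=0.5, c=0.95."""
    return SigmoidalParams(a=100.0, b=0.5, c=0.95)


def simulate_bouts_mc(params: SigmoidalParams, n_bouts: int, seed: int, n_cap: int = 500) -> np.ndarray:
    """Independent Monte-Carlo oracle: sequential uniform draws against p_r(k).

    Deliberately avoids the closed-form distribution so it can serve as an
    independent check of it.
    """
    rng = np.random.default_rng(seed)
    alive = np.full(n_bouts, True)
    out = np.zeros(n_bouts, dtype=int)
    for k in range(1, n_cap + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x = rng.random(idx.size)
        exits = x > repeat_prob_at(float(k), params)
        out[idx[exits]] = k
        alive[idx[exits]] = False
    out[out == 0] = n_cap
    return out


@pytest.fixture(scope="session")
def network_conditions():
    """Reduced-network repeat experiments for the three feedback conditions.

    Returns a dict mapping condition name to (trials, RepeatHistogram):
    ``off`` (no auditory feedback), ``on`` (depressing feedback at the
    reduced-tier default strength) and ``nodep`` (same feedback strength
    with depression disabled, capped at 900 ms).
    """
    from repeatloop.network import reduced_config, run_repeat_experiment

    runs = {}
    cfg_off = reduced_config(feedback_matrix={}, max_duration_ms=800.0)
    runs["off"] = run_repeat_experiment(cfg_off, 40, seed=11)
    cfg_on = reduced_config(max_duration_ms=1500.0)
    runs["on"] = run_repeat_experiment(cfg_on, 40, seed=13)
    cfg_nodep = reduced_config(
        max_duration_ms=900.0,
        depression=DepressionParams(alpha=0.0, tau_R=3.25, g0=1.0),
    )
    runs["nodep"] = run_repeat_experiment(cfg_nodep, 50, seed=17)
    return runs
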