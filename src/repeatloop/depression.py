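"""Use-dependent short-term synaptic depression.

A depressing synapse loses a constant fraction ``alpha`` of its strength each
time it transmits a spike (``g -> (1 - alpha) g``) and recovers between spikes
with first-order dynamics toward its base strength ``g0``:

    tau_R dg/dt = -(g - g0)

Driven by a regular spike train of frequency ``f`` the strength right before
spike ``n`` follows an affine spike-to-spike map with a closed-form geometric
solution, so the large-scale behaviour is an exponential decay to a steady
state.  This module provides

* event-exact simulation of arbitrary spike trains (analytic between spikes,
  no integrator error),
* the closed-form pre-spike strengths and the slow-scale summary (steady
  state, per-spike ratio, continuous decay time constant), and
* the constituent-synapse matching procedure, which finds the depression
  parameters of ``N`` lower-frequency constituent synapses whose combined
  slow-scale dynamics reproduce those of a single high-frequency model
  synapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DepressionParams",
    "PoissonDrive",
    "SlowScaleSummary",
    "ConstituentMatch",
    "simulate_depressing_synapse",
    "relative_strength_before_spike",
    "slow_scale_summary",
    "match_constituent",
]


@dataclass(frozen=True)
class DepressionParams:
    """Parameters of a depressing synapse.

    alpha : fraction of strength lost per transmitted spike (dimensionless)
    tau_R : recovery time constant toward base strength (seconds)
    g0    : base synaptic strength (mS/cm^2)
    """

    alpha: float
    tau_R: float
    g0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.tau_R <= 0.0:
            raise ValueError(f"tau_R must be positive, got {self.tau_R}")
        if self.g0 < 0.0:
            raise ValueError(f"g0 must be non-negative, got {self.g0}")


@dataclass(frozen=True)
class PoissonDrive:
    """A homogeneous Poisson spike train specification.

    rate : mean spike frequency (Hz); duration : seconds; seed : RNG seed.
    """

    rate: float
    duration: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0.0:
            raise ValueError(f"rate must be non-negative, got {self.rate}")
        if self.duration <= 0.0:
            raise ValueError(f"duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class SlowScaleSummary:
    """Slow-scale characterisation of a depressing synapse under regular drive.

    map_offset : offset of the affine spike-to-spike map (relative units)
    map_ratio  : per-spike geometric ratio r of the decay
    g_inf_rel  : steady-state strength relative to g0
    tau_decay  : time constant of the equivalent continuous exponential decay (s)
    degenerate : True when alpha == 0 (no depression; decay amplitude is zero
                 and tau_decay is reported but carries no decaying component)
    """

    map_offset: float
    map_ratio: float
    g_inf_rel: float
    tau_decay: float
    degenerate: bool = False


@dataclass(frozen=True)
class ConstituentMatch:
    """Result of matching N constituent synapses to one model synapse."""

    n_constituents: int
    alpha_prime: float
    tau_R_prime: float
    residual: float


def _check_times(times: np.ndarray, name: str) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if times.size and times.min() < 0.0:
        raise ValueError(f"{name} contains negative times")
    return times


def simulate_depressing_synapse(
    params: DepressionParams,
    spike_times,
    query_times,
) -> np.ndarray:
    """Event-exact strength of a depressing synapse at ``query_times``.

    Between spikes the recovery ODE is integrated analytically
    (``g(t) = g0 + (g_i - g0) exp(-(t - t_i)/tau_R)``); at each spike the
    strength is multiplied by ``1 - alpha``.  Query times falling exactly on a
    spike time report the post-spike (depressed) strength.
    """
    spikes = _check_times(spike_times, "spike_times")
    queries = _check_times(query_times, "query_times")
    if spikes.size > 1 and np.any(np.diff(spikes) <= 0.0):
        raise ValueError("spike_times must be strictly increasing")

    out = np.empty_like(queries)
    g_after = params.g0  # strength right after the most recent event
    t_last = 0.0
    order = np.argsort(queries, kind="stable")
    qi = 0
    events = list(spikes)
    ei = 0
    sorted_q = queries[order]

    def recover(g_from: float, dt: float) -> float:
        return params.g0 + (g_from - params.g0) * math.exp(-dt / params.tau_R)

    for qt in sorted_q:
        while ei < len(events) and events[ei] <= qt:
            t_sp = events[ei]
            g_before = recover(g_after, t_sp - t_last)
            g_after = (1.0 - params.alpha) * g_before
            t_last = t_sp
            ei += 1
        out[order[qi]] = recover(g_after, qt - t_last)
        qi += 1
    return out


def _map_coefficients(params: DepressionParams, f: float) -> tuple[float, float]:
    """Offset and ratio of the relative-strength spike-to-spike map."""
    e = math.exp(-1.0 / (params.tau_R * f))
    return 1.0 - e, (1.0 - params.alpha) * e


def relative_strength_before_spike(params: DepressionParams, f: float, n) -> np.ndarray | float:
    """Closed-form relative strength A_n just before spike ``n`` of a regular train.

    A_1 = 1 and A_n decreases geometrically toward map_offset / (1 - map_ratio).
    ``n`` may be a scalar or array of integers >= 1.
    """
    if f <= 0.0:
        raise ValueError("f must be positive")
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("spike index n must be >= 1")
    a, b = _map_coefficients(params, f)
    if b == 1.0:  # alpha == 0 and infinitely fast drive limit
        result = np.ones_like(n_arr, dtype=float)
    else:
        result = a / (1.0 - b) + (1.0 - a - b) / (1.0 - b) * b ** (n_arr - 1.0)
    return float(result) if np.isscalar(n) else result


def slow_scale_summary(params: DepressionParams, f: float) -> SlowScaleSummary:
    """Steady state and decay time constant of a depressing synapse at rate ``f``.

    g_inf_rel = (1 - e^(-1/(tau_R f))) / (1 - (1-alpha) e^(-1/(tau_R f)))
    map_ratio = (1-alpha) e^(-1/(tau_R f))
    tau_decay = tau_R / (1 - tau_R f log(1-alpha))

    With ``alpha == 0`` there is no depression: the steady state is 1, the
    decay amplitude is zero and the result is flagged degenerate instead of
    raising, because the Markov special case of the statistical model needs it.
    """
    if f <= 0.0:
        raise ValueError("f must be positive")
    a, b = _map_coefficients(params, f)
    if params.alpha == 0.0:
        return SlowScaleSummary(
            map_offset=a, map_ratio=b, g_inf_rel=1.0, tau_decay=params.tau_R,
            degenerate=True,
        )
    g_inf = a / (1.0 - b)
    tau = params.tau_R / (1.0 - params.tau_R * f * math.log(1.0 - params.alpha))
    return SlowScaleSummary(map_offset=a, map_ratio=b, g_inf_rel=g_inf, tau_decay=tau)


def _tau_decay(alpha: float, tau_R: float, f: float) -> float:
    return tau_R / (1.0 - tau_R * f * math.log(1.0 - alpha))


def _g_inf_rel(alpha: float, tau_R: float, f: float) -> float:
    e = math.exp(-1.0 / (tau_R * f))
    return (1.0 - e) / (1.0 - (1.0 - alpha) * e)


def match_constituent(
    params: DepressionParams,
    f: float,
    n_constituents: int,
    tol: float = 1e-10,
) -> ConstituentMatch:
    """Depression parameters of N constituent synapses matching a model synapse.

    The model synapse carries rate ``f``; each of the ``N`` constituents
    carries rate ``f/N``.  We solve for (alpha', tau_R') such that both the
    slow-scale decay constant and the steady-state relative strength of a
    constituent match those of the model synapse.

    Given alpha', the decay-constant equation is linear in tau_R':

        tau* = tau_R' / (1 - tau_R' (f/N) log(1 - alpha'))
        =>  tau_R' = tau* / (1 + tau* (f/N) log(1 - alpha'))

    which is only positive for alpha' below a critical value; the remaining
    one-dimensional root of the steady-state equation is bracketed and solved
    over that interval with Brent's method.
    """
    if n_constituents < 1:
        raise ValueError("n_constituents must be >= 1")
    if f <= 0.0:
        raise ValueError("f must be positive")
    if not 0.0 < params.alpha < 1.0:
        raise ValueError("match_constituent requires 0 < alpha < 1")

    if n_constituents == 1:
        return ConstituentMatch(1, params.alpha, params.tau_R, 0.0)

    target_tau = _tau_decay(params.alpha, params.tau_R, f)
    target_ginf = _g_inf_rel(params.alpha, params.tau_R, f)
    f_sub = f / n_constituents

    # tau_R' > 0 requires 1 + tau* f_sub log(1-alpha') > 0
    crit = 1.0 - math.exp(-1.0 / (target_tau * f_sub))

    def tau_r_prime(alpha_p: float) -> float:
        return target_tau / (1.0 + target_tau * f_sub * math.log(1.0 - alpha_p))

    def residual(alpha_p: float) -> float:
        return _g_inf_rel(alpha_p, tau_r_prime(alpha_p), f_sub) - target_ginf

    lo = 1e-6
    hi = min(crit * (1.0 - 1e-9), 1.0 - 1e-6)
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0.0:
        raise RuntimeError(
            "match_constituent: no sign change of the steady-state residual in "
            f"alpha' bracket ({lo:.2e}, {hi:.6f}); residuals ({r_lo:.3e}, {r_hi:.3e})"
        )
    alpha_p = brentq(residual, lo, hi, xtol=1e-14, rtol=1e-14)
    tau_p = tau_r_prime(alpha_p)
    res = max(
        abs(_g_inf_rel(alpha_p, tau_p, f_sub) - target_ginf),
        abs(_tau_decay(alpha_p, tau_p, f_sub) - target_tau) / target_tau,
    )
    if res > tol:
        raise RuntimeError(
            f"match_constituent: residual {res:.3e} above tolerance {tol:.1e}"
        )
    return ConstituentMatch(n_constituents, alpha_p, tau_p, res)
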