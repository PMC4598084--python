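"""Analysis of network trials: transition statistics and feedback decay.

Pooling branch transitions across trials relates the instantaneous feedback
strength to the probability of the repeating chain transitioning to itself,
which is fitted with the sigmoid p_r(A) = 1 - c / (1 + eta A^nu); per-repeat
probabilities carry Wilson-score confidence intervals with continuity
correction.  The mean feedback-synapse strength trace of a trial is fitted
with an exponential to extract the decay time constant during a repeat bout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .simulate import TrialResult

__all__ = [
    "TransitionAnalysis",
    "wilson_interval",
    "collect_transitions",
    "transition_analysis",
    "mean_feedback_strength_trace",
]


@dataclass
class TransitionAnalysis:
    """Pooled branch-transition statistics and the fitted sigmoid."""

    transitions: pd.DataFrame  # fb_strength, repeated, repeat_index, trial
    eta: float | None
    nu: float | None
    c: float | None
    repeat_prob_by_index: pd.DataFrame  # index, n, k, p, ci_low, ci_high
    degenerate: bool = False


def wilson_interval(k: int, n: int, z: float = 1.645) -> tuple[float, float]:
    """Wilson score interval with continuity correction (default 90%)."""
    if n == 0:
        return 0.0, 1.0
    p = k / n
    z2 = z * z
    denom = 2.0 * (n + z2)
    lo_num = 2.0 * n * p + z2 - 1.0 - z * math.sqrt(
        max(0.0, z2 - 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) + 1.0))
    )
    hi_num = 2.0 * n * p + z2 + 1.0 + z * math.sqrt(
        max(0.0, z2 + 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) - 1.0))
    )
    lo = 0.0 if p == 0.0 else max(0.0, lo_num / denom)
    hi = 1.0 if p == 1.0 else min(1.0, hi_num / denom)
    return lo, hi


def collect_transitions(trials: Iterable[TrialResult]) -> pd.DataFrame:
    """Per-transition (feedback strength, repeated flag) pairs, pooled.

    Each chain-end event of the repeating chain is a branch transition;
    it counts as repeated when the next completed traversal is again the
    repeating chain.  A final event with no successor (duration cap) has an
    unknown outcome and is dropped.
    """
    rows = []
    for ti, tr in enumerate(trials):
        rc = tr.repeat_chain
        seq = tr.end_chains
        idx_in_bout = 0
        for k, chain in enumerate(seq):
            if chain != rc:
                continue
            idx_in_bout += 1
            if k + 1 >= len(seq):
                if tr.terminated:
                    # reached terminal chain already; cannot happen for rc
                    continue
                continue  # outcome unknown (hit cap)
            rows.append(
                {
                    "trial": ti,
                    "repeat_index": idx_in_bout,
                    "fb_strength": tr.end_fb_strength[k],
                    "repeated": bool(seq[k + 1] == rc),
                }
            )
    return pd.DataFrame(rows, columns=["trial", "repeat_index", "fb_strength", "repeated"])


def _fit_sigmoid_curve(
    A: np.ndarray, p: np.ndarray, weights: np.ndarray, n_restarts: int = 20, seed: int = 0
) -> tuple[float, float, float]:
    rng = np.random.default_rng(seed)
    scale = max(A.max(), 1e-12)

    def residuals(theta):
        eta, nu, c = 10.0 ** theta[0], theta[1], theta[2]
        model = 1.0 - c / (1.0 + eta * (A / scale) ** nu)
        return np.sqrt(weights) * (model - p)

    best = None
    for _ in range(n_restarts):
        theta0 = np.array(
            [rng.uniform(-2, 3), rng.uniform(0.5, 8.0), rng.uniform(0.05, 0.95)]
        )
        try:
            sol = least_squares(
                residuals,
                theta0,
                bounds=([-8, 0.1, 1e-6], [8, 30.0, 1.0]),
                method="trf",
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("sigmoid fit failed")
    eta_scaled, nu, c = 10.0 ** best.x[0], float(best.x[1]), float(best.x[2])
    # undo the abscissa scaling: eta A^nu = eta_scaled (A/scale)^nu
    eta = eta_scaled / scale**nu
    return eta, nu, c


def transition_analysis(
    trials: Sequence[TrialResult],
    min_transitions: int = 50,
    n_bins: int = 8,
    seed: int = 0,
) -> TransitionAnalysis:
    """Repeat probability versus feedback strength across pooled transitions."""
    df = collect_transitions(trials)
    if len(df) < min_transitions:
        raise ValueError(
            f"only {len(df)} transitions available; need >= {min_transitions}"
        )

    by_index = []
    for idx, grp in df.groupby("repeat_index"):
        n = len(grp)
        k = int(grp["repeated"].sum())
        lo, hi = wilson_interval(k, n)
        by_index.append(
            {"repeat_index": idx, "n": n, "k": k, "p": k / n, "ci_low": lo, "ci_high": hi}
        )
    by_index = pd.DataFrame(by_index)

    A = df["fb_strength"].to_numpy()
    if np.ptp(A) < 1e-9 * max(1.0, abs(A).max()):
        return TransitionAnalysis(
            transitions=df, eta=None, nu=None, c=None,
            repeat_prob_by_index=by_index, degenerate=True,
        )
    # bin by feedback strength, fit the sigmoid to binned repeat fractions
    edges = np.quantile(A, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    which = np.clip(np.searchsorted(edges, A, side="right") - 1, 0, len(edges) - 2)
    centers, props, weights = [], [], []
    for b in range(len(edges) - 1):
        mask = which == b
        if mask.sum() == 0:
            continue
        centers.append(A[mask].mean())
        props.append(df["repeated"].to_numpy()[mask].mean())
        weights.append(mask.sum())
    eta, nu, c = _fit_sigmoid_curve(
        np.asarray(centers), np.asarray(props), np.asarray(weights, dtype=float),
        seed=seed,
    )
    return TransitionAnalysis(
        transitions=df, eta=eta, nu=nu, c=c, repeat_prob_by_index=by_index
    )


def mean_feedback_strength_trace(
    trial: TrialResult,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Mean feedback-synapse strength versus time plus its fitted decay constant.

    Fits g(t) = g_inf + (g_0 - g_inf) exp(-(t - t0)/tau) over the repeat bout
    (from the first decline of the trace to the last rendition of the
    repeating chain).  Returns (times_ms, trace, tau_ms); tau is None when
    the trace never declines (feedback never gated on).
    """
    t = trial.trace_times_ms
    g = trial.trace_fb_strength
    if t.size < 10 or np.all(np.isnan(g)):
        return t, g, None
    g0 = g[0]
    declined = np.flatnonzero(g < g0 * (1.0 - 1e-6))
    if declined.size == 0:
        return t, g, None
    start = declined[0]
    rc_events = trial.end_times_ms[trial.end_chains == trial.repeat_chain]
    t_end = rc_events[-1] if rc_events.size else t[-1]
    mask = (t >= t[start]) & (t <= t_end)
    if mask.sum() < 5:
        mask = t >= t[start]
    tt, gg = t[mask], g[mask]

    def model(x, g_inf, amp, tau):
        return g_inf + amp * np.exp(-(x - tt[0]) / tau)

    try:
        popt, _ = curve_fit(
            model,
            tt,
            gg,
            p0=[gg.min(), max(gg[0] - gg.min(), 1e-6), max(50.0, (tt[-1] - tt[0]) / 3.0)],
            bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 1e5]),
            maxfev=10000,
        )
    except Exception:
        return t, g, None
    return t, g, float(popt[2])
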