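"""Sigmoidal-adaptation statistical model of syllable repeat numbers.

A repeating syllable is modelled as a single state that transitions to itself
with a history-dependent probability.  The repeat probability after ``n``
completed renditions follows from a sigmoidal dependence on auditory-feedback
strength combined with exponential feedback decay:

    p_r(A) = 1 - c / (1 + eta * A**nu)        (sigmoid of feedback strength)
    A(n)   = a0 * exp(-n * T / tau)           (feedback decay across repeats)
    p_r(n) = 1 - c / (1 + a * b**n)           with a = eta * a0**nu,
                                                   b = exp(-nu * T / tau)

The repeat-number distribution is P(N) = (1 - p_r(N)) * prod_{n<N} p_r(n).
Special cases: b = 1 gives the Markov (geometric) model; c = 1 with
a*b << 1 gives geometric adaptation, where the repeat probability shrinks by
a constant factor per repeat.

The module provides the forward distribution, Monte-Carlo bout simulation,
constrained least-squares fitting with random restarts, multi-state serial
chain models with geometric adaptation, the split-half benchmark error, and
the feedback-strength x adaptation-strength phase diagram of peak repeat
numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .depression import DepressionParams, slow_scale_summary

logger = logging.getLogger(__name__)

__all__ = [
    "SigmoidalParams",
    "RepeatHistogram",
    "RepeatDistribution",
    "FitResult",
    "ChainState",
    "StateChainModel",
    "PhaseDiagram",
    "DEFAULT_STAT_CONSTANTS",
    "repeat_prob_vs_feedback",
    "feedback_at_repeat",
    "repeat_prob_at",
    "repeat_distribution",
    "feedback_decay_constant",
    "simulate_bouts",
    "fit_sigmoidal",
    "state_chain_distribution",
    "fit_state_chain",
    "distribution_distance",
    "benchmark_error",
    "peak_repeat_number",
    "phase_diagram",
]

#: Constants shared by the bout simulator and phase diagram: sigmoid shape
#: (eta, nu, c) from the packaged fit to this package's network transition
#: curve, feedback-synapse depression parameters (tau_R, f) and syllable
#: duration T (seconds).
DEFAULT_STAT_CONSTANTS: dict[str, float] = {
    "eta": 1.22e7,
    "nu": 7.1,
    "c": 0.633,
    "tau_R": 3.25,
    "f": 1340.0,
    "T": 0.1,
}

#: Adaptation strengths below this floor are clamped (the peak repeat number
#: diverges as the adaptation strength goes to zero).
ALPHA_FLOOR = 0.001


@dataclass(frozen=True)
class SigmoidalParams:
    """Parameters (a, b, c) of the sigmoidal adaptation repeat-probability law.

    ``a`` is the feedback-scale parameter, ``b`` the per-repeat decay factor
    and ``c`` the asymptotic exit bias (repeat probability tends to 1 - c).
    The optional mechanistic parents (eta, nu, a0, tau, T) record where a and
    b came from when constructed via :meth:`from_mechanistic`.
    """

    a: float
    b: float
    c: float
    eta: float | None = None
    nu: float | None = None
    a0: float | None = None
    tau: float | None = None
    T: float | None = None

    def __post_init__(self) -> None:
        if self.a < 0.0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if not 0.0 < self.b <= 1.0:
            raise ValueError(f"b must be in (0, 1], got {self.b}")
        if not 0.0 < self.c <= 1.0:
            raise ValueError(f"c must be in (0, 1], got {self.c}")

    @classmethod
    def from_mechanistic(
        cls, eta: float, nu: float, c: float, a0: float, tau: float, T: float
    ) -> "SigmoidalParams":
        """Build (a, b, c) from the sigmoid and feedback-decay parents."""
        if eta <= 0 or nu <= 0:
            raise ValueError("eta and nu must be positive")
        if tau <= 0 or T <= 0:
            raise ValueError("tau and T must be positive")
        if a0 < 0:
            raise ValueError("a0 must be non-negative")
        a = eta * a0**nu
        b = math.exp(-nu * T / tau)
        return cls(a=a, b=b, c=c, eta=eta, nu=nu, a0=a0, tau=tau, T=T)


@dataclass
class RepeatHistogram:
    """Observed repeat numbers: counts per repeat number plus bout-level data.

    ``bout_level_data`` keeps the individual repeat numbers (one per bout);
    it is required for the split-half benchmark error.
    """

    counts: dict[int, int]
    bout_level_data: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("histogram must contain at least one count")
        if any(n < 1 for n in self.counts):
            raise ValueError("repeat numbers must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("total count must be >= 1")
        if self.bout_level_data is not None:
            self.bout_level_data = np.asarray(self.bout_level_data, dtype=int)

    @classmethod
    def from_bouts(cls, repeat_numbers: Sequence[int]) -> "RepeatHistogram":
        arr = np.asarray(repeat_numbers, dtype=int)
        if arr.size == 0:
            raise ValueError("no bouts supplied")
        vals, cnt = np.unique(arr, return_counts=True)
        return cls(counts=dict(zip(vals.tolist(), cnt.tolist())), bout_level_data=arr)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_max(self) -> int:
        return max(self.counts)

    def probabilities(self, n_max: int | None = None) -> np.ndarray:
        """Normalized histogram P_o(N) for N = 1..n_max."""
        n_max = n_max or self.n_max
        p = np.zeros(n_max)
        tot = self.total
        for n, cnt in self.counts.items():
            if n <= n_max:
                p[n - 1] = cnt / tot
        return p


@dataclass(frozen=True)
class RepeatDistribution:
    """Model repeat-number probabilities P(N) for N = 1..n_max plus tail mass."""

    probs: np.ndarray
    tail_mass: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if np.any(self.probs < -1e-15) or np.any(self.probs > 1 + 1e-15):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.tail_mass < -1e-12:
            raise ValueError("tail mass must be non-negative")

    @property
    def n_max(self) -> int:
        return len(self.probs)


@dataclass
class FitResult:
    """Outcome of fitting a repeat-number model to an observed histogram."""

    params: "SigmoidalParams | StateChainModel"
    sse: float
    distance: float
    benchmark: float | None = None
    n_restarts: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")
        if not 0.0 <= self.distance <= 1.0 + 1e-12:
            raise ValueError("distance must lie in [0, 1]")


@dataclass(frozen=True)
class ChainState:
    """One state of a serial transition model with geometric adaptation.

    A repeating state stays in itself with probability
    ``p_init * adapt_factor**(k-1)`` at its k-th self-transition decision;
    every visit produces one syllable rendition.
    """

    repeats: bool
    p_init: float = 0.0
    adapt_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_init <= 1.0:
            raise ValueError("p_init must lie in [0, 1]")
        if not 0.0 < self.adapt_factor <= 1.0:
            raise ValueError("adapt_factor must lie in (0, 1]")


@dataclass(frozen=True)
class StateChainModel:
    """Serial chain of states all producing the same syllable."""

    states: tuple[ChainState, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("at least one state required")
        object.__setattr__(self, "states", tuple(self.states))


@dataclass
class PhaseDiagram:
    """Peak repeat number over an (a0, alpha) grid.

    ``peak[i, j]`` is the peak repeat number at a0_grid[i], alpha_grid[j].
    """

    a0_grid: np.ndarray
    alpha_grid: np.ndarray
    peak: np.ndarray
    n_bouts: int
    seed: int


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def repeat_prob_vs_feedback(A, eta: float, nu: float, c: float):
    """Repeat probability as a sigmoidal function of feedback strength A.

    p_r(A) = 1 - c / (1 + eta * A**nu); increases from 1 - c at A = 0
    toward 1 for large A.
    """
    if eta <= 0 or nu <= 0:
        raise ValueError("eta and nu must be positive")
    if not 0.0 < c <= 1.0:
        raise ValueError("c must lie in (0, 1]")
    A_arr = np.asarray(A, dtype=float)
    if np.any(A_arr < 0):
        raise ValueError("feedback strength A must be non-negative")
    out = 1.0 - c / (1.0 + eta * A_arr**nu)
    return float(out) if np.isscalar(A) else out


def feedback_at_repeat(n, a0: float, tau: float, T: float):
    """Feedback strength at the end of the n-th repeat: a0 * exp(-n T / tau)."""
    if a0 < 0:
        raise ValueError("a0 must be non-negative")
    if tau <= 0 or T <= 0:
        raise ValueError("tau and T must be positive")
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("repeat index n must be >= 0")
    out = a0 * np.exp(-n_arr * T / tau)
    return float(out) if np.isscalar(n) else out


def repeat_prob_at(n, params: SigmoidalParams):
    """Repeat probability after n completed renditions: 1 - c / (1 + a b**n)."""
    n_arr = np.asarray(n, dtype=float)
    out = 1.0 - params.c / (1.0 + params.a * params.b**n_arr)
    return float(out) if np.isscalar(n) else out


def repeat_distribution(params: SigmoidalParams, n_max: int) -> RepeatDistribution:
    """Exact repeat-number distribution up to n_max.

    P(N) = (1 - p_r(N)) * prod_{n=1}^{N-1} p_r(n); the remaining probability
    of repeating beyond n_max is reported as tail mass so the result sums to
    one exactly.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if params.c == 0.0 and params.b == 1.0:
        logger.warning(
            "c=0 with b=1: repeat probability never leaves 1 (perseveration); "
            "the distribution has no finite support"
        )
    n = np.arange(1, n_max + 1)
    pr = repeat_prob_at(n, params)
    survival = np.concatenate([[1.0], np.cumprod(pr[:-1])])
    probs = (1.0 - pr) * survival
    tail = float(survival[-1] * pr[-1])
    return RepeatDistribution(probs=probs, tail_mass=tail)


def feedback_decay_constant(alpha: float, tau_R: float, f: float) -> float:
    """Feedback decay time constant implied by synaptic depression at rate f."""
    return slow_scale_summary(
        DepressionParams(alpha=alpha, tau_R=tau_R, g0=1.0), f
    ).tau_decay


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _params_from_mechanism(
    a0: float, alpha: float, constants: Mapping[str, float]
) -> SigmoidalParams:
    cst = dict(DEFAULT_STAT_CONSTANTS)
    cst.update(constants)
    if alpha < ALPHA_FLOOR:
        logger.warning(
            "adaptation strength %.3g below floor; clamped to %.3g", alpha, ALPHA_FLOOR
        )
        alpha = ALPHA_FLOOR
    tau = feedback_decay_constant(alpha, cst["tau_R"], cst["f"])
    return SigmoidalParams.from_mechanistic(
        eta=cst["eta"], nu=cst["nu"], c=cst["c"], a0=a0, tau=tau, T=cst["T"]
    )


def simulate_bouts(
    a0: float,
    alpha: float,
    constants: Mapping[str, float] | None = None,
    n_bouts: int = 10_000,
    seed: int | np.random.Generator = 0,
    max_repeats: int = 100_000,
) -> RepeatHistogram:
    """Monte-Carlo repeat bouts under the sigmoidal adaptation model.

    The feedback decay constant tau is computed from the depression
    parameters (alpha, tau_R, f); each bout draws uniforms x_k against
    p_r(k) until the first exceedance, which ends the bout at k repeats.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    params = _params_from_mechanism(a0, alpha, constants or {})
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    alive = np.full(n_bouts, True)
    repeats = np.zeros(n_bouts, dtype=int)
    k = 1
    while alive.any():
        if k > max_repeats:
            repeats[alive] = k
            logger.warning("bout simulation truncated at %d repeats", max_repeats)
            break
        idx = np.flatnonzero(alive)
        x = rng.random(idx.size)
        exits = x > repeat_prob_at(float(k), params)
        repeats[idx[exits]] = k
        alive[idx[exits]] = False
        k += 1
    return RepeatHistogram.from_bouts(repeats)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_support(hist: RepeatHistogram) -> int:
    # support truncation: generous room beyond the largest observed repeat
    return hist.n_max * 3 + 20


def fit_sigmoidal(
    hist: RepeatHistogram,
    n_restarts: int = 20,
    seed: int = 0,
    with_benchmark: bool = False,
) -> FitResult:
    """Least-squares fit of the sigmoidal adaptation model to a histogram.

    Minimizes E = sum_N (P(N) - P_o(N))^2 over 0 < a < 1e8, 0 < b < 1,
    0 < c < 1 (a searched on a log scale), keeping the best of ``n_restarts``
    random initializations.
    """
    if len(hist.counts) < 2:
        raise ValueError(
            "histogram has a single support point; the sigmoidal model is not "
            "identifiable from it"
        )
    n_max = _fit_support(hist)
    target = hist.probabilities(n_max)
    rng = np.random.default_rng(seed)

    def model_probs(theta: np.ndarray) -> np.ndarray:
        a = 10.0 ** theta[0]
        params = SigmoidalParams(a=a, b=theta[1], c=theta[2])
        return repeat_distribution(params, n_max).probs

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model_probs(theta) - target

    lb = np.array([-8.0, 1e-6, 1e-6])
    ub = np.array([8.0, 1.0 - 1e-9, 1.0 - 1e-9])
    best = None
    any_ok = False
    for _ in range(n_restarts):
        theta0 = np.array(
            [
                rng.uniform(-2.0, 6.0),  # log10 a ~ log-uniform(1e-2, 1e6)
                rng.uniform(0.01, 0.99),
                rng.uniform(0.01, 0.99),
            ]
        )
        try:
            sol = least_squares(residuals, theta0, bounds=(lb, ub), method="trf")
        except Exception:  # pragma: no cover - solver pathologies
            continue
        any_ok = any_ok or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit restarts failed")
    a = 10.0 ** best.x[0]
    params = SigmoidalParams(a=a, b=float(best.x[1]), c=float(best.x[2]))
    fitted = model_probs(best.x)
    sse = float(np.sum((fitted - target) ** 2))
    dist = distribution_distance(fitted, target)
    bench = None
    if with_benchmark:
        bench = benchmark_error(hist, seed=seed)
    return FitResult(
        params=params,
        sse=sse,
        distance=dist,
        benchmark=bench,
        n_restarts=n_restarts,
        converged=any_ok,
    )


# ---------------------------------------------------------------------------
# Serial state-chain models (geometric adaptation)
# ---------------------------------------------------------------------------

def _state_rendition_pmf(state: ChainState, n_max: int) -> np.ndarray:
    """PMF of the number of renditions produced by one visit to a state."""
    pmf = np.zeros(n_max + 1)
    if not state.repeats or state.p_init == 0.0:
        pmf[1] = 1.0
        return pmf
    # m renditions: survive m-1 self-transitions with decreasing probability
    survive = 1.0
    for m in range(1, n_max + 1):
        p_stay = state.p_init * state.adapt_factor ** (m - 1)
        pmf[m] = survive * (1.0 - p_stay)
        survive *= p_stay
    # remaining mass beyond n_max folded into the last bin's complement; the
    # caller tracks tail mass from the total
    return pmf


def state_chain_distribution(model: StateChainModel, n_max: int) -> RepeatDistribution:
    """Exact distribution of total renditions across the serial states.

    Computed by convolving the per-state rendition-count distributions
    (dynamic programming over state index and running total).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    total = np.zeros(n_max + 1)
    total[0] = 1.0
    for state in model.states:
        pmf = _state_rendition_pmf(state, n_max)
        total = np.convolve(total, pmf)[: n_max + 1]
    probs = total[1:]
    tail = float(max(0.0, 1.0 - probs.sum()))
    return RepeatDistribution(probs=probs, tail_mass=tail)


def _chain_from_theta(topology: str, n_prefix: int, theta: np.ndarray) -> StateChainModel:
    if topology == "single":
        states = [ChainState(True, theta[0], theta[1])]
    elif topology == "two_repeating":
        states = [
            ChainState(True, theta[0], theta[1]),
            ChainState(True, theta[2], theta[3]),
        ]
    elif topology == "prefix_then_repeating":
        states = [ChainState(False) for _ in range(n_prefix)]
        states.append(ChainState(True, theta[0], theta[1]))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return StateChainModel(states=tuple(states))


def fit_state_chain(
    hist: RepeatHistogram,
    topology: str = "single",
    n_prefix: int = 0,
    n_restarts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of a geometric-adaptation state chain.

    ``topology`` is one of ``single`` (one repeating state),
    ``two_repeating`` (two repeating states in series) or
    ``prefix_then_repeating`` (``n_prefix`` non-repeating states followed by
    one repeating state, forcing a minimum repeat number of n_prefix + 1).
    """
    if len(hist.counts) < 2:
        raise ValueError("histogram has a single support point")
    n_params = 4 if topology == "two_repeating" else 2
    n_max = _fit_support(hist)
    target = hist.probabilities(n_max)
    rng = np.random.default_rng(seed)

    def model_probs(theta: np.ndarray) -> np.ndarray:
        model = _chain_from_theta(topology, n_prefix, theta)
        return state_chain_distribution(model, n_max).probs

    lb = np.full(n_params, 1e-6)
    ub = np.full(n_params, 1.0 - 1e-9)
    best = None
    any_ok = False
    for _ in range(n_restarts):
        theta0 = rng.uniform(0.05, 0.95, size=n_params)
        try:
            sol = least_squares(
                lambda th: model_probs(th) - target, theta0, bounds=(lb, ub),
                method="trf",
            )
        except Exception:  # pragma: no cover
            continue
        any_ok = any_ok or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit restarts failed")
    model = _chain_from_theta(topology, n_prefix, best.x)
    fitted = model_probs(best.x)
    sse = float(np.sum((fitted - target) ** 2))
    dist = distribution_distance(fitted, target)
    return FitResult(
        params=model, sse=sse, distance=dist, n_restarts=n_restarts, converged=any_ok
    )


# ---------------------------------------------------------------------------
# Distribution comparison
# ---------------------------------------------------------------------------

def _as_prob_array(p) -> np.ndarray:
    if isinstance(p, RepeatDistribution):
        return np.asarray(p.probs, dtype=float)
    if isinstance(p, RepeatHistogram):
        return p.probabilities()
    return np.asarray(p, dtype=float)


def distribution_distance(p1, p2) -> float:
    """Maximum absolute difference normalized by the overall maximum.

    d = max_n |p1(n) - p2(n)| / max_n max(p1(n), p2(n)); symmetric, in [0, 1].
    Distributions of different lengths are zero-padded to a common support.
    """
    a1, a2 = _as_prob_array(p1), _as_prob_array(p2)
    n = max(len(a1), len(a2))
    a1 = np.pad(a1, (0, n - len(a1)))
    a2 = np.pad(a2, (0, n - len(a2)))
    denom = max(a1.max(), a2.max())
    if denom <= 0:
        raise ValueError("both distributions are identically zero")
    return float(np.abs(a1 - a2).max() / denom)


def benchmark_error(
    hist: RepeatHistogram,
    n_resamples: int = 1000,
    percentile: float = 80.0,
    seed: int = 0,
) -> float:
    """Split-half benchmark error of a repeat-number data set.

    The bout-level data are randomly split into two equal halves (an odd
    leftover bout goes to the first half), the distance between the two
    half-histograms is computed, and the ``percentile``-th percentile over
    ``n_resamples`` splits is returned.  This is the fit-quality yardstick:
    it measures the distance expected between two finite samples of the same
    underlying distribution.
    """
    if hist.bout_level_data is None:
        raise ValueError(
            "benchmark error needs bout-level data; a histogram alone cannot "
            "be resampled into halves"
        )
    data = np.asarray(hist.bout_level_data, dtype=int)
    if data.size < 4:
        raise ValueError("need at least 4 bouts for split-half resampling")
    rng = np.random.default_rng(seed)
    n_max = int(data.max())
    half = (data.size + 1) // 2
    dists = np.empty(n_resamples)
    for i in range(n_resamples):
        perm = rng.permutation(data)
        h1 = np.bincount(perm[:half], minlength=n_max + 1)[1:]
        h2 = np.bincount(perm[half:], minlength=n_max + 1)[1:]
        p1 = h1 / h1.sum()
        p2 = h2 / h2.sum()
        diff = np.abs(p1 - p2).max()
        denom = max(p1.max(), p2.max())
        dists[i] = diff / denom
    return float(np.percentile(dists, percentile))


def peak_repeat_number(dist) -> int:
    """Most probable repeat number (mode); smallest index on exact ties."""
    p = _as_prob_array(dist)
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("empty distribution")
    return int(np.argmax(p)) + 1


def phase_diagram(
    a0_grid,
    alpha_grid,
    constants: Mapping[str, float] | None = None,
    n_bouts: int = 10_000,
    seed: int = 0,
) -> PhaseDiagram:
    """Peak repeat number over a grid of feedback and adaptation strengths."""
    a0_grid = np.asarray(a0_grid, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if a0_grid.size == 0 or alpha_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(alpha_grid < ALPHA_FLOOR):
        raise ValueError(f"alpha values must be >= {ALPHA_FLOOR}")
    rng = np.random.default_rng(seed)
    peak = np.zeros((a0_grid.size, alpha_grid.size), dtype=int)
    for i, a0 in enumerate(a0_grid):
        for j, alpha in enumerate(alpha_grid):
            hist = simulate_bouts(a0, alpha, constants, n_bouts=n_bouts, seed=rng)
            peak[i, j] = peak_repeat_number(hist)
    return PhaseDiagram(
        a0_grid=a0_grid, alpha_grid=alpha_grid, peak=peak, n_bouts=n_bouts, seed=seed
    )
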