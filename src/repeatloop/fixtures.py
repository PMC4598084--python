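"""Seeded synthetic-data generators.

Every other module gets a no-download test surface from here: labeled song
bouts of the form ``a b^n c`` with repeat numbers drawn from a named
statistical model, homogeneous Poisson spike trains, and deterministic toy
spike rasters for the syllable-onset detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .repeat_model import (
    ChainState,
    RepeatDistribution,
    SigmoidalParams,
    StateChainModel,
    repeat_distribution,
    state_chain_distribution,
)
from .song_sequences import BoutSequence

__all__ = [
    "GeneratorSpec",
    "generate_bouts",
    "generate_repeat_numbers",
    "generate_poisson_train",
    "make_toy_raster",
]

_MODELS = ("sigmoidal", "markov", "geometric", "state_chain")


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic bout generator.

    model : one of sigmoidal | markov | geometric | state_chain
    parameters : model parameters --
        sigmoidal: a, b, c; markov: c (exit probability);
        geometric: a, b (repeat probability a*b**n, exit otherwise);
        state_chain: states = sequence of (repeats, p_init, adapt_factor)
    n_bouts : number of bouts; prefix/suffix : context labels around the run.
    """

    model: str
    parameters: Mapping[str, object]
    n_bouts: int = 1000
    prefix: str = "a"
    suffix: str = "c"
    repeat_label: str = "b"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.n_bouts < 1:
            raise ValueError("n_bouts must be >= 1")


def _model_distribution(spec: GeneratorSpec, n_max: int = 1000) -> RepeatDistribution:
    p = dict(spec.parameters)
    if spec.model == "sigmoidal":
        params = SigmoidalParams(a=float(p["a"]), b=float(p["b"]), c=float(p["c"]))
        return repeat_distribution(params, n_max)
    if spec.model == "markov":
        # constant exit probability c: geometric repeat numbers
        params = SigmoidalParams(a=0.0, b=1.0, c=float(p["c"]))
        return repeat_distribution(params, n_max)
    if spec.model == "geometric":
        # geometric adaptation: p_r(n) = a * b**n (requires a*b <= 1)
        params = SigmoidalParams(a=float(p["a"]), b=float(p["b"]), c=1.0)
        return repeat_distribution(params, n_max)
    states = tuple(
        ChainState(repeats=bool(r), p_init=float(pi), adapt_factor=float(ad))
        for r, pi, ad in p["states"]
    )
    return state_chain_distribution(StateChainModel(states=states), n_max)


def generate_repeat_numbers(spec: GeneratorSpec) -> np.ndarray:
    """Draw ``n_bouts`` repeat numbers from the named model distribution."""
    rng = np.random.default_rng(spec.seed)
    dist = _model_distribution(spec)
    probs = np.append(dist.probs, dist.tail_mass)
    probs = probs / probs.sum()
    draws = rng.choice(probs.size, size=spec.n_bouts, p=probs) + 1
    return draws.astype(int)


def generate_bouts(spec: GeneratorSpec) -> list[BoutSequence]:
    """Bouts of the form prefix + repeat_label*N + suffix."""
    repeats = generate_repeat_numbers(spec)
    bouts = []
    for i, n in enumerate(repeats):
        labels = (
            tuple(spec.prefix) + (spec.repeat_label,) * int(n) + tuple(spec.suffix)
        )
        bouts.append(BoutSequence(bout_id=str(i), labels=labels))
    return bouts


def generate_poisson_train(
    rate: float, duration: float, seed: int = 0
) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration) at ``rate`` Hz."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    # draw enough exponential gaps to cover the window with margin
    n_guess = int(rate * duration + 10 * np.sqrt(rate * duration) + 10)
    times = np.cumsum(rng.exponential(1.0 / rate, size=n_guess))
    while times.size and times[-1] < duration:
        extra = np.cumsum(rng.exponential(1.0 / rate, size=n_guess)) + times[-1]
        times = np.concatenate([times, extra])
    return times[times < duration]


def make_toy_raster(
    schedule: Sequence[tuple[float, int]],
) -> np.ndarray:
    """Deterministic spike raster from an explicit (time_ms, neuron_id) schedule.

    Returns a structured float array of shape (n, 2) sorted by time.
    Duplicate (time, id) pairs are rejected.
    """
    if len(schedule) == 0:
        return np.empty((0, 2))
    arr = np.asarray(schedule, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("schedule must be a sequence of (time_ms, neuron_id)")
    if np.any(arr[:, 0] < 0):
        raise ValueError("schedule times must be non-negative")
    uniq = {tuple(row) for row in arr.tolist()}
    if len(uniq) != len(arr):
        raise ValueError("duplicate (time, neuron_id) pairs in schedule")
    return arr[np.lexsort((arr[:, 1], arr[:, 0]))]
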