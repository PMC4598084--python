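"""Sequence analytics for labeled song bouts.

A bout is an ordered sequence of syllable labels (a continuous period of
singing).  Repeat numbers are the lengths of maximal runs of identical
consecutive labels; runs never span bout boundaries.  Syllables are
classified by the shape of their repeat-number distribution:

* NR  - non-repeated: never produced twice in a row,
* MR  - Markovian repeated: peak repeat number = 1,
* nMR - non-Markovian repeated: peak repeat number > 1.

A few repeated syllables show double-peaked distributions (a sharp peak at
repeat number 1 plus a broad peak far away), consistent with two separate
neural substrates mapping to the same syllable; those are flagged and the
repeat-number-1 bin removed before classification of the long-repeat part.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby, product
from typing import Iterable, Sequence

import numpy as np

from .repeat_model import RepeatHistogram, peak_repeat_number

__all__ = [
    "BoutSequence",
    "SyllableStats",
    "parse_bout_line",
    "read_bout_file",
    "extract_repeat_histograms",
    "classify_syllable",
    "detect_and_trim_double_peak",
    "pseudo_random_stimulus_sequences",
]


@dataclass(frozen=True)
class BoutSequence:
    """One bout: an id and the ordered syllable labels it contains."""

    bout_id: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError(f"bout {self.bout_id!r} is empty")


@dataclass
class SyllableStats:
    """Per-syllable repeat statistics and classification."""

    label: str
    histogram: RepeatHistogram
    syllable_class: str  # NR | MR | nMR
    intro: bool = False
    double_peak: bool = False
    trimmed_histogram: RepeatHistogram | None = None


def parse_bout_line(line: str, bout_id: str = "") -> BoutSequence:
    """Parse one bout line; whitespace-separated tokens or single characters.

    The dialect is auto-detected: lines containing whitespace are split into
    tokens, otherwise each character is one syllable label.
    """
    line = line.strip()
    if not line:
        raise ValueError("empty bout line")
    labels = tuple(line.split()) if any(ch.isspace() for ch in line) else tuple(line)
    return BoutSequence(bout_id=bout_id, labels=labels)


def read_bout_file(path) -> list[BoutSequence]:
    """Read a plain-text bout file, one bout per line."""
    bouts = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.strip():
                bouts.append(parse_bout_line(line, bout_id=str(i)))
    if not bouts:
        raise ValueError(f"no bouts found in {path}")
    return bouts


def _runs(labels: Sequence[str]) -> Iterable[tuple[str, int]]:
    for label, grp in groupby(labels):
        yield label, sum(1 for _ in grp)


def extract_repeat_histograms(
    bouts: Iterable[BoutSequence],
) -> dict[str, RepeatHistogram]:
    """Run-length repeat histograms per syllable label.

    Each maximal run of identical consecutive labels contributes one count at
    its run length.  Runs truncated at bout edges are counted as complete.
    """
    per_label: dict[str, list[int]] = {}
    n_bouts = 0
    for bout in bouts:
        n_bouts += 1
        for label, length in _runs(bout.labels):
            per_label.setdefault(label, []).append(length)
    if n_bouts == 0:
        raise ValueError("empty bout collection")
    return {
        label: RepeatHistogram.from_bouts(lengths)
        for label, lengths in per_label.items()
    }


def detect_and_trim_double_peak(
    hist: RepeatHistogram,
    min_second_peak: int = 4,
    trough_ratio: float = 0.5,
    min_peak_fraction: float = 0.05,
) -> tuple[bool, RepeatHistogram]:
    """Flag and trim double-peaked repeat histograms.

    Flags when the count at repeat number 1 is a local maximum and a second,
    prominent local maximum exists at N >= ``min_second_peak``, separated by
    a trough at most ``trough_ratio`` of the smaller peak.  The prominence
    requirement (second peak carries at least ``min_peak_fraction`` of the
    total count) keeps sampling noise in long geometric tails from
    registering as a second mode.  Trimming removes the N = 1 bin only,
    leaving the long-repeat part for analysis.
    """
    n_max = hist.n_max
    if n_max < min_second_peak:
        return False, hist
    counts = np.zeros(n_max + 1)
    for n, cnt in hist.counts.items():
        counts[n] = cnt
    c = counts[1:]  # c[k] = count at repeat number k+1
    if c[0] <= c[1]:  # N=1 not a local maximum
        return False, hist
    # prominent interior local maxima at N >= min_second_peak
    second = None
    floor = min_peak_fraction * hist.total
    for k in range(min_second_peak - 1, len(c)):
        left = c[k - 1] if k > 0 else -np.inf
        right = c[k + 1] if k + 1 < len(c) else -np.inf
        if c[k] >= floor and c[k] >= left and c[k] >= right:
            if second is None or c[k] > c[second]:
                second = k
    if second is None:
        return False, hist
    trough = c[1:second].min() if second > 1 else np.inf
    smaller_peak = min(c[0], c[second])
    if trough > trough_ratio * smaller_peak:
        return False, hist
    trimmed_counts = {n: cnt for n, cnt in hist.counts.items() if n >= 2}
    if not trimmed_counts:
        return False, hist
    data = None
    if hist.bout_level_data is not None:
        arr = np.asarray(hist.bout_level_data)
        data = arr[arr >= 2]
    return True, RepeatHistogram(counts=trimmed_counts, bout_level_data=data)


def classify_syllable(
    hist: RepeatHistogram,
    intro: bool = False,
    trim_double_peak: bool = True,
) -> SyllableStats:
    """Classify a syllable as NR, MR or nMR from its repeat histogram."""
    label = ""
    if set(hist.counts) == {1}:
        return SyllableStats(label, hist, "NR", intro=intro)
    flagged, trimmed = (False, hist)
    if trim_double_peak:
        flagged, trimmed = detect_and_trim_double_peak(hist)
    use = trimmed if flagged else hist
    peak = peak_repeat_number(use)
    cls = "MR" if peak == 1 else "nMR"
    return SyllableStats(
        label, hist, cls, intro=intro, double_peak=flagged,
        trimmed_histogram=trimmed if flagged else None,
    )


def _natural_kmers(natural_sequences: Iterable[Sequence[str]], k: int) -> set[tuple[str, ...]]:
    kmers = set()
    for seq in natural_sequences:
        seq = tuple(seq)
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])
    return kmers


def pseudo_random_stimulus_sequences(
    repertoire: Sequence[str],
    natural_sequences: Iterable[Sequence[str]],
    seed: int = 0,
    n_sequences: int = 10,
    length: int = 1000,
    max_piece: int = 10,
) -> list[tuple[str, ...]]:
    """Pseudo-random stimulus strings from natural and non-natural pieces.

    Concatenates subsequences of length 1..``max_piece`` -- drawn with equal
    probability per length, alternating with equal probability between
    natural pieces (k-mers occurring in ``natural_sequences``) and
    non-natural pieces (k-mers over the repertoire that never occur) -- until
    each string reaches ``length`` labels (the final piece is truncated).
    """
    repertoire = list(dict.fromkeys(repertoire))
    natural = [tuple(s) for s in natural_sequences]
    if not natural:
        raise ValueError("natural_sequences must be non-empty")
    for seq in natural:
        unknown = set(seq) - set(repertoire)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in repertoire")
    rng = np.random.default_rng(seed)

    natural_by_k: dict[int, list[tuple[str, ...]]] = {}
    nonnatural_by_k: dict[int, list[tuple[str, ...]]] = {}
    for k in range(1, max_piece + 1):
        nat = sorted(_natural_kmers(natural, k))
        if nat:
            natural_by_k[k] = nat
        if len(repertoire) ** k <= 4096:
            non = sorted(set(product(repertoire, repeat=k)) - set(nat))
            nonnatural_by_k[k] = non  # may be empty: every k-mer is natural
        # large alphabets: absent key means rejection-sample on demand
    if not any(nonnatural_by_k.get(k, [None]) for k in range(1, max_piece + 1)):
        raise ValueError("repertoire too small to form non-natural sequences")

    def draw_nonnatural(k: int) -> tuple[str, ...] | None:
        if k in nonnatural_by_k:
            pool = nonnatural_by_k[k]
            return pool[rng.integers(len(pool))] if pool else None
        nat_k = _natural_kmers(natural, k)
        for _ in range(1000):
            cand = tuple(repertoire[i] for i in rng.integers(len(repertoire), size=k))
            if cand not in nat_k:
                return cand
        return None

    def draw_piece(k: int, natural_piece: bool) -> tuple[str, ...]:
        if natural_piece:
            pool = natural_by_k.get(k)
            if pool:
                return pool[rng.integers(len(pool))]
            piece = draw_nonnatural(k)  # no natural piece of this length
        else:
            piece = draw_nonnatural(k)
            if piece is None:
                pool = natural_by_k.get(k)
                piece = pool[rng.integers(len(pool))] if pool else None
        if piece is None:
            raise ValueError(f"no sequences of length {k} available")
        return piece

    sequences = []
    for _ in range(n_sequences):
        out: list[str] = []
        while len(out) < length:
            k = int(rng.integers(1, max_piece + 1))
            natural_piece = bool(rng.integers(2))
            out.extend(draw_piece(k, natural_piece))
        sequences.append(tuple(out[:length]))
    return sequences
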