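"""F-motif segmentation and its derived spectra.

An F-motif is the longest continuous run of tokens whose within-chunk
frequency values are equal or increasing.  A text therefore decomposes
exhaustively into F-motifs: a new motif starts exactly where the frequency
value drops below its predecessor.  Because function words sit at the
high-frequency end of the spectrum, the last element of a motif tends to be
a function word, and motif length tracks the local density of function
words — the structural fact the downstream group comparisons exploit.

The module derives four summaries from a motif list:

* the rank-frequency spectrum of motif types (domain of the Zipf–Mandelbrot
  fit),
* the length spectrum (domain of the Hyper-Pascal fit),
* the position grid of mean frequency values at position p of motifs of
  length L, and
* function/content word tallies from a closed-class stoplist.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import EmptyInputError, FrequencyTable, TokenSequence
from .stoplist import DEFAULT_FUNCTION_WORDS

__all__ = [
    "FMotif",
    "MotifSpectrum",
    "LengthSpectrum",
    "PositionGrid",
    "WordClassTally",
    "annotate_frequencies",
    "extract_fmotifs",
    "rank_frequency_spectrum",
    "length_spectrum",
    "position_grid",
    "classify_function_content",
    "short_long_counts",
    "motif_str",
]

SHORT_MAX = 3  # "shorter" motifs: lengths 1..3
LONG_MAX = 7  # "longer" motifs: lengths 4..7; >7 excluded from both bins


@dataclass(frozen=True)
class FMotif:
    """One maximal non-decreasing run of frequency values.

    ``start`` is the 0-based token index of the run in its chunk; ``words``
    optionally carries the underlying token slice.
    """

    values: tuple[int, ...]
    start: int = 0
    words: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("an F-motif holds at least one value")
        if any(b < a for a, b in zip(self.values, self.values[1:])):
            raise ValueError(f"motif values must be non-decreasing: {self.values}")
        if self.words is not None and len(self.words) != len(self.values):
            raise ValueError("words and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def motif_str(values: Sequence[int]) -> str:
    """Hyphen notation for a motif type, e.g. ``(1, 8, 24)`` -> ``"1-8-24"``."""
    return "-".join(str(v) for v in values)


@dataclass
class MotifSpectrum:
    """Type-frequency spectrum of motif types.

    ``entries`` is sorted by descending frequency with ties broken by
    lexicographic order of the value tuple, so ranks 1..V are deterministic.
    ``N`` counts motif tokens (instances), ``V`` motif types.
    """

    entries: list[tuple[tuple[int, ...], int]]
    N: int
    V: int

    @classmethod
    def from_motifs(cls, motifs: Sequence[FMotif]) -> "MotifSpectrum":
        if not motifs:
            raise EmptyInputError("cannot build a spectrum from zero motifs")
        counts = Counter(m.values for m in motifs)
        entries = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(entries=entries, N=len(motifs), V=len(entries))

    @property
    def frequencies(self) -> list[int]:
        return [f for _, f in self.entries]


@dataclass
class LengthSpectrum:
    """Counts of motifs by length (number of words in the run)."""

    counts: dict[int, int]

    @classmethod
    def from_motifs(cls, motifs: Sequence[FMotif]) -> "LengthSpectrum":
        if not motifs:
            raise EmptyInputError("cannot build a length spectrum from zero motifs")
        return cls(counts=dict(Counter(len(m) for m in motifs)))

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    @property
    def max_length(self) -> int:
        return max(self.counts)


@dataclass
class PositionGrid:
    """Mean word frequency at position p of motifs of length L (L <= max_len)."""

    mean_freq: dict[tuple[int, int], float]
    log10_mean_freq: dict[tuple[int, int], float]
    n_motifs: dict[int, int]
    max_len: int = LONG_MAX


@dataclass
class WordClassTally:
    function_count: int
    content_count: int
    labels: list[str] = field(default_factory=list)


def annotate_frequencies(chunk: TokenSequence, table: FrequencyTable) -> list[int]:
    """Map each token of the chunk to its within-chunk frequency value."""
    return [table[t] for t in chunk.tokens]


def extract_fmotifs(
    values: Sequence[int], words: Sequence[str] | None = None
) -> list[FMotif]:
    """Segment a value sequence into maximal non-decreasing runs.

    A new motif starts exactly where ``values[i] < values[i-1]``; the
    concatenation of the motifs reproduces the input.
    """
    if any(v < 1 for v in values):
        raise ValueError("frequency values must be positive integers")
    motifs: list[FMotif] = []
    n = len(values)
    i = 0
    while i < n:
        j = i + 1
        while j < n and values[j] >= values[j - 1]:
            j += 1
        motifs.append(
            FMotif(
                values=tuple(values[i:j]),
                start=i,
                words=tuple(words[i:j]) if words is not None else None,
            )
        )
        i = j
    return motifs


def rank_frequency_spectrum(motifs: Sequence[FMotif]) -> MotifSpectrum:
    """Rank-frequency spectrum over motif types (identity = value tuple)."""
    return MotifSpectrum.from_motifs(motifs)


def length_spectrum(motifs: Sequence[FMotif]) -> LengthSpectrum:
    return LengthSpectrum.from_motifs(motifs)


def position_grid(motifs: Iterable[FMotif], max_len: int = LONG_MAX) -> PositionGrid:
    """Arithmetic mean frequency per (length, position) cell, lengths <= max_len.

    Cells with no contributing motifs are absent.  The last position of a
    run holds its maximum, so mean_freq[(L, L)] >= mean_freq[(L, 1)].
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    sums: dict[tuple[int, int], float] = {}
    n_by_len: Counter[int] = Counter()
    for m in motifs:
        L = len(m)
        if L > max_len:
            continue
        n_by_len[L] += 1
        for p, v in enumerate(m.values, start=1):
            sums[(L, p)] = sums.get((L, p), 0.0) + v
    means = {lp: s / n_by_len[lp[0]] for lp, s in sums.items()}
    return PositionGrid(
        mean_freq=means,
        log10_mean_freq={lp: math.log10(v) for lp, v in means.items()},
        n_motifs=dict(n_by_len),
        max_len=max_len,
    )


def classify_function_content(
    chunk: TokenSequence | Sequence[str],
    stoplist: frozenset[str] | set[str] | None = None,
) -> WordClassTally:
    """Label each token FUNCTION iff its normalized form is on the stoplist."""
    tokens = chunk.tokens if isinstance(chunk, TokenSequence) else list(chunk)
    stop = DEFAULT_FUNCTION_WORDS if stoplist is None else stoplist
    labels = ["FUNCTION" if t in stop else "CONTENT" for t in tokens]
    fc = labels.count("FUNCTION")
    return WordClassTally(function_count=fc, content_count=len(labels) - fc, labels=labels)


def short_long_counts(motifs: Iterable[FMotif]) -> tuple[int, int]:
    """Counts of shorter (length 1-3) and longer (length 4-7) motifs.

    Motifs longer than 7 fall in neither bin; they remain visible in the
    length spectrum.
    """
    short = long = 0
    for m in motifs:
        L = len(m)
        if L <= SHORT_MAX:
            short += 1
        elif L <= LONG_MAX:
            long += 1
    return short, long
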