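"""A small worked example: one 15-token sentence with within-file counts.

The sentence comes from a press-conference interpreting transcript; the
frequency value attached to each token is its occurrence count in the file
the sentence was drawn from.  It is the canonical hand-checkable input for
motif segmentation, word-class tallies and position statistics.
"""

from __future__ import annotations

from .corpus_io import FrequencyTable, TokenSequence, tokenize

__all__ = [
    "WORKED_SENTENCE",
    "WORKED_FREQUENCIES",
    "worked_chunk",
    "worked_table",
    "worked_values",
]

WORKED_SENTENCE = (
    "On trade issue we have always maintained that trade disputes "
    "should be resolved through consultations."
)

#: within-file occurrence count of each word form of the sentence
WORKED_FREQUENCIES: dict[str, int] = {
    "on": 23,
    "trade": 14,
    "issue": 6,
    "we": 44,
    "have": 29,
    "always": 3,
    "maintained": 1,
    "that": 70,
    "disputes": 1,
    "should": 8,
    "be": 24,
    "resolved": 1,
    "through": 3,
    "consultations": 3,
}


def worked_chunk() -> TokenSequence:
    """The worked sentence, tokenized."""
    return tokenize(WORKED_SENTENCE, doc_id="worked-example")


def worked_table() -> FrequencyTable:
    """The within-file frequency table for the worked sentence."""
    return FrequencyTable(scope_id="worked-example", counts=dict(WORKED_FREQUENCIES))


def worked_values() -> list[int]:
    """The 15 per-token frequency values, in surface order."""
    return [WORKED_FREQUENCIES[t] for t in worked_chunk().tokens]
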