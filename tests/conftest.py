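from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_chunk():
    from fmotif.examples import worked_chunk

    return worked_chunk()


@pytest.fixture
def worked_values():
    from fmotif.examples import worked_values

    return worked_values()


@pytest.fixture
def worked_motifs(worked_values):
    from fmotif import extract_fmotifs

    return extract_fmotifs(worked_values)


def build_worked_fixture_text() -> str:
    """Synthetic document in which the worked sentence opens the file and
    filler paragraphs pad each word up to its reference within-file count,
    so that within-chunk frequencies reproduce the reference values."""
    from collections import Counter

    from fmotif.examples import WORKED_FREQUENCIES, WORKED_SENTENCE
    from fmotif.corpus_io import tokenize

    sent_tokens = tokenize(WORKED_SENTENCE).tokens
    have = Counter(sent_tokens)
    filler = []
    for word in sorted(WORKED_FREQUENCIES):
        filler.extend([word] * (WORKED_FREQUENCIES[word] - have[word]))
    return WORKED_SENTENCE + "\n\n" + " ".join(filler) + "\n"


@pytest.fixture
def worked_fixture_text():
    return build_worked_fixture_text()
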