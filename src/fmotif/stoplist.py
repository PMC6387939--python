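"""Packaged default function-word list.

The classification is lexicon-based over the enumerable closed classes:
articles, conjunctions, prepositions, pronouns, and the non-lexical
(auxiliary) verbs *do*, *be* and *have*.  Modal verbs are deliberately NOT
on the list — auxiliaries are restricted to do/be/have forms, so modals
such as "should" count as content (lexical) verbs.  Users can pass their
own set to :func:`fmotif.motif.classify_function_content` or point the
pipeline at a replacement list (one word form per line).
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["DEFAULT_FUNCTION_WORDS", "load_stoplist", "STOPLIST_VERSION"]

STOPLIST_VERSION = "1.0"

_ARTICLES = {"a", "an", "the"}

_CONJUNCTIONS = {
    "and", "or", "but", "nor", "so", "yet", "that", "if", "because",
    "although", "though", "while", "whereas", "since", "unless", "until",
    "than", "whether", "as", "when", "whenever", "where", "wherever",
    "after", "before", "once", "lest",
}

_PREPOSITIONS = {
    "of", "in", "to", "on", "at", "by", "with", "from", "into", "onto",
    "upon", "about", "above", "below", "under", "underneath", "over",
    "between", "among", "amongst", "through", "throughout", "during",
    "against", "within", "without", "across", "behind", "beyond", "near",
    "off", "out", "up", "down", "around", "round", "toward", "towards",
    "per", "via", "amid", "amidst", "despite", "except", "beside",
    "besides", "along", "alongside", "inside", "outside", "past", "for",
}

_PRONOUNS = {
    "i", "you", "he", "she", "it", "we", "they",
    "me", "him", "her", "us", "them",
    "my", "your", "his", "its", "our", "their",
    "mine", "yours", "hers", "ours", "theirs",
    "myself", "yourself", "yourselves", "himself", "herself", "itself",
    "ourselves", "themselves", "oneself",
    "this", "these", "those",
    "who", "whom", "whose", "which", "what",
    "anybody", "anyone", "anything", "everybody", "everyone", "everything",
    "nobody", "nothing", "somebody", "someone", "something", "none",
}

_AUX_DO_BE_HAVE = {
    "do", "does", "did", "done", "doing",
    "be", "am", "is", "are", "was", "were", "been", "being",
    "have", "has", "had", "having",
}

DEFAULT_FUNCTION_WORDS: frozenset[str] = frozenset(
    _ARTICLES | _CONJUNCTIONS | _PREPOSITIONS | _PRONOUNS | _AUX_DO_BE_HAVE
)


def load_stoplist(path: str | Path) -> frozenset[str]:
    """Load a user stoplist: one lowercase word form per line, # comments."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)
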