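"""Corpus ingestion: tokenization, paragraph-aware chunking, frequency tables.

Documents are plain UTF-8 text, one document per file, with paragraphs
separated by blank lines.  Word frequencies are always counted *within* the
chunk being analysed — no external reference corpus is consulted — because
the frequency value of a word is meaningful only relative to the text it
occurs in.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "RawDocument",
    "TokenSequence",
    "FrequencyTable",
    "EmptyInputError",
    "EncodingError",
    "ConsistencyError",
    "tokenize",
    "segment_corpus",
    "word_frequencies",
    "read_manifest",
    "load_documents",
    "write_chunks",
]


class EmptyInputError(ValueError):
    """An operation requiring tokens received an empty chunk."""


class EncodingError(ValueError):
    """Input bytes are not valid UTF-8."""


class ConsistencyError(KeyError):
    """Two artifacts that must come from the same chunk do not agree."""


# Maximal runs of letters/digits, optionally joined by internal apostrophes
# ("don't" stays one token); hyphens split; leading/trailing apostrophes drop.
_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)
_PARA_RE = re.compile(r"\n[ \t\r]*\n")


@dataclass
class RawDocument:
    """One input document with its group label and optional speaker id."""

    doc_id: str
    text: str
    group: str
    speaker_id: str | None = None
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if not self.text and not self.allow_empty:
            raise EmptyInputError(f"document {self.doc_id!r} is empty")


@dataclass
class TokenSequence:
    """Ordered normalized tokens of one document or chunk.

    ``paragraph_breaks`` holds the token index at which each paragraph
    starts (the first entry is 0 for any non-empty sequence).
    """

    doc_id: str
    tokens: list[str]
    paragraph_breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if any(not (0 <= b <= n) for b in self.paragraph_breaks):
            raise ValueError("paragraph break outside [0, len(tokens)]")
        if self.paragraph_breaks != sorted(self.paragraph_breaks):
            raise ValueError("paragraph_breaks must be sorted")

    def __len__(self) -> int:
        return len(self.tokens)

    def paragraphs(self) -> Iterator[tuple[int, int]]:
        """Yield (start, end) token spans of the paragraphs, in order."""
        bounds = list(self.paragraph_breaks) + [len(self.tokens)]
        if not self.paragraph_breaks and self.tokens:
            bounds = [0, len(self.tokens)]
        for s, e in zip(bounds, bounds[1:]):
            if e > s:
                yield s, e


@dataclass
class FrequencyTable:
    """Within-chunk occurrence counts of normalized word forms."""

    scope_id: str
    counts: dict[str, int]

    def __getitem__(self, token: str) -> int:
        try:
            return self.counts[token]
        except KeyError:
            raise ConsistencyError(
                f"token {token!r} absent from frequency table {self.scope_id!r};"
                " the table must be computed over the same chunk"
            ) from None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def tokenize(text: str | bytes, doc_id: str = "", *, lowercase: bool = True) -> TokenSequence:
    """Normalize and tokenize raw text.

    Tokens are maximal runs of letters/digits with internal apostrophes
    kept, lowercased by default; all other punctuation is discarded and
    hyphens split.  Blank lines mark paragraph starts, recorded as token
    indices in ``paragraph_breaks``.
    """
    if isinstance(text, bytes):
        try:
            text = text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise EncodingError(f"{doc_id or 'input'}: not valid UTF-8: {exc}") from exc
    tokens: list[str] = []
    breaks: list[int] = []
    for para in _PARA_RE.split(text):
        if lowercase:
            para = para.lower()
        ptoks = _TOKEN_RE.findall(para)
        if ptoks:
            breaks.append(len(tokens))
            tokens.extend(ptoks)
    return TokenSequence(doc_id=doc_id, tokens=tokens, paragraph_breaks=breaks)


def segment_corpus(docs: Iterable[TokenSequence], target_size: int) -> list[TokenSequence]:
    """Split documents into chunks of roughly ``target_size`` tokens.

    Paragraphs are packed greedily: a chunk is closed at the first paragraph
    end at which its token count reaches or exceeds ``target_size``.  Chunk
    boundaries always coincide with paragraph boundaries, chunks never span
    documents, and concatenating the chunks reproduces the token stream.

    A single paragraph longer than twice the target is emitted as its own
    chunk with a warning.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    chunks: list[TokenSequence] = []

    def close(doc: TokenSequence, toks: list[str], brks: list[int], k: int) -> int:
        chunks.append(
            TokenSequence(doc_id=f"{doc.doc_id}#{k:03d}", tokens=toks, paragraph_breaks=brks)
        )
        return k + 1

    for doc in docs:
        cur_toks: list[str] = []
        cur_brks: list[int] = []
        k = 0
        for s, e in doc.paragraphs():
            if e - s > 2 * target_size:
                warnings.warn(
                    f"{doc.doc_id}: paragraph of {e - s} tokens exceeds twice the "
                    f"target chunk size {target_size}; emitted as its own chunk",
                    stacklevel=2,
                )
                if cur_toks:
                    k = close(doc, cur_toks, cur_brks, k)
                    cur_toks, cur_brks = [], []
                k = close(doc, list(doc.tokens[s:e]), [0], k)
                continue
            cur_brks.append(len(cur_toks))
            cur_toks.extend(doc.tokens[s:e])
            if len(cur_toks) >= target_size:
                k = close(doc, cur_toks, cur_brks, k)
                cur_toks, cur_brks = [], []
        if cur_toks:
            close(doc, cur_toks, cur_brks, k)
    return chunks


def word_frequencies(chunk: TokenSequence) -> FrequencyTable:
    """Raw within-chunk occurrence counts of every normalized form."""
    if not chunk.tokens:
        raise EmptyInputError(f"chunk {chunk.doc_id!r} is empty")
    return FrequencyTable(scope_id=chunk.doc_id, counts=dict(Counter(chunk.tokens)))


# ---------------------------------------------------------------------------
# manifest / file IO


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a TSV manifest with columns path, group and optional speaker_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"path", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required column(s) {sorted(missing)}")
    if "speaker_id" not in df.columns:
        df["speaker_id"] = None
    return df


def load_documents(manifest: pd.DataFrame, base_dir: str | Path = ".") -> list[RawDocument]:
    """Load the documents a manifest points at, relative to ``base_dir``."""
    base = Path(base_dir)
    docs = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        text = p.read_bytes()
        try:
            decoded = text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise EncodingError(f"{p}: not valid UTF-8: {exc}") from exc
        docs.append(
            RawDocument(
                doc_id=p.stem,
                text=decoded,
                group=row.group,
                speaker_id=getattr(row, "speaker_id", None),
            )
        )
    return docs


def write_chunks(
    chunks: Iterable[TokenSequence],
    out_dir: str | Path,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Write chunk text files plus a chunk-manifest TSV; return the manifest.

    ``groups`` maps source doc_id -> group label (chunk ids are
    ``doc_id#NNN``).  Paragraph structure is preserved as blank lines.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for chunk in chunks:
        paras = [" ".join(chunk.tokens[s:e]) for s, e in chunk.paragraphs()]
        fname = chunk.doc_id.replace("#", "_") + ".txt"
        (out / fname).write_text("\n\n".join(paras) + "\n", encoding="utf-8")
        src = chunk.doc_id.split("#")[0]
        rows.append(
            {
                "chunk_id": chunk.doc_id,
                "source_doc": src,
                "token_count": len(chunk),
                "group": (groups or {}).get(src, ""),
                "path": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "chunk_manifest.tsv", sep="\t", index=False)
    return manifest
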