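"""Synthetic Zipfian corpora with a controllable function-word register.

Real interpreting transcripts are not redistributable, so the generator
emulates the statistical structure the pipeline assumes: word frequencies
follow a Zipf–Mandelbrot law over a fixed vocabulary, and a high-frequency
"function-word" register (the top-K ranks) is emitted with a tunable
probability ``phi``.  Raising ``phi`` densifies function words, which
truncates motifs earlier and shifts the length spectrum toward shorter
runs — the mechanism behind the consecutive-vs-simultaneous contrast the
analysis is designed to detect.

Tokens are i.i.d.; there is no n-gram syntax.  That is sufficient to
exercise every pipeline stage and to create the function-density contrast,
but it is a deliberate simplification of real speech (see docs/methods.md).

Default sizes follow the study design the pipeline targets: chunks of
4,000 tokens and 14 chunks per group (~57,000 running words).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus_io import RawDocument
from .distfit import hp_pmf, zm_pmf

__all__ = [
    "SyntheticSpec",
    "sample_zm_ranks",
    "sample_hyperpascal",
    "generate_corpus",
    "write_corpus",
]


@dataclass
class SyntheticSpec:
    """Generator settings; identical specs (and seeds) give identical corpora.

    vocab_size : ranks in the Zipf–Mandelbrot vocabulary.
    zm_a, zm_b : decay exponent and shift of the word-frequency law.
    function_top_ranks : top-K ranks designated as the function register.
    phi : probability of emitting a token from the function register.
    tokens_per_chunk, n_chunks, paragraph_len : corpus geometry.
    """

    vocab_size: int = 3000
    zm_a: float = 1.0
    zm_b: float = 2.5
    function_top_ranks: int = 50
    phi: float = 0.35
    tokens_per_chunk: int = 4000
    n_chunks: int = 14
    paragraph_len: int = 200
    seed: int = 0
    group: str = "SYN"

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.function_top_ranks > self.vocab_size:
            raise ValueError("function_top_ranks cannot exceed vocab_size")
        if self.phi > 0.0 and self.function_top_ranks == 0:
            raise ValueError("phi > 0 requires a non-empty function register")
        if self.phi < 1.0 and self.function_top_ranks >= self.vocab_size:
            raise ValueError("phi < 1 requires a non-empty content register")


def _inverse_cdf(pmf: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Map uniforms to 1-based indices by inverse CDF over an exact pmf."""
    cum = np.cumsum(pmf)
    idx = np.searchsorted(cum, u, side="right") + 1
    return np.minimum(idx, len(pmf))


def sample_zm_ranks(a: float, b: float, n: int, N: int, seed: int | np.random.Generator) -> np.ndarray:
    """N i.i.d. ranks drawn by inverse CDF over the exact ZM pmf."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if N < 0:
        raise ValueError("N must be >= 0")
    pmf = zm_pmf(a, b, n)
    return _inverse_cdf(pmf, rng.random(N))


def sample_hyperpascal(
    k: float, m: float, q: float, N: int, seed: int | np.random.Generator
) -> np.ndarray:
    """N i.i.d. Hyper-Pascal draws (support 0, 1, 2, ...) by inverse CDF.

    The pmf is truncated where the remaining tail mass falls below 1e-9.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if N < 0:
        raise ValueError("N must be >= 0")
    # grow the support until the tail is negligible
    x_max = 32
    while True:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pmf = hp_pmf(k, m, q, x_max)
        if 1.0 - pmf.sum() < 1e-9 or x_max > 100_000:
            break
        x_max *= 2
    return _inverse_cdf(pmf, rng.random(N)) - 1


def _word(rank: int) -> str:
    return f"w{rank:05d}"


def generate_corpus(spec: SyntheticSpec) -> tuple[list[RawDocument], pd.DataFrame]:
    """Generate one group of chunk-sized documents plus their manifest.

    Each token is drawn in two stages: with probability ``phi`` a rank from
    the top ``function_top_ranks`` (ZM-weighted, renormalized), otherwise a
    rank from the remaining vocabulary (ZM-weighted, renormalized).  Word
    forms are synthetic strings keyed by rank; paragraph breaks fall every
    ``paragraph_len`` tokens.
    """
    rng = np.random.default_rng(spec.seed)
    pmf = zm_pmf(spec.zm_a, spec.zm_b, spec.vocab_size)
    K = spec.function_top_ranks
    fun_pmf = pmf[:K] / pmf[:K].sum() if K > 0 else None
    con_pmf = pmf[K:] / pmf[K:].sum() if K < spec.vocab_size else None

    docs: list[RawDocument] = []
    rows = []
    for c in range(spec.n_chunks):
        T = spec.tokens_per_chunk
        ranks = np.empty(T, dtype=int)
        from_fun = rng.random(T) < spec.phi
        u = rng.random(T)
        nf = int(from_fun.sum())
        if nf:
            ranks[from_fun] = _inverse_cdf(fun_pmf, u[from_fun])
        if T - nf:
            ranks[~from_fun] = K + _inverse_cdf(con_pmf, u[~from_fun])
        words = [_word(r) for r in ranks]
        paras = [
            " ".join(words[i : i + spec.paragraph_len])
            for i in range(0, T, spec.paragraph_len)
        ]
        doc_id = f"{spec.group.lower()}_{c:03d}"
        docs.append(
            RawDocument(
                doc_id=doc_id, text="\n\n".join(paras) + "\n", group=spec.group
            )
        )
        rows.append(
            {
                "path": doc_id + ".txt",
                "group": spec.group,
                "speaker_id": f"spk{c % 3}",
                "token_count": T,
            }
        )
    return docs, pd.DataFrame(rows)


def write_corpus(
    docs: list[RawDocument],
    manifest: pd.DataFrame,
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
) -> Path:
    """Write a self-contained synthetic study directory: .txt chunks,
    manifest TSV and, if given, the generator spec as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (out / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    if spec is not None:
        (out / "spec.yaml").write_text(yaml.safe_dump(asdict(spec)), encoding="utf-8")
    return out
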