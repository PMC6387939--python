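"""End-to-end pipeline: extract motifs, fit models, compare groups.

Each stage reads and writes plain-text artifacts (TSV tables, JSON fit
reports, YAML configs) under a run directory, so a run is fully
reproducible from its directory: the resolved configuration is written
verbatim, and identical configs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus_io, distfit, motif, stats_compare
from .stoplist import DEFAULT_FUNCTION_WORDS, load_stoplist

__all__ = [
    "RunConfig",
    "run_extract",
    "run_fit",
    "run_compare",
    "run_all",
    "features_frame",
]

log = logging.getLogger("fmotif")

FEATURE_PARAMS = ["a", "b", "k", "m", "q"]


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run."""

    manifest: str
    outdir: str
    target_size: int = 4000
    stoplist: str | None = None
    models: tuple[str, ...] = ("zm", "hp")
    design: dict | None = None
    max_position_len: int = 7
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def dump(self, out: Path) -> None:
        d = dataclasses.asdict(self)
        d["models"] = list(d["models"])
        (out / "config.yaml").write_text(yaml.safe_dump(d), encoding="utf-8")

    def stoplist_set(self) -> frozenset[str]:
        return load_stoplist(self.stoplist) if self.stoplist else DEFAULT_FUNCTION_WORDS


def _setup(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(config.log_level)
    if not any(
        isinstance(h, logging.FileHandler) and h.baseFilename == fh.baseFilename
        for h in log.handlers
    ):
        log.addHandler(fh)
    config.dump(out)
    return out


def _chunk_artifacts(chunk: corpus_io.TokenSequence, stop: frozenset[str], max_len: int):
    table = corpus_io.word_frequencies(chunk)
    values = motif.annotate_frequencies(chunk, table)
    motifs = motif.extract_fmotifs(values, words=chunk.tokens)
    spectrum = motif.rank_frequency_spectrum(motifs)
    lengths = motif.length_spectrum(motifs)
    grid = motif.position_grid(motifs, max_len=max_len)
    tally = motif.classify_function_content(chunk, stop)
    short, long_ = motif.short_long_counts(motifs)
    return {
        "motifs": motifs,
        "spectrum": spectrum,
        "lengths": lengths,
        "grid": grid,
        "tally": tally,
        "short": short,
        "long": long_,
    }


def _write_chunk_tables(out: Path, chunk_id: str, art: dict) -> None:
    safe = chunk_id.replace("#", "_")
    mot_rows = [
        {
            "chunk_id": chunk_id,
            "start": m.start,
            "length": len(m),
            "values": motif.motif_str(m.values),
            "words": " ".join(m.words) if m.words else "",
        }
        for m in art["motifs"]
    ]
    pd.DataFrame(mot_rows).to_csv(out / f"{safe}_motifs.tsv", sep="\t", index=False)
    spec_rows = [
        {"rank": i + 1, "motif": motif.motif_str(v), "frequency": f}
        for i, (v, f) in enumerate(art["spectrum"].entries)
    ]
    pd.DataFrame(spec_rows).to_csv(out / f"{safe}_spectrum.tsv", sep="\t", index=False)
    len_rows = [
        {"length": L, "count": c} for L, c in sorted(art["lengths"].counts.items())
    ]
    pd.DataFrame(len_rows).to_csv(out / f"{safe}_lengths.tsv", sep="\t", index=False)
    grid = art["grid"]
    pos_rows = [
        {
            "length": L,
            "position": p,
            "mean_freq": grid.mean_freq[(L, p)],
            "log10_mean_freq": grid.log10_mean_freq[(L, p)],
            "n_motifs": grid.n_motifs[L],
        }
        for (L, p) in sorted(grid.mean_freq)
    ]
    pd.DataFrame(pos_rows).to_csv(out / f"{safe}_positions.tsv", sep="\t", index=False)


def run_extract(config: RunConfig) -> pd.DataFrame:
    """Tokenize, chunk and motif-annotate every manifest document.

    Writes per-chunk motif/spectrum/length/position TSVs plus the base
    feature table; returns the feature table.  Raises RuntimeError if any
    chunk fails (failures are logged per chunk first).
    """
    out = _setup(config)
    manifest = corpus_io.read_manifest(config.manifest)
    docs = corpus_io.load_documents(manifest, base_dir=Path(config.manifest).parent)
    groups = {d.doc_id: d.group for d in docs}
    speakers = {d.doc_id: d.speaker_id for d in docs}
    token_seqs = [corpus_io.tokenize(d.text, d.doc_id) for d in docs]
    chunks = corpus_io.segment_corpus(token_seqs, config.target_size)
    if not chunks:
        raise RuntimeError("no chunks produced — empty corpus?")
    chunk_dir = out / "chunks"
    corpus_io.write_chunks(chunks, chunk_dir, groups)
    tdir = out / "tables"
    tdir.mkdir(exist_ok=True)
    stop = config.stoplist_set()
    rows = []
    failures = []
    for chunk in chunks:
        src = chunk.doc_id.split("#")[0]
        try:
            art = _chunk_artifacts(chunk, stop, config.max_position_len)
        except Exception as exc:  # noqa: BLE001 - per-chunk isolation
            log.error("chunk %s failed: %s", chunk.doc_id, exc)
            failures.append(chunk.doc_id)
            continue
        _write_chunk_tables(tdir, chunk.doc_id, art)
        row = {
            "chunk_id": chunk.doc_id,
            "group": groups.get(src, ""),
            "speaker_id": speakers.get(src),
            "token_count": len(chunk),
            "total_motifs": len(art["motifs"]),
            "short_count": art["short"],
            "long_count": art["long"],
            "function_count": art["tally"].function_count,
            "content_count": art["tally"].content_count,
        }
        for (L, p), v in sorted(art["grid"].mean_freq.items()):
            row[f"L{L}P{p}"] = v
        rows.append(row)
    features = pd.DataFrame(rows)
    features.to_csv(out / "features_base.tsv", sep="\t", index=False)
    if failures:
        raise RuntimeError(f"{len(failures)} chunk(s) failed: {failures}")
    return features


def _reload_chunks(out: Path) -> list[corpus_io.TokenSequence]:
    cm = pd.read_csv(out / "chunks" / "chunk_manifest.tsv", sep="\t")
    chunks = []
    for row in cm.itertuples(index=False):
        text = (out / "chunks" / row.path).read_text(encoding="utf-8")
        ts = corpus_io.tokenize(text, doc_id=row.chunk_id)
        chunks.append(ts)
    return chunks


def _report_dict(params: dict, report: distfit.FitReport, model: str, settings: dict) -> dict:
    return {
        "model": model,
        "params": params,
        "X2": report.X2,
        "p": report.p_X2,
        "df": report.df,
        "C": report.C,
        "R2": report.R2,
        "pooled_classes": report.pooled_classes,
        "converged": report.converged,
        "settings": settings,
    }


def run_fit(config: RunConfig) -> pd.DataFrame:
    """Fit ZM to each chunk spectrum (and pooled group spectra) and HP to
    each length spectrum; write JSON reports and the final feature table."""
    out = _setup(config)
    features = pd.read_csv(out / "features_base.tsv", sep="\t")
    chunks = _reload_chunks(out)
    fdir = out / "fits"
    fdir.mkdir(exist_ok=True)
    settings = {"criterion": "pearson_chisq", "optimizer": "nelder-mead"}
    for col in FEATURE_PARAMS + ["zm_R2", "hp_R2", "zm_converged", "hp_converged"]:
        features[col] = np.nan
    features = features.set_index("chunk_id")

    group_motifs: dict[str, list] = {}
    for chunk in chunks:
        art = None
        try:
            table = corpus_io.word_frequencies(chunk)
            values = motif.annotate_frequencies(chunk, table)
            motifs = motif.extract_fmotifs(values)
        except Exception as exc:  # noqa: BLE001
            log.error("fit: chunk %s unreadable: %s", chunk.doc_id, exc)
            continue
        grp = features.loc[chunk.doc_id, "group"] if chunk.doc_id in features.index else ""
        group_motifs.setdefault(str(grp), []).extend(motifs)
        safe = chunk.doc_id.replace("#", "_")
        if "zm" in config.models:
            try:
                spectrum = motif.rank_frequency_spectrum(motifs)
                params, report = distfit.fit_zm(spectrum)
                d = _report_dict(
                    {"a": params.a, "b": params.b, "n": params.n}, report, "zipf-mandelbrot", settings
                )
                (fdir / f"{safe}_zm.json").write_text(json.dumps(d, indent=1))
                features.loc[chunk.doc_id, ["a", "b", "zm_R2", "zm_converged"]] = [
                    params.a, params.b, report.R2, float(report.converged),
                ]
            except (distfit.InsufficientDataError, Exception) as exc:  # noqa: BLE001
                log.error("ZM fit failed for %s: %s", chunk.doc_id, exc)
        if "hp" in config.models:
            try:
                lengths = motif.length_spectrum(motifs)
                params, report = distfit.fit_hyperpascal(lengths)
                d = _report_dict(
                    {"k": params.k, "m": params.m, "q": params.q, "p0": params.p0},
                    report, "hyper-pascal", settings,
                )
                (fdir / f"{safe}_hp.json").write_text(json.dumps(d, indent=1))
                features.loc[chunk.doc_id, ["k", "m", "q", "hp_R2", "hp_converged"]] = [
                    params.k, params.m, params.q, report.R2, float(report.converged),
                ]
            except (distfit.InsufficientDataError, Exception) as exc:  # noqa: BLE001
                log.error("HP fit failed for %s: %s", chunk.doc_id, exc)

    # pooled per-group spectra
    for grp, motifs in group_motifs.items():
        if not motifs or "zm" not in config.models:
            continue
        try:
            spectrum = motif.rank_frequency_spectrum(motifs)
            params, report = distfit.fit_zm(spectrum)
            d = _report_dict(
                {"a": params.a, "b": params.b, "n": params.n}, report, "zipf-mandelbrot", settings
            )
            (fdir / f"group_{grp}_zm.json").write_text(json.dumps(d, indent=1))
        except Exception as exc:  # noqa: BLE001
            log.error("pooled ZM fit failed for group %s: %s", grp, exc)

    features = features.reset_index()
    features.to_csv(out / "features.tsv", sep="\t", index=False)
    return features


def features_frame(
    docs,
    *,
    target_size: int | None = None,
    models: tuple[str, ...] = ("zm", "hp"),
    stoplist: frozenset[str] | None = None,
    max_position_len: int = 7,
) -> pd.DataFrame:
    """Compute the per-chunk feature table in memory from RawDocuments.

    With ``target_size`` set, documents are chunked first; otherwise each
    document is treated as one chunk.  Failed fits leave NaN features
    (never zeros).
    """
    stop = DEFAULT_FUNCTION_WORDS if stoplist is None else stoplist
    seqs = [corpus_io.tokenize(d.text, d.doc_id) for d in docs]
    chunks = corpus_io.segment_corpus(seqs, target_size) if target_size else seqs
    meta = {d.doc_id: (d.group, d.speaker_id) for d in docs}
    rows = []
    for chunk in chunks:
        src = chunk.doc_id.split("#")[0]
        grp, spk = meta.get(src, ("", None))
        art = _chunk_artifacts(chunk, stop, max_position_len)
        row: dict = {
            "chunk_id": chunk.doc_id,
            "group": grp,
            "speaker_id": spk,
            "token_count": len(chunk),
            "total_motifs": len(art["motifs"]),
            "short_count": art["short"],
            "long_count": art["long"],
            "function_count": art["tally"].function_count,
            "content_count": art["tally"].content_count,
        }
        for p in FEATURE_PARAMS + ["zm_R2", "hp_R2"]:
            row[p] = np.nan
        if "zm" in models:
            try:
                params, report = distfit.fit_zm(art["spectrum"])
                row.update(a=params.a, b=params.b, zm_R2=report.R2)
            except Exception as exc:  # noqa: BLE001
                log.warning("ZM fit failed for %s: %s", chunk.doc_id, exc)
        if "hp" in models:
            try:
                params, report = distfit.fit_hyperpascal(art["lengths"])
                row.update(k=params.k, m=params.m, q=params.q, hp_R2=report.R2)
            except Exception as exc:  # noqa: BLE001
                log.warning("HP fit failed for %s: %s", chunk.doc_id, exc)
        for (L, p), v in sorted(art["grid"].mean_freq.items()):
            row[f"L{L}P{p}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def run_compare(config: RunConfig) -> stats_compare.ComparisonReport:
    """Run the declared comparison battery over the fitted feature table."""
    out = _setup(config)
    features = pd.read_csv(out / "features.tsv", sep="\t")
    design = config.design
    if design is None:
        groups = sorted(set(features["group"].dropna()))
        if len(groups) < 2:
            raise ValueError("comparison needs at least 2 groups in the feature table")
        design = {"groups": groups[:2]}
    report = stats_compare.compare_groups(features, design)
    frame = report.to_frame()
    frame.to_csv(out / "comparison.tsv", sep="\t", index=False)
    (out / "comparison.json").write_text(
        json.dumps(
            {
                "n_tests": report.n_tests,
                "n_flagged": report.n_flagged,
                "alpha": report.alpha,
                "skipped": report.skipped,
                "results": frame.to_dict(orient="records"),
            },
            indent=1,
            default=float,
        )
    )
    return report


def run_all(config: RunConfig) -> stats_compare.ComparisonReport:
    run_extract(config)
    run_fit(config)
    return run_compare(config)
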