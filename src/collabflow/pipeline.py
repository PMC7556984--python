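"""End-to-end analysis pipeline: corpus → tag selection → networks →
indices → exports, with a machine-readable run manifest.

The analyzed paper set is the tagged core plus the papers citing it —
the same corpus semantics as building a topic literature from a
bibliographic database (tagged papers and their incoming citations).
The pipeline is fully deterministic: identical inputs yield
byte-identical artifacts, and the manifest records input hashes and
stage counts so a run can be audited without re-execution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from . import corpus as corpus_io
from . import indices as indices_mod
from . import network_build as nb
from .errors import CollabflowError
from .network_build import (
    CollaborationGraph,
    KnowledgeFlowGraph,
    SelfCitationMode,
)


@dataclass(frozen=True)
class RunConfig:
    corpus_path: Path
    alias_path: Path
    sector_path: Path
    output_dir: Path
    self_citation_mode: SelfCitationMode = "shared_institution"
    exclude_self: bool = False
    top_k: int = 20
    share_threshold: float = 0.9

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 < self.share_threshold <= 1.0:
            raise ValueError("share_threshold must lie in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def top_k_edges(
    g: Union[CollaborationGraph, KnowledgeFlowGraph], k: int
) -> list[tuple[tuple[str, str], int]]:
    """The k highest-weight edges (weight descending, pair id ascending);
    all edges if fewer than k exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = g.weights if isinstance(g, CollaborationGraph) else g.flow
    return sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def rank_institutions(scores: dict[str, int], k: int) -> list[tuple[str, int]]:
    """Top-k institutions under a ranking score (weighted degree or paper
    count), descending, id-ascending tiebreak."""
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write all artifacts to
    ``cfg.output_dir``.

    Artifacts: collaboration/flow TSV edge lists, annual series CSVs
    with and without self-citation exclusion, index-report CSV, flow
    fractions CSV, top-k edge tables, and ``manifest.json``.  Returns
    the manifest; on stage failure the manifest (with the failing stage
    recorded) is still written before the error propagates.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {
            "corpus": {"path": str(cfg.corpus_path), "sha256": None},
            "aliases": {"path": str(cfg.alias_path), "sha256": None},
            "sectors": {"path": str(cfg.sector_path), "sha256": None},
        },
        "config": {
            "self_citation_mode": cfg.self_citation_mode,
            "exclude_self": cfg.exclude_self,
            "top_k": cfg.top_k,
            "share_threshold": cfg.share_threshold,
        },
        "counts": {},
        "warnings": [],
        "outputs": [],
        "failed_stage": None,
    }

    def _write_manifest():
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    stage = "read_inputs"
    try:
        for key, path in (
            ("corpus", cfg.corpus_path),
            ("aliases", cfg.alias_path),
            ("sectors", cfg.sector_path),
        ):
            manifest["inputs"][key]["sha256"] = _sha256(Path(path))
        corpus = corpus_io.read_corpus(cfg.corpus_path)
        query = corpus_io.read_tag_query(cfg.alias_path)
        sectors = corpus_io.load_sector_map(cfg.sector_path)
        if corpus.n_without_institutions:
            manifest["warnings"].append(
                f"{corpus.n_without_institutions} record(s) without "
                "institutional affiliations"
            )
        if corpus.dangling_refs:
            manifest["warnings"].append(
                f"{len(corpus.dangling_refs)} dangling reference id(s)"
            )

        stage = "select"
        core = corpus_io.select_tagged(corpus, query)
        if not core:
            raise CollabflowError(
                f"no papers matched tag query {query.canonical_name!r}"
            )
        pairs = corpus_io.collect_citations(corpus, core)
        analyzed = core | pairs.citing_ids()

        stage = "build_networks"
        g = nb.build_collaboration(corpus, analyzed)
        f = nb.build_flow(corpus, pairs)

        stage = "series"
        series_all = nb.annual_series(
            corpus, core, pairs, exclude_self=False
        )
        series_noself = nb.annual_series(
            corpus, core, pairs, exclude_self=True,
            mode=cfg.self_citation_mode,
        )

        stage = "indices"
        report = indices_mod.compile_index_report(
            corpus, analyzed, g, sectors, share=cfg.share_threshold
        )
        try:
            flow_frac = indices_mod.flow_fractions(f)
        except indices_mod.UndefinedIndexError:
            flow_frac = None
            manifest["warnings"].append(
                "zero total flow: flow fractions undefined"
            )

        stage = "export"
        nb.write_collaboration_edges(g, out / "collaboration_edges.tsv")
        nb.write_flow_edges(f, out / "flow_edges.tsv")
        nb.write_annual_series(series_all, out / "annual_series.csv")
        nb.write_annual_series(
            series_noself, out / "annual_series_no_self.csv"
        )
        indices_mod.write_index_reports([report], out / "index_report.csv")
        if flow_frac is not None:
            indices_mod.write_flow_fractions(
                flow_frac, out / "flow_fractions.csv"
            )
        with open(out / "top_edges.tsv", "w", encoding="utf-8") as fh:
            fh.write("kind\ta\tb\tweight\n")
            for (a, b), w in top_k_edges(g, cfg.top_k):
                fh.write(f"collaboration\t{a}\t{b}\t{w}\n")
            for (a, b), w in top_k_edges(f, cfg.top_k):
                fh.write(f"flow\t{a}\t{b}\t{w}\n")

        manifest["counts"] = {
            "corpus_papers": len(corpus),
            "core_papers": len(core),
            "analyzed_papers": len(analyzed),
            "citation_events": pairs.n_events,
            "citing_papers": pairs.n_citing_papers,
            "core_internal_citations": len(pairs.core_internal),
            "institutions": len(g.nodes),
            "collaboration_edges": g.n_edges,
            "collaboration_total_weight": g.total_weight,
            "flow_edges": f.n_edges,
            "flow_total_weight": f.total_flow,
        }
        manifest["outputs"] = sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        )
    except Exception:
        manifest["failed_stage"] = stage
        _write_manifest()
        raise
    _write_manifest()
    return manifest
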