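"""Projection of a corpus into institution-level networks.

Two projections are supported:

* the undirected **collaboration network**, where the weight of edge
  ``{i, j}`` counts the papers on which institutions *i* and *j*
  co-appear (one increment per paper per unordered institution pair, no
  matter how many author pairs span the two institutions);
* the directed **knowledge-flow network**, where the weight of edge
  ``u → v`` counts citation cases in which a paper affiliated with *v*
  cites a paper affiliated with *u* — knowledge moves from the cited
  institution toward the citing one.  Self-loops ``u → u`` are retained:
  within-institution flow is a quantity of interest in its own right.

The module also computes annual publication/citation series, with
optional exclusion of self-citations (shared-author or
shared-institution, the field never having settled on one definition).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple

import networkx as nx
import pandas as pd

from .corpus import CitationPairs, Corpus, PaperRecord
from .errors import IntegrityError, UnknownPaperError

SelfCitationMode = Literal["shared_author", "shared_institution"]

#: Default self-citation definition: institution overlap, consistent with
#: institution-level networks.
DEFAULT_SELF_CITATION_MODE: SelfCitationMode = "shared_institution"


@dataclass(frozen=True)
class CollaborationGraph:
    """Undirected institution graph with positive integer edge weights.

    Edge keys are sorted 2-tuples ``(i, j)`` with ``i < j``; self-loops
    are forbidden (within-institution collaboration is a property of
    paper-level author sets, not an edge).  Total weight conserves the
    number of co-publication cases: it equals the sum over projected
    papers of C(|institutions|, 2).
    """

    nodes: frozenset[str]
    weights: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        for (i, j), w in self.weights.items():
            if i >= j:
                raise IntegrityError(
                    f"edge key ({i!r}, {j!r}) must be a sorted distinct pair"
                )
            if i not in self.nodes or j not in self.nodes:
                raise IntegrityError(f"edge ({i!r}, {j!r}) endpoint not a node")
            if not isinstance(w, int) or w < 1:
                raise IntegrityError(f"edge ({i!r}, {j!r}) weight {w!r} not a positive integer")

    def weight(self, i: str, j: str) -> int:
        """Weight of edge {i, j}; 0 if absent."""
        key = (i, j) if i < j else (j, i)
        return self.weights.get(key, 0)

    @cached_property
    def adjacency(self) -> dict[str, dict[str, int]]:
        adj: dict[str, dict[str, int]] = {n: {} for n in self.nodes}
        for (i, j), w in self.weights.items():
            adj[i][j] = w
            adj[j][i] = w
        return adj

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            (i, j, w) for (i, j), w in self.weights.items()
        )
        return g


@dataclass(frozen=True)
class KnowledgeFlowGraph:
    """Directed institution graph; ``flow[(u, v)]`` counts citation cases
    where a paper affiliated with *v* cites a paper affiliated with *u*.
    Self-loops are permitted and carry the within-institution flow."""

    nodes: frozenset[str]
    flow: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        for (u, v), w in self.flow.items():
            if u not in self.nodes or v not in self.nodes:
                raise IntegrityError(f"flow edge ({u!r}, {v!r}) endpoint not a node")
            if not isinstance(w, int) or w < 1:
                raise IntegrityError(f"flow edge ({u!r}, {v!r}) weight {w!r} not a positive integer")

    def get(self, u: str, v: str) -> int:
        return self.flow.get((u, v), 0)

    @property
    def n_edges(self) -> int:
        return len(self.flow)

    @property
    def total_flow(self) -> int:
        return sum(self.flow.values())

    def out_flow(self, u: str) -> int:
        """Total flow disseminated by u (citations of u's papers)."""
        return sum(w for (a, _), w in self.flow.items() if a == u)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self.flow.items())
        return g


class YearCounts(NamedTuple):
    publications: int
    citations: int


@dataclass(frozen=True)
class AnnualSeries:
    """Per-year publication and citation counts."""

    counts: Mapping[int, YearCounts]

    def years(self) -> list[int]:
        return sorted(self.counts)

    def publications(self, year: int) -> int:
        return self.counts.get(year, YearCounts(0, 0)).publications

    def citations(self, year: int) -> int:
        return self.counts.get(year, YearCounts(0, 0)).citations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"year": y, "publications": c.publications, "citations": c.citations}
                for y, c in sorted(self.counts.items())
            ],
            columns=["year", "publications", "citations"],
        )


# ---------------------------------------------------------------------------
# Construction


def build_collaboration(
    corpus: Corpus, paper_ids: Iterable[str] | None = None
) -> CollaborationGraph:
    """Project papers onto the institutional collaboration network.

    Every unordered pair of distinct institutions in a paper's
    (deduplicated) institution set increments that pair's weight by
    exactly one.  Nodes are all institutions appearing on any selected
    paper; single-institution papers contribute a node but no edge.
    """
    ids = corpus.ids() if paper_ids is None else set(paper_ids)
    unknown = ids - corpus.ids()
    if unknown:
        raise UnknownPaperError(f"unknown paper id(s): {sorted(unknown)[:5]}")
    nodes: set[str] = set()
    weights: Counter[tuple[str, str]] = Counter()
    for pid in ids:
        insts = sorted(corpus[pid].institutions)
        nodes.update(insts)
        for pair in combinations(insts, 2):
            weights[pair] += 1
    return CollaborationGraph(frozenset(nodes), dict(weights))


def build_flow(
    corpus: Corpus, citation_pairs: Iterable[tuple[str, str]]
) -> KnowledgeFlowGraph:
    """Project citation events onto the knowledge-flow network.

    For each pair ``(citing, cited)``, each cited institution sends one
    unit of flow to each citing institution (cited → citing).  A pair
    whose citing or cited paper has no affiliations contributes nothing.
    """
    nodes: set[str] = set()
    flow: Counter[tuple[str, str]] = Counter()
    for citing_id, cited_id in citation_pairs:
        if citing_id not in corpus or cited_id not in corpus:
            raise UnknownPaperError(
                f"citation pair ({citing_id!r}, {cited_id!r}) references "
                "a paper absent from the corpus"
            )
        cited_insts = corpus[cited_id].institutions
        citing_insts = corpus[citing_id].institutions
        nodes.update(cited_insts)
        nodes.update(citing_insts)
        for u in cited_insts:
            for v in citing_insts:
                flow[(u, v)] += 1
    return KnowledgeFlowGraph(frozenset(nodes), dict(flow))


def is_self_citation(
    citing: PaperRecord,
    cited: PaperRecord,
    mode: SelfCitationMode = DEFAULT_SELF_CITATION_MODE,
) -> bool:
    """True iff citing and cited papers share an author
    (``shared_author``) or an institution (``shared_institution``)."""
    if mode == "shared_author":
        return bool(citing.authors & cited.authors)
    if mode == "shared_institution":
        return bool(citing.institutions & cited.institutions)
    raise ValueError(f"unknown self-citation mode {mode!r}")


def annual_series(
    corpus: Corpus,
    core_ids: Iterable[str],
    citation_pairs: Iterable[tuple[str, str]],
    exclude_self: bool = False,
    mode: SelfCitationMode = DEFAULT_SELF_CITATION_MODE,
) -> AnnualSeries:
    """Annual publication counts of the core papers and annual citation
    counts of the citation pairs.

    A citation is dated by the CITING paper's year — the year the
    citation accrues.  With ``exclude_self`` set, pairs that are
    self-citations under ``mode`` are dropped from the citation counts
    (publication counts are unaffected).
    """
    pubs: Counter[int] = Counter()
    cites: Counter[int] = Counter()
    for pid in core_ids:
        pubs[corpus[pid].year] += 1
    for citing_id, cited_id in citation_pairs:
        citing = corpus[citing_id]
        if exclude_self and is_self_citation(citing, corpus[cited_id], mode):
            continue
        cites[citing.year] += 1
    return AnnualSeries(
        {
            y: YearCounts(pubs.get(y, 0), cites.get(y, 0))
            for y in set(pubs) | set(cites)
        }
    )


# ---------------------------------------------------------------------------
# Exports


def write_collaboration_edges(g: CollaborationGraph, path: str | Path) -> None:
    """TSV edge list ``inst_a<TAB>inst_b<TAB>weight``, weight descending
    then pair lexicographic; pairs themselves are sorted."""
    rows = sorted(g.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["inst_a", "inst_b", "weight"])
        for (i, j), w in rows:
            writer.writerow([i, j, w])


def write_flow_edges(f: KnowledgeFlowGraph, path: str | Path) -> None:
    """TSV edge list ``from<TAB>to<TAB>weight`` (cited → citing), weight
    descending then pair lexicographic."""
    rows = sorted(f.flow.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["from", "to", "weight"])
        for (u, v), w in rows:
            writer.writerow([u, v, w])


def write_annual_series(series: AnnualSeries, path: str | Path) -> None:
    """CSV ``year,publications,citations`` sorted by year."""
    series.to_frame().to_csv(path, index=False)
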