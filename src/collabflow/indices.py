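"""Network indices for institutional collaboration and flow networks.

All indices are defined on the whole weighted collaboration network:

* **weighted degree** s_i = Σ_j w_ij, the collaboration strength of an
  institution summed over its partners;
* **industrial participation** — the fraction of total edge weight on
  edges with at least one corporate endpoint (each qualifying edge
  counted once, even when both endpoints are corporate, so the fraction
  stays in [0, 1]);
* **average clustering** — the weighted clustering coefficient built on
  the geometric average of subgraph (triangle) edge weights, normalized
  by the graph's maximum edge weight; nodes with fewer than two
  neighbors contribute 0 and are included in the average;
* **assortativity** — the Pearson correlation of weighted degrees across
  the two endpoints of each edge (edges enter once, symmetrized, and are
  not weight-sampled); negative values mean hubs link to low-degree
  institutions;
* **top-share fraction** — the minimal fraction of highest-weighted-degree
  institutions whose degrees cumulate to a given share (default 90%) of
  the network's total weighted degree: a Lorenz-style concentration
  measure of how much a few institutions dominate.

For the directed flow network, the internal-dissemination fractions
quantify how much of the knowledge an institution spreads (citations of
its papers) is generated by the institution itself (the self-loop flow).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .corpus import Corpus, SectorMap
from .errors import UndefinedIndexError
from .network_build import CollaborationGraph, KnowledgeFlowGraph


@dataclass(frozen=True)
class IndexReport:
    """One row of the per-corpus summary table.

    Indices that are undefined for the network at hand (e.g. on an
    edgeless graph) are ``None`` and exported as empty cells, never
    coerced to 0.
    """

    n_papers: int
    n_authors: int
    n_institutions: int
    frac_inter_institutional: float | None
    frac_industrial: float | None
    avg_clustering: float | None
    assortativity: float | None
    frac_top_90: float | None


@dataclass(frozen=True)
class FlowFractions:
    """Within-institution knowledge-flow summary.

    ``overall_internal`` is the fraction of total citation flow on
    self-loops.  ``per_institution_internal[u]`` is self-loop flow over
    u's total out-flow: the share of citations of u's papers that u
    itself generates.  Institutions with zero out-flow are omitted.
    """

    overall_internal: float
    per_institution_internal: Mapping[str, float]


# ---------------------------------------------------------------------------
# Collaboration-network indices


def weighted_degree(g: CollaborationGraph, institution: str) -> int:
    """s_i = Σ_j w_ij; 0 for isolated nodes."""
    if institution not in g.nodes:
        raise KeyError(institution)
    return sum(g.adjacency[institution].values())


def all_weighted_degrees(g: CollaborationGraph) -> dict[str, int]:
    return {n: sum(nbrs.values()) for n, nbrs in g.adjacency.items()}


def industrial_fraction(g: CollaborationGraph, sectors: SectorMap) -> float:
    """Fraction of collaboration weight on edges touching a corporate
    institution: (Σ_{i or j corporate} w_ij) / (Σ w_ij), each edge summed
    once in both numerator and denominator."""
    total = g.total_weight
    if total == 0:
        raise UndefinedIndexError(
            "industrial participation is undefined on an edgeless graph"
        )
    corporate = sum(
        w
        for (i, j), w in g.weights.items()
        if sectors.is_industrial(i) or sectors.is_industrial(j)
    )
    return corporate / total


def average_clustering(g: CollaborationGraph) -> float:
    """Weighted average clustering coefficient.

    With edge weights normalized by the graph maximum, ŵ = w / max(w),
    each node's coefficient is

        C_i = (1 / (k_i (k_i − 1))) Σ_{j,k} (ŵ_ij ŵ_ik ŵ_jk)^{1/3}

    summed over ordered neighbor pairs; nodes with degree < 2 have
    C_i = 0 and are included in the unweighted mean over all nodes.
    Invariant under uniform scaling of all weights.
    """
    if not g.nodes:
        raise UndefinedIndexError("clustering is undefined on an empty graph")
    if not g.weights:
        raise UndefinedIndexError(
            "clustering normalization is undefined without edges"
        )
    nodes = sorted(g.nodes)
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    wmax = max(g.weights.values())
    # Cube roots once; the triangle term factorizes over the three edges.
    w = np.zeros((n, n))
    for (i, j), wt in g.weights.items():
        w[index[i], index[j]] = w[index[j], index[i]] = np.cbrt(wt / wmax)
    triangle_sum = np.diagonal(w @ w @ w).copy()
    degree = (w > 0).sum(axis=1)
    coeff = np.zeros(n)
    mask = degree >= 2
    coeff[mask] = triangle_sum[mask] / (degree[mask] * (degree[mask] - 1))
    return float(coeff.mean())


def assortativity(g: CollaborationGraph) -> float | None:
    """Pearson correlation of weighted degree between the two endpoints
    of each edge, enumerated symmetrically (each edge contributes the
    ordered pairs (s_i, s_j) and (s_j, s_i)).

    Returns ``None`` when undefined: no edges, or zero variance in
    endpoint degrees (e.g. a regular ring) — not-applicable, not 0.
    """
    if not g.weights:
        return None
    s = all_weighted_degrees(g)
    x = np.empty(2 * len(g.weights))
    y = np.empty(2 * len(g.weights))
    for k, (i, j) in enumerate(g.weights):
        x[2 * k], y[2 * k] = s[i], s[j]
        x[2 * k + 1], y[2 * k + 1] = s[j], s[i]
    dx = x - x.mean()
    dy = y - y.mean()
    vx = float(dx @ dx)
    vy = float(dy @ dy)
    if vx <= 0 or vy <= 0:
        return None
    return float((dx @ dy) / math.sqrt(vx * vy))


def top_share_fraction(g: CollaborationGraph, share: float = 0.9) -> float:
    """Minimal fraction of top institutions (by weighted degree,
    descending, ties broken by institution id) whose cumulative degree
    reaches ``share`` of the total; the denominator counts all nodes,
    isolated ones included.

    The threshold comparison is carried out in exact rational arithmetic
    so integer degree sums sitting exactly on the boundary are ranked in,
    never lost to float rounding.
    """
    if not g.nodes:
        raise UndefinedIndexError("top-share is undefined on an empty graph")
    degrees = all_weighted_degrees(g)
    total = sum(degrees.values())
    if total == 0:
        raise UndefinedIndexError(
            "top-share is undefined with zero total degree"
        )
    threshold = Fraction(share).limit_denominator(10**9) * total
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    cumulative = 0
    for m, (_, d) in enumerate(ranked, start=1):
        cumulative += d
        if cumulative >= threshold:
            return m / len(degrees)
    return 1.0


# ---------------------------------------------------------------------------
# Flow-network and corpus-level indices


def flow_fractions(f: KnowledgeFlowGraph) -> FlowFractions:
    """Within-institution flow fractions of a knowledge-flow network."""
    total = f.total_flow
    if total == 0:
        raise UndefinedIndexError(
            "flow fractions are undefined with zero total flow"
        )
    internal = sum(w for (u, v), w in f.flow.items() if u == v)
    out: dict[str, int] = {}
    for (u, _), w in f.flow.items():
        out[u] = out.get(u, 0) + w
    per_inst = {
        u: f.flow.get((u, u), 0) / out_u for u, out_u in out.items()
    }
    return FlowFractions(internal / total, per_inst)


def inter_institutional_fraction(
    corpus: Corpus, paper_ids: Iterable[str]
) -> float:
    """Fraction of selected papers whose institution set has size ≥ 2.

    Papers with empty institution sets count in the denominator: a paper
    with no resolved affiliations is not an inter-institutional one.
    """
    ids = list(paper_ids)
    if not ids:
        raise UndefinedIndexError(
            "inter-institutional fraction is undefined for an empty selection"
        )
    multi = sum(1 for pid in ids if len(corpus[pid].institutions) >= 2)
    return multi / len(ids)


def author_count(corpus: Corpus, paper_ids: Iterable[str]) -> int:
    """Number of distinct author ids over a paper selection (usable for
    the core papers alone or core plus citing papers)."""
    authors: set[str] = set()
    for pid in paper_ids:
        authors.update(corpus[pid].authors)
    return len(authors)


def compile_index_report(
    corpus: Corpus,
    paper_ids: Iterable[str],
    g: CollaborationGraph,
    sectors: SectorMap,
    share: float = 0.9,
) -> IndexReport:
    """Assemble one summary row from the index operations above.

    Indices undefined for the supplied network carry ``None``.
    """
    ids = set(paper_ids)

    def _try(fn):
        try:
            return fn()
        except UndefinedIndexError:
            return None

    return IndexReport(
        n_papers=len(ids),
        n_authors=author_count(corpus, ids),
        n_institutions=len(g.nodes),
        frac_inter_institutional=_try(
            lambda: inter_institutional_fraction(corpus, ids)
        ),
        frac_industrial=_try(lambda: industrial_fraction(g, sectors)),
        avg_clustering=_try(lambda: average_clustering(g)),
        assortativity=assortativity(g),
        frac_top_90=_try(lambda: top_share_fraction(g, share)),
    )


# ---------------------------------------------------------------------------
# Exports

_REPORT_COLUMNS = (
    "papers",
    "authors",
    "institutions",
    "frac_inter_institutional",
    "frac_industrial",
    "avg_clustering",
    "assortativity",
    "frac_top_90",
)


def write_index_reports(
    reports: Iterable[IndexReport], path: str | Path
) -> None:
    """CSV with one row per analyzed corpus; undefined indices are empty
    cells."""

    def cell(v):
        return "" if v is None else v

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REPORT_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    r.n_papers,
                    r.n_authors,
                    r.n_institutions,
                    cell(r.frac_inter_institutional),
                    cell(r.frac_industrial),
                    cell(r.avg_clustering),
                    cell(r.assortativity),
                    cell(r.frac_top_90),
                ]
            )


def write_flow_fractions(ff: FlowFractions, path: str | Path) -> None:
    """CSV ``institution,internal_fraction`` preceded by a one-line
    overall summary comment."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# overall_internal,{ff.overall_internal!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["institution", "internal_fraction"])
        for inst in sorted(ff.per_institution_internal):
            writer.writerow([inst, repr(ff.per_institution_internal[inst])])
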