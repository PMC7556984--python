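"""Shared fixtures: the worked-example corpus, random corpus/graph
factories, and naive reference implementations used as oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from collabflow import (
    CollaborationGraph,
    Corpus,
    GeneratorConfig,
    PaperRecord,
    SectorMap,
    fig1_corpus,
    generate_corpus,
)


@pytest.fixture
def fig1():
    return fig1_corpus()


@pytest.fixture
def fig1_collab_sectors():
    """Sector map for the worked example: institution c corporate."""
    return SectorMap({"c": "industrial", "a": "academic", "b": "academic",
                      "d": "academic", "e": "academic"})


def make_random_corpus(seed: int, n_papers: int = 120, n_inst: int = 40) -> Corpus:
    """Small synthetic corpus for property tests."""
    return generate_corpus(
        GeneratorConfig(
            n_institutions=n_inst,
            n_papers=n_papers,
            year_range=(2000, 2010),
            seed=seed,
        )
    )


def make_random_graph(rng: np.random.Generator, max_n: int = 12) -> CollaborationGraph:
    """Random weighted collaboration graph with up to ``max_n`` nodes."""
    n = int(rng.integers(2, max_n + 1))
    nodes = [f"i{k:02d}" for k in range(n)]
    weights = {}
    for i, j in itertools.combinations(nodes, 2):
        if rng.random() < 0.45:
            weights[(i, j)] = int(rng.integers(1, 10))
    return CollaborationGraph(frozenset(nodes), weights)


def make_record(pid: str, year: int = 2005, insts=(), authors=(), refs=(), tags=()) -> PaperRecord:
    return PaperRecord(
        paper_id=pid,
        year=year,
        institutions=frozenset(insts),
        authors=frozenset(authors),
        references=frozenset(refs),
        tags=frozenset(tags),
    )


# ---------------------------------------------------------------------------
# Naive reference implementations (kept deliberately simple-minded)


def clustering_oracle(g: CollaborationGraph) -> float:
    """Per-node triple loop over ordered neighbor pairs, geometric mean
    of normalized triangle edge weights."""
    wmax = max(g.weights.values())
    total = 0.0
    for node in g.nodes:
        nbrs = sorted(g.adjacency[node])
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j in nbrs:
            for l in nbrs:
                if j == l:
                    continue
                wjl = g.weight(j, l)
                if wjl == 0:
                    continue
                s += (
                    (g.weight(node, j) / wmax)
                    * (g.weight(node, l) / wmax)
                    * (wjl / wmax)
                ) ** (1.0 / 3.0)
        total += s / (k * (k - 1))
    return total / len(g.nodes)


def assortativity_oracle(g: CollaborationGraph):
    """Pearson over the explicitly materialized symmetric endpoint-degree
    pair list, via numpy's correlation matrix."""
    degrees = {n: sum(g.adjacency[n].values()) for n in g.nodes}
    xs, ys = [], []
    for i, j in g.weights:
        xs += [degrees[i], degrees[j]]
        ys += [degrees[j], degrees[i]]
    if not xs:
        return None
    x, y = np.asarray(xs, float), np.asarray(ys, float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
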