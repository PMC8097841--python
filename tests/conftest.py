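"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own BFS primitives:
distances are checked against exhaustive simple-path enumeration and
supportedness against per-vertex connectivity queries on an induced
subgraph, both via networkx.
"""

from __future__ import annotations

import random
from typing import Dict, Optional, Set, Tuple

import networkx as nx
import pytest

from binrefine.graph import ContigGraph, Labelling, RefinerConfig
from binrefine.datasets import worked_example


@pytest.fixture
def example():
    return worked_example()


@pytest.fixture
def config():
    return RefinerConfig()


def path_graph(*vertices: str, coverages=None) -> ContigGraph:
    """A simple path contig graph for hand-built scenarios."""
    edges = list(zip(vertices, vertices[1:]))
    return ContigGraph.from_edges(
        edges, coverages=coverages or {}, vertices=vertices,
        lengths={v: 1000 for v in vertices},
    )


def random_contig_graph(
    rng: random.Random,
    n_max: int = 25,
    labels: Tuple[str, ...] = ("red", "green", "blue"),
    label_prob: float = 0.5,
) -> Tuple[ContigGraph, Labelling]:
    """A random Erdos-Renyi contig graph with a random partial labelling."""
    n = rng.randint(2, n_max)
    p = rng.uniform(0.05, 0.3)
    gx = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
    g = ContigGraph()
    for v in gx.nodes:
        g.add_vertex(str(v), length=rng.randint(1, 5000),
                     coverage=rng.uniform(0, 200))
    for u, v in gx.edges:
        g.add_edge(str(u), str(v))
    lab = Labelling()
    for v in gx.nodes:
        if rng.random() < label_prob:
            lab.assign(str(v), rng.choice(labels))
    return g, lab


def oracle_unlabelled_distance(
    g: ContigGraph, lab: Labelling, v: str, t: str, cap: Optional[int] = None
):
    """Exhaustive-enumeration D(v, t): min edges over simple paths whose
    interior vertices are all unlabelled."""
    gx = nx.Graph()
    gx.add_nodes_from(g.vertices)
    gx.add_edges_from(tuple(e) for e in g.edges)
    best = None
    limit = cap if cap is not None else len(g)
    for path in nx.all_simple_paths(gx, v, t, cutoff=limit):
        if all(not lab.is_labelled(w) for w in path[1:-1]):
            d = len(path) - 1
            if best is None or d < best:
                best = d
    if best is None or (cap is not None and best > cap):
        return "unreachable"
    return best


def oracle_is_supported(g: ContigGraph, lab: Labelling, v: str) -> bool:
    """Per-vertex connectivity oracle for the unsupported-label rule."""
    if g.degree(v) == 0:
        return True
    x = lab.label_of(v)
    same = {t for t in lab.labelled if t != v and x in lab.labels(t) and t in g}
    if not same:
        return False
    gx = nx.Graph()
    keep = {w for w in g.vertices if not lab.is_labelled(w)} | {v} | same
    gx.add_nodes_from(keep)
    gx.add_edges_from(
        tuple(e) for e in g.edges if set(e) <= keep
    )
    return any(nx.has_path(gx, v, t) for t in same)


def oracle_subset_sum(candidates: Dict[str, float], target: float):
    """Independent subset-sum enumeration (bitmask loop, not itertools)."""
    ids = sorted(candidates)
    best_key = None
    best_subset = None
    for mask in range(2 ** len(ids)):
        subset = tuple(ids[i] for i in range(len(ids)) if mask >> i & 1)
        s = sum(candidates[c] for c in subset)
        key = (abs(s - target), len(subset), subset)
        if best_key is None or key < best_key:
            best_key = key
            best_subset = subset
    return frozenset(best_subset)
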