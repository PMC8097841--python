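"""Contig-graph data model and breadth-first-search primitives.

The assembly graph is treated as an undirected graph whose vertices are
contigs.  Every refinement rule in this package is phrased in terms of
*unlabelled-interior* paths: paths between two contigs whose interior
vertices carry no bin label.  This module provides the container types
(:class:`ContigGraph`, :class:`Labelling`, :class:`RefinerConfig`) and the
two BFS primitives built on that notion — shortest unlabelled-interior
distances and connected components of the unlabelled subgraph.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

import networkx as nx

#: Sentinel returned when no qualifying path exists.  Kept as an explicit
#: object (never a large number) so that 2**(-D) contributions of
#: unreachable vertices are exactly zero, not merely tiny.
UNREACHABLE = "unreachable"


class ContigGraph:
    """Undirected graph of contigs with per-vertex length and coverage.

    Vertices are opaque contig-id strings.  ``length(v)`` is the contig
    length in bases (>= 1) and ``coverage(v)`` the mean number of reads
    covering each base (>= 0).  Self-loops are dropped and duplicate edges
    collapsed on construction.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------

    def add_vertex(
        self,
        v: str,
        length: int = 1,
        coverage: Optional[float] = None,
    ) -> None:
        if length < 1:
            raise ValueError(f"length of contig {v!r} must be >= 1, got {length}")
        if coverage is not None and coverage < 0:
            raise ValueError(f"coverage of contig {v!r} must be >= 0, got {coverage}")
        self._g.add_node(str(v), length=int(length), coverage=coverage)

    def add_edge(self, u: str, v: str) -> None:
        u, v = str(u), str(v)
        if u == v:  # self-loops carry no connectivity information
            return
        for w in (u, v):
            if w not in self._g:
                raise KeyError(f"edge endpoint {w!r} is not a vertex")
        self._g.add_edge(u, v)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        lengths: Optional[Mapping[str, int]] = None,
        coverages: Optional[Mapping[str, float]] = None,
        vertices: Iterable[str] = (),
    ) -> "ContigGraph":
        g = cls()
        edges = list(edges)
        lengths = dict(lengths or {})
        coverages = dict(coverages or {})
        seen: Set[str] = set()
        for v in list(vertices) + [w for e in edges for w in e]:
            v = str(v)
            if v not in seen:
                seen.add(v)
                g.add_vertex(v, lengths.get(v, 1), coverages.get(v))
        for u, v in edges:
            g.add_edge(str(u), str(v))
        return g

    def set_coverage(self, v: str, coverage: float) -> None:
        if coverage < 0:
            raise ValueError(f"coverage of contig {v!r} must be >= 0")
        self._check(v)
        self._g.nodes[v]["coverage"] = float(coverage)

    def set_length(self, v: str, length: int) -> None:
        if length < 1:
            raise ValueError(f"length of contig {v!r} must be >= 1")
        self._check(v)
        self._g.nodes[v]["length"] = int(length)

    # -- queries -------------------------------------------------------

    def _check(self, v: str) -> None:
        if v not in self._g:
            raise KeyError(f"unknown contig id {v!r}")

    @property
    def vertices(self) -> Set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> Set[FrozenSet[str]]:
        return {frozenset(e) for e in self._g.edges}

    def __contains__(self, v: str) -> bool:
        return v in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def neighbors(self, v: str) -> Set[str]:
        self._check(v)
        return set(self._g[v])

    def degree(self, v: str) -> int:
        self._check(v)
        return self._g.degree[v]

    def length(self, v: str) -> int:
        self._check(v)
        return self._g.nodes[v]["length"]

    def coverage(self, v: str) -> float:
        self._check(v)
        c = self._g.nodes[v]["coverage"]
        if c is None:
            raise ValueError(f"contig {v!r} has no coverage assigned")
        return c

    def has_coverage(self, v: str) -> bool:
        self._check(v)
        return self._g.nodes[v]["coverage"] is not None

    def missing_coverage(self) -> List[str]:
        return sorted(v for v in self._g if self._g.nodes[v]["coverage"] is None)

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying :class:`networkx.Graph`."""
        return self._g.copy()


class Labelling:
    """Partial assignment of bin labels to contigs.

    Each contig maps to a *set* of bin labels.  Input binnings assign at
    most one label per contig; multi-bin inference may later grow a
    contig's set beyond one.
    """

    def __init__(self, labels: Optional[Mapping[str, Iterable[str]]] = None) -> None:
        self._labels: Dict[str, Set[str]] = {}
        if labels:
            for v, ls in labels.items():
                ls = {str(x) for x in (ls if not isinstance(ls, str) else [ls])}
                if ls:
                    self._labels[str(v)] = ls

    @classmethod
    def from_single(cls, assignment: Mapping[str, str]) -> "Labelling":
        return cls({v: {x} for v, x in assignment.items()})

    def copy(self) -> "Labelling":
        return Labelling({v: set(ls) for v, ls in self._labels.items()})

    def labels(self, v: str) -> FrozenSet[str]:
        return frozenset(self._labels.get(v, ()))

    def is_labelled(self, v: str) -> bool:
        return bool(self._labels.get(v))

    def label_of(self, v: str) -> str:
        """The single label of ``v``; error if unlabelled or multi-labelled."""
        ls = self._labels.get(v)
        if not ls:
            raise KeyError(f"contig {v!r} is unlabelled")
        if len(ls) > 1:
            raise ValueError(f"contig {v!r} carries multiple labels {sorted(ls)}")
        return next(iter(ls))

    def assign(self, v: str, label: str) -> None:
        self._labels.setdefault(v, set()).add(label)

    def set_labels(self, v: str, labels: Iterable[str]) -> None:
        ls = set(labels)
        if ls:
            self._labels[v] = ls
        else:
            self._labels.pop(v, None)

    def remove(self, v: str) -> None:
        self._labels.pop(v, None)

    @property
    def labelled(self) -> Set[str]:
        return {v for v, ls in self._labels.items() if ls}

    def unlabelled(self, g: ContigGraph) -> Set[str]:
        return {v for v in g if not self.is_labelled(v)}

    @property
    def bin_ids(self) -> Set[str]:
        return {x for ls in self._labels.values() for x in ls}

    def is_overlapped(self) -> bool:
        return any(len(ls) > 1 for ls in self._labels.values())

    def as_dict(self) -> Dict[str, FrozenSet[str]]:
        return {v: frozenset(ls) for v, ls in self._labels.items() if ls}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Labelling):
            return NotImplemented
        return self.as_dict() == other.as_dict()

    def __repr__(self) -> str:
        return f"Labelling({len(self.labelled)} labelled, {len(self.bin_ids)} bins)"


@dataclass(frozen=True)
class RefinerConfig:
    """Tunable parameters of the refinement pipeline.

    alpha
        Inconsistency factor: a labelled vertex is corrected when
        ``alpha * S(v, own) <= S(v, other)``.  Must exceed 1.
    bfs_depth_cap
        Depth limit for the unlabelled-interior BFS used when scoring and
        propagating labels (component detection in the unsupported-label
        step is uncapped).
    max_components_for_subset
        Largest number of adjacent foreign components for which the
        subset-sum enumeration is attempted during multi-bin inference.
    threads
        Worker count accepted for interface compatibility; results are
        required to be independent of it.
    """

    alpha: float = 1.5
    bfs_depth_cap: int = 5
    max_components_for_subset: int = 4
    threads: int = 8

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.bfs_depth_cap < 1:
            raise ValueError("bfs_depth_cap must be >= 1")
        if self.max_components_for_subset < 1:
            raise ValueError("max_components_for_subset must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


# ---------------------------------------------------------------------------
# BFS primitives
# ---------------------------------------------------------------------------


def labelled_within(
    g: ContigGraph,
    lab: Labelling,
    v: str,
    cap: Optional[int] = None,
) -> Dict[str, int]:
    """Shortest unlabelled-interior distances from ``v`` to labelled vertices.

    Returns a map ``t -> D(v, t)`` over every labelled vertex ``t != v``
    that is adjacent to ``v`` (distance 1) or joined to it by a path whose
    interior vertices are all unlabelled, with ``D <= cap`` when a cap is
    given.  Distance counts edges.  A single BFS that expands only through
    unlabelled vertices: labelled vertices are absorbed as endpoints and
    never expanded.
    """
    if v not in g:
        raise KeyError(f"unknown contig id {v!r}")
    out: Dict[str, int] = {}
    seen: Set[str] = {v}
    frontier = deque([(v, 0)])
    while frontier:
        u, d = frontier.popleft()
        if cap is not None and d >= cap:
            continue
        for w in g.neighbors(u):
            if w in seen:
                continue
            seen.add(w)
            if lab.is_labelled(w):
                out[w] = d + 1
            else:
                frontier.append((w, d + 1))
    return out


def unlabelled_distance(
    g: ContigGraph,
    lab: Labelling,
    v: str,
    t: str,
    cap: Optional[int] = None,
):
    """D(v, t): edges on the shortest path v..t with all-unlabelled interior.

    Returns :data:`UNREACHABLE` when no such path of length <= ``cap``
    exists.  Adjacent vertices are at distance 1 regardless of labels.
    """
    for w in (v, t):
        if w not in g:
            raise KeyError(f"unknown contig id {w!r}")
    if v == t:
        raise ValueError("v and t must differ")
    if t in g.neighbors(v):
        return 1
    # BFS through unlabelled interiors only; t is a valid endpoint whether
    # labelled or not.
    seen: Set[str] = {v}
    frontier = deque([(v, 0)])
    while frontier:
        u, d = frontier.popleft()
        if cap is not None and d >= cap:
            continue
        for w in g.neighbors(u):
            if w in seen:
                continue
            if w == t:
                return d + 1
            seen.add(w)
            if not lab.is_labelled(w):
                frontier.append((w, d + 1))
    return UNREACHABLE


@dataclass
class UnlabelledComponent:
    """A maximal connected set of unlabelled vertices plus its labelled rim."""

    members: FrozenSet[str]
    labelled_neighbours: FrozenSet[str] = field(default_factory=frozenset)


def unlabelled_components(g: ContigGraph, lab: Labelling) -> List[UnlabelledComponent]:
    """Connected components of the unlabelled subgraph.

    Each component comes with ``labelled_neighbours``: the labelled
    vertices adjacent to at least one member.  Components are maximal,
    disjoint, cover exactly the unlabelled vertices, and are returned in a
    canonical order (sorted by smallest member id) so the output does not
    depend on vertex iteration order.
    """
    unvisited = {v for v in g if not lab.is_labelled(v)}
    comps: List[UnlabelledComponent] = []
    while unvisited:
        start = next(iter(unvisited))
        members: Set[str] = {start}
        rim: Set[str] = set()
        queue = deque([start])
        unvisited.discard(start)
        while queue:
            u = queue.popleft()
            for w in g.neighbors(u):
                if lab.is_labelled(w):
                    rim.add(w)
                elif w in unvisited:
                    unvisited.discard(w)
                    members.add(w)
                    queue.append(w)
        comps.append(UnlabelledComponent(frozenset(members), frozenset(rim)))
    comps.sort(key=lambda c: min(c.members))
    return comps
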