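"""The four-stage bin-refinement algorithm.

Given an assembly graph whose vertices are contigs (with length and
coverage) and an initial, possibly incomplete and partly wrong, one-bin-
per-contig labelling, the pipeline

1. removes labels that are *unsupported* by graph connectivity,
2. corrects labels that are *inconsistent* with the labelled score
   ``S(v, x) = sum over label-x vertices t of 2**(-D(v, t))``,
3. propagates labels to unlabelled contigs by repeatedly executing the
   minimal candidate action ``(D(v,t), |c(v)-c(t)|, t, v)``, and
4. infers contigs shared by several genomes: a contig whose coverage
   exceeds its own component's length-weighted average may additionally
   receive the labels of adjacent foreign components whose averages best
   explain the excess (an exhaustive subset-sum decomposition).

Steps 1, 2 and 4 evaluate all decisions against a snapshot of the
labelling at step entry and apply them simultaneously, so their results do
not depend on vertex iteration order or on any parallel schedule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .graph import (
    ContigGraph,
    Labelling,
    RefinerConfig,
    labelled_within,
    unlabelled_components,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Step 1 — remove unsupported labels
# ---------------------------------------------------------------------------


def is_supported(g: ContigGraph, lab: Labelling, v: str) -> bool:
    """Whether labelled vertex ``v`` is backed up by a same-label vertex.

    ``v`` is supported iff it is isolated, directly adjacent to a vertex of
    the same label, or joined to one by a path whose interior vertices are
    all unlabelled (no depth cap).
    """
    if not lab.is_labelled(v):
        raise ValueError(f"contig {v!r} is unlabelled")
    x = lab.label_of(v)
    if g.degree(v) == 0:
        return True
    for t, _d in labelled_within(g, lab, v, cap=None).items():
        if x in lab.labels(t):
            return True
    return False


def step1_remove_unsupported(g: ContigGraph, lab: Labelling) -> Labelling:
    """Drop the label of every unsupported vertex.

    Uses the component-based detection rather than one BFS per labelled
    vertex: a labelled vertex is supported when it is isolated, adjacent to
    a same-label vertex, or when another vertex of its label borders the
    same all-unlabelled component.  Support is judged against the input
    labelling and all removals are applied at once.
    """
    supported: Set[str] = set()
    for v in lab.labelled:
        if v not in g:
            continue
        if g.degree(v) == 0:
            supported.add(v)
            continue
        x = lab.label_of(v)
        if any(x in lab.labels(w) for w in g.neighbors(v)):
            supported.add(v)
    for comp in unlabelled_components(g, lab):
        by_label: Dict[str, List[str]] = {}
        for t in comp.labelled_neighbours:
            by_label.setdefault(lab.label_of(t), []).append(t)
        for ts in by_label.values():
            if len(ts) > 1:
                supported.update(ts)
    out = lab.copy()
    removed = [v for v in lab.labelled if v in g and v not in supported]
    for v in removed:
        out.remove(v)
    logger.info("step1: removed %d unsupported label(s)", len(removed))
    return out


# ---------------------------------------------------------------------------
# Step 2 — correct inconsistent labels
# ---------------------------------------------------------------------------


def label_scores(
    g: ContigGraph,
    lab: Labelling,
    v: str,
    cap: Optional[int],
) -> Dict[str, float]:
    """All labelled scores S(v, .) in one BFS.

    Every labelled vertex ``t`` adjacent to ``v`` or reachable through an
    all-unlabelled interior within the depth cap contributes ``2**(-D)``
    to the score of its label, through its shortest such distance.
    """
    scores: Dict[str, float] = {}
    for t, d in labelled_within(g, lab, v, cap).items():
        x = lab.label_of(t)
        scores[x] = scores.get(x, 0.0) + 2.0 ** (-d)
    return scores


def labelled_score(
    g: ContigGraph,
    lab: Labelling,
    v: str,
    x: str,
    cap: Optional[int] = None,
) -> float:
    """S(v, x): summed 2**(-D) contributions of label-x vertices near v."""
    return label_scores(g, lab, v, cap).get(x, 0.0)


def step2_correct_inconsistent(
    g: ContigGraph, lab: Labelling, cfg: RefinerConfig
) -> Labelling:
    """Relabel every inconsistent vertex to its score-maximising label.

    A labelled vertex v with label x is inconsistent iff
    ``alpha * S(v, x) <= S(v, y)`` for some other label y with positive
    score.  Scores are computed against the entry labelling and all
    corrections applied simultaneously; ties in the argmax break towards
    the lexicographically smallest label.
    """
    out = lab.copy()
    corrected = 0
    for v in sorted(lab.labelled):
        if v not in g:
            continue
        x = lab.label_of(v)
        scores = label_scores(g, lab, v, cfg.bfs_depth_cap)
        own = scores.get(x, 0.0)
        if any(
            y != x and s > 0.0 and cfg.alpha * own <= s for y, s in scores.items()
        ):
            top = max(scores.values())
            winner = min(y for y, s in scores.items() if s == top)
            if winner != x:
                out.set_labels(v, {winner})
                corrected += 1
    logger.info("step2: corrected %d inconsistent label(s)", corrected)
    return out


# ---------------------------------------------------------------------------
# Step 3 — propagate labels to unlabelled vertices
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class PropagationAction:
    """Candidate action ``(D(v,t), |c(v)-c(t)|, t, v)``.

    The dataclass ordering implements the execution order: smaller
    distance first, then smaller coverage difference; remaining ties break
    deterministically on the target id, then the source id (string
    comparison).
    """

    d: int
    cdiff: float
    target: str = field(compare=False)
    source: str = field(compare=False)
    _tie: Tuple[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_tie", (self.target, self.source))

    def as_tuple(self) -> Tuple[int, float, str, str]:
        return (self.d, self.cdiff, self.source, self.target)


def _sort_key(a: PropagationAction) -> Tuple[int, float, str, str]:
    return (a.d, a.cdiff, a.target, a.source)


def best_action(
    g: ContigGraph,
    lab: Labelling,
    v: str,
    cap: Optional[int],
) -> Optional[PropagationAction]:
    """The best candidate action for unlabelled vertex ``v``, if any.

    The source is the nearest labelled vertex; among equally near sources
    the one with the smallest coverage difference wins, then the smallest
    id.  ``None`` when no labelled vertex lies within the depth cap.
    """
    reach = labelled_within(g, lab, v, cap)
    if not reach:
        return None
    cv = g.coverage(v)
    best: Optional[Tuple[int, float, str]] = None
    for t, d in reach.items():
        key = (d, abs(cv - g.coverage(t)), t)
        if best is None or key < best:
            best = key
    d, cdiff, t = best
    return PropagationAction(d=d, cdiff=cdiff, target=v, source=t)


def step3_propagate(
    g: ContigGraph,
    lab: Labelling,
    cfg: RefinerConfig,
    trace: Optional[List[Tuple[PropagationAction, str]]] = None,
) -> Labelling:
    """Propagate labels to unlabelled vertices, one per iteration.

    Maintains the best candidate action per unlabelled vertex; each
    iteration executes the globally minimal action (the target inherits
    the source's single label) and then refreshes only the candidates a
    newly labelled vertex can affect — every unlabelled vertex reachable
    from it through previously unlabelled interiors within the depth cap.
    This local refresh is observationally identical to recomputing the
    whole ranked list.  Vertices with no labelled vertex in range remain
    unlabelled.  Pass ``trace`` to record the executed actions in order
    together with the label each target received.
    """
    out = lab.copy()
    cap = cfg.bfs_depth_cap
    candidates: Dict[str, PropagationAction] = {}
    for v in out.unlabelled(g):
        a = best_action(g, out, v, cap)
        if a is not None:
            candidates[v] = a
    executed = 0
    while candidates:
        action = min(candidates.values(), key=_sort_key)
        v, t = action.target, action.source
        label = out.label_of(t)
        out.set_labels(v, {label})
        if trace is not None:
            trace.append((action, label))
        executed += 1
        del candidates[v]
        # v turned labelled: it may now serve as a nearer source, and paths
        # that used v as an interior are no longer valid — refresh every
        # unlabelled vertex within reach of v through unlabelled interiors.
        for u in _unlabelled_near(g, out, v, cap):
            a = best_action(g, out, u, cap)
            if a is None:
                candidates.pop(u, None)
            else:
                candidates[u] = a
    logger.info("step3: propagated %d label(s)", executed)
    return out


def _unlabelled_near(
    g: ContigGraph, lab: Labelling, v: str, cap: Optional[int]
) -> Set[str]:
    """Unlabelled vertices joined to ``v`` by an all-unlabelled path <= cap."""
    from collections import deque

    out: Set[str] = set()
    seen = {v}
    queue = deque([(v, 0)])
    while queue:
        u, d = queue.popleft()
        if cap is not None and d >= cap:
            continue
        for w in g.neighbors(u):
            if w in seen or lab.is_labelled(w):
                continue
            seen.add(w)
            out.add(w)
            queue.append((w, d + 1))
    return out


# ---------------------------------------------------------------------------
# Step 4 — infer multi-labelled vertices
# ---------------------------------------------------------------------------


def component_avg_coverage(g: ContigGraph, members: Sequence[str]) -> float:
    """Length-weighted mean coverage sum(c_i * L_i) / sum(L_i) of a component."""
    members = list(members)
    if not members:
        raise ValueError("component must be non-empty")
    num = sum(g.coverage(v) * g.length(v) for v in members)
    den = sum(g.length(v) for v in members)
    return num / den


def subset_sum_select(
    candidates: Dict[str, float], target: float
) -> FrozenSet[str]:
    """Exhaustively pick the candidate subset whose sum is closest to target.

    ``candidates`` maps component ids to their average coverages.  All
    2**k subsets including the empty one are scored by ``|sum - target|``;
    ties break towards fewer elements, then lexicographically by the
    sorted tuple of component ids.
    """
    ids = sorted(candidates)
    best: Optional[Tuple[float, int, Tuple[str, ...]]] = None
    for r in range(len(ids) + 1):
        for combo in combinations(ids, r):
            s = sum(candidates[c] for c in combo)
            key = (abs(s - target), r, combo)
            if best is None or key < best:
                best = key
    return frozenset(best[2])


@dataclass(frozen=True)
class LabelComponent:
    """Maximal connected same-label subgraph with its coverage average."""

    comp_id: str  # smallest member contig id — stable across runs
    label: str
    members: FrozenSet[str]
    avg_coverage: float


def label_components(g: ContigGraph, lab: Labelling) -> List[LabelComponent]:
    """Maximal connected components of each label's induced subgraph."""
    comps: List[LabelComponent] = []
    for x in sorted(lab.bin_ids):
        vs = {v for v in g if x in lab.labels(v)}
        unvisited = set(vs)
        while unvisited:
            start = next(iter(unvisited))
            members = {start}
            queue = [start]
            unvisited.discard(start)
            while queue:
                u = queue.pop()
                for w in g.neighbors(u):
                    if w in unvisited:
                        unvisited.discard(w)
                        members.add(w)
                        queue.append(w)
            comps.append(
                LabelComponent(
                    comp_id=min(members),
                    label=x,
                    members=frozenset(members),
                    avg_coverage=component_avg_coverage(g, sorted(members)),
                )
            )
    return comps


def step4_infer_multilabel(
    g: ContigGraph, lab: Labelling, cfg: RefinerConfig
) -> Labelling:
    """Assign extra labels to contigs whose coverage exceeds their component's.

    For each labelled vertex v in component P with ``c(v) > c(P)`` and
    direct edges into components of other labels, the subset of adjacent
    foreign components whose summed averages best explain ``c(v) - c(P)``
    is found by exhaustive enumeration; v gains those components' labels.
    Every decision is made against the entry labelling, so the result is
    independent of vertex order and of any parallel schedule (the
    ``threads`` setting never changes the output).
    """
    comps = label_components(g, lab)
    comp_of: Dict[Tuple[str, str], LabelComponent] = {}
    for comp in comps:
        for v in comp.members:
            comp_of[(v, comp.label)] = comp
    out = lab.copy()
    gained = 0
    for v in sorted(lab.labelled):
        if v not in g:
            continue
        for x in sorted(lab.labels(v)):
            own = comp_of[(v, x)]
            cv = g.coverage(v)
            if cv <= own.avg_coverage:
                continue
            foreign: Dict[str, LabelComponent] = {}
            for w in g.neighbors(v):
                for y in lab.labels(w):
                    if y == x:
                        continue
                    comp = comp_of[(w, y)]
                    foreign[comp.comp_id] = comp
            if not foreign:
                continue
            if len(foreign) > cfg.max_components_for_subset:
                logger.warning(
                    "step4: contig %s touches %d foreign components "
                    "(limit %d); skipped",
                    v,
                    len(foreign),
                    cfg.max_components_for_subset,
                )
                continue
            chosen = subset_sum_select(
                {cid: comp.avg_coverage for cid, comp in foreign.items()},
                cv - own.avg_coverage,
            )
            new_labels = {foreign[cid].label for cid in chosen}
            if new_labels - out.labels(v):
                gained += 1
            for y in new_labels:
                out.assign(v, y)
    logger.info("step4: %d contig(s) gained extra label(s)", gained)
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RefinementResult:
    """Final labelling plus per-step bookkeeping."""

    labelling: Labelling
    removed: int
    corrected: int
    propagated: int
    multi_labelled: int
    trace: List[Tuple[PropagationAction, str]]

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "removed": self.removed,
            "corrected": self.corrected,
            "propagated": self.propagated,
            "multi_labelled": self.multi_labelled,
        }


def run_pipeline(
    g: ContigGraph,
    lab0: Labelling,
    cfg: Optional[RefinerConfig] = None,
    multilabel: bool = True,
) -> RefinementResult:
    """Run the full refinement: remove, correct, propagate, infer shared.

    ``lab0`` must be non-overlapped (at most one bin per contig).  With
    ``multilabel=False`` the final inference stage is skipped and the
    output stays one-bin-per-contig.
    """
    if lab0.is_overlapped():
        raise ValueError("initial binning must assign at most one bin per contig")
    missing = [v for v in g.missing_coverage()]
    if missing:
        raise ValueError(
            f"{len(missing)} contig(s) lack coverage (e.g. {missing[:3]}); "
            "supply an abundance file"
        )
    cfg = cfg or RefinerConfig()
    lab1 = step1_remove_unsupported(g, lab0)
    removed = len(lab0.labelled) - len(lab1.labelled)
    lab2 = step2_correct_inconsistent(g, lab1, cfg)
    corrected = sum(
        1 for v in lab1.labelled if lab1.labels(v) != lab2.labels(v)
    )
    trace: List[Tuple[PropagationAction, str]] = []
    lab3 = step3_propagate(g, lab2, cfg, trace=trace)
    propagated = len(lab3.labelled) - len(lab2.labelled)
    if multilabel:
        lab4 = step4_infer_multilabel(g, lab3, cfg)
        multi = sum(1 for v in lab4.labelled if len(lab4.labels(v)) > 1)
    else:
        lab4, multi = lab3, 0
    return RefinementResult(
        labelling=lab4,
        removed=removed,
        corrected=corrected,
        propagated=propagated,
        multi_labelled=multi,
        trace=trace,
    )
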