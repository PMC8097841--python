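"""Binning evaluation: precision/recall/F1 and shared-contig diagnostics.

A binning result against a known ground truth is summarised by a K x S
count matrix ``a[k, s]`` (contigs placed in bin k that belong to species
s) plus the number of ground-truth contigs left unclassified:

    precision = sum_k max_s a[k, s] / sum_{k,s} a[k, s]
    recall    = sum_s max_k a[k, s] / (sum_{k,s} a[k, s] + unclassified)
    F1        = 2 * precision * recall / (precision + recall)

Ground truth is derived from per-species alignment lengths: a contig is
attributed to the species of its longest alignment when that alignment
covers at least half of the contig.  The ratio of second-longest to
longest alignment length flags contigs likely shared between species.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple, Union

import numpy as np
import pandas as pd

from .graph import ContigGraph, Labelling

UNASSIGNED = "unassigned"


@dataclass
class BinningMatrix:
    """K x S contig-count matrix plus the unclassified count.

    ``counts`` is a DataFrame indexed by bin id with species-id columns;
    multi-binned contigs contribute one count per (contig, bin) pair.
    """

    counts: pd.DataFrame
    unclassified: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValueError("matrix needs at least one bin and one species")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.unclassified < 0:
            raise ValueError("unclassified must be non-negative")


def precision(m: BinningMatrix) -> float:
    """Fraction of binned contigs agreeing with their bin's majority species."""
    a = m.counts.to_numpy(dtype=float)
    total = a.sum()
    if total == 0:
        raise ValueError("precision undefined for an all-zero matrix")
    return float(a.max(axis=1).sum() / total)


def recall(m: BinningMatrix) -> float:
    """Fraction of ground-truth contigs recovered into their species' best bin."""
    a = m.counts.to_numpy(dtype=float)
    denom = a.sum() + m.unclassified
    if denom == 0:
        raise ValueError("recall undefined with no contigs at all")
    return float(a.max(axis=0).sum() / denom)


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; defined as 0 at p = r = 0."""
    if p == 0 and r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def binning_matrix(
    lab: Labelling,
    truth: Mapping[str, str],
    eligible: Optional[Iterable[str]] = None,
) -> BinningMatrix:
    """Tabulate a labelling against a contig -> species ground truth.

    Only contigs present in ``truth`` (and in ``eligible`` when given)
    enter the matrix; each (contig, bin) assignment adds one count.
    Ground-truth contigs with no bin at all make up ``unclassified``.
    """
    pool = set(truth)
    if eligible is not None:
        pool &= set(eligible)
    bins = sorted(
        {x for v in pool for x in lab.labels(v)}
    )
    species = sorted(set(truth[v] for v in pool))
    if not bins or not species:
        raise ValueError("no binned ground-truth contigs to evaluate")
    counts = pd.DataFrame(0, index=bins, columns=species, dtype=int)
    unclassified = 0
    for v in sorted(pool):
        ls = lab.labels(v)
        if not ls:
            unclassified += 1
            continue
        for x in ls:
            counts.loc[x, truth[v]] += 1
    return BinningMatrix(counts=counts, unclassified=unclassified)


# ---------------------------------------------------------------------------
# Ground truth from alignment tables
# ---------------------------------------------------------------------------


@dataclass
class AlignmentTable:
    """Per-contig best alignment length against each reference species."""

    #: contig id -> contig length in bases
    contig_lengths: Dict[str, int]
    #: contig id -> {species id -> best alignment length in bases}
    alignments: Dict[str, Dict[str, float]]

    def __post_init__(self) -> None:
        for v, per_species in self.alignments.items():
            length = self.contig_lengths.get(v)
            if length is None:
                raise ValueError(f"contig {v!r} has alignments but no length")
            for sp, al in per_species.items():
                if al < 0 or al > length:
                    raise ValueError(
                        f"alignment of {v!r} to {sp!r} ({al}) outside "
                        f"[0, contig length {length}]"
                    )


def assign_ground_truth(
    table: AlignmentTable,
    g: Optional[ContigGraph] = None,
    min_fraction: float = 0.5,
) -> Dict[str, str]:
    """Species attribution per contig under the half-length alignment rule.

    A contig belongs to the species of its longest alignment iff that
    alignment covers at least ``min_fraction`` of the contig; ties for the
    longest alignment leave the contig unassigned, as does falling short
    of the threshold.  When a graph is supplied, isolated contigs (degree
    zero) are excluded from the ground-truth set entirely.
    """
    out: Dict[str, str] = {}
    for v in sorted(table.contig_lengths):
        if g is not None and (v not in g or g.degree(v) == 0):
            continue
        per_species = table.alignments.get(v, {})
        positive = {sp: al for sp, al in per_species.items() if al > 0}
        if not positive:
            out[v] = UNASSIGNED
            continue
        best = max(positive.values())
        winners = [sp for sp, al in positive.items() if al == best]
        if len(winners) > 1 or best < min_fraction * table.contig_lengths[v]:
            out[v] = UNASSIGNED
        else:
            out[v] = winners[0]
    return out


def ratio_2nd_1st(alignment_lengths: Mapping[str, float]) -> float:
    """Second-longest over longest alignment length across species.

    Zero when the contig aligns to a single species only.  Values near 1
    indicate a contig shared between two references.
    """
    positive = sorted((al for al in alignment_lengths.values() if al > 0), reverse=True)
    if not positive:
        raise ValueError("contig has no positive alignment")
    if len(positive) == 1:
        return 0.0
    return positive[1] / positive[0]


def ratio_table(table: AlignmentTable) -> pd.DataFrame:
    """Per-contig Ratio(2nd/1st) as a tidy frame (plain-data violin input)."""
    rows = []
    for v in sorted(table.alignments):
        if any(al > 0 for al in table.alignments[v].values()):
            rows.append((v, ratio_2nd_1st(table.alignments[v])))
    return pd.DataFrame(rows, columns=["contig", "ratio_2nd_1st"])


def read_ground_truth_table(path: Union[str, "Path"]) -> AlignmentTable:  # noqa: F821
    """TSV of ``contig-id  species  alignment-length  contig-length`` rows."""
    lengths: Dict[str, int] = {}
    aligns: Dict[str, Dict[str, float]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected contig, species, "
                    "alignment-length, contig-length"
                )
            cid, sp = row[0].strip(), row[1].strip()
            al, cl = float(row[2]), int(row[3])
            if cid in lengths and lengths[cid] != cl:
                raise ValueError(
                    f"{path}:{lineno}: conflicting lengths for {cid!r}"
                )
            lengths[cid] = cl
            prev = aligns.setdefault(cid, {}).get(sp, 0.0)
            aligns[cid][sp] = max(prev, al)
    return AlignmentTable(contig_lengths=lengths, alignments=aligns)


def evaluate_binning(
    lab: Labelling,
    table: AlignmentTable,
    g: Optional[ContigGraph] = None,
) -> Dict[str, float]:
    """Precision, recall and F1 of a labelling against an alignment table."""
    truth = {
        v: sp
        for v, sp in assign_ground_truth(table, g).items()
        if sp != UNASSIGNED
    }
    m = binning_matrix(lab, truth)
    p = precision(m)
    r = recall(m)
    return {"precision": p, "recall": r, "f1": f1(p, r)}
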