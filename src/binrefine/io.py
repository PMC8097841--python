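"""Readers and writers for assembly-graph and binning file formats.

Supported inputs: GFA 1.0 (S/L records, optionally collapsed to a
contig-level graph via a SPAdes ``contigs.paths`` file), SGA's ASQG
(VT/ED records), SPAdes-style FASTA headers (``NODE_i_length_L_cov_c``),
plain abundance TSV (contig id, coverage) and two-column initial-binning
CSV.  Output: refined binning CSV plus a companion list of contigs left
unbinned.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple, Union

from .graph import ContigGraph, Labelling

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SPADES_HEADER = re.compile(
    r"NODE_(?P<idx>\d+)_length_(?P<length>\d+)_cov_(?P<cov>\d+(?:\.\d+)?)"
)


class GraphParseError(ValueError):
    """Malformed assembly-graph file; message names the offending line."""


def parse_spades_header(name: str) -> Optional[Tuple[int, float]]:
    """Extract (length, coverage) from a SPAdes-style sequence name.

    Names of the form ``NODE_<i>_length_<L>_cov_<c>`` yield ``(L, c)``;
    anything else yields ``None``.
    """
    m = _SPADES_HEADER.search(name)
    if m is None:
        return None
    return int(m.group("length")), float(m.group("cov"))


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------


def _parse_gfa_records(path: PathLike):
    segments: Dict[str, Tuple[int, Optional[float]]] = {}
    links: List[Tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise GraphParseError(
                        f"{path}:{lineno}: S record needs name and sequence"
                    )
                name, seq = fields[1], fields[2]
                length = None if seq == "*" else len(seq)
                cov = None
                for opt in fields[3:]:
                    if opt.startswith("LN:i:"):
                        length = int(opt[5:])
                    elif opt.startswith(("dp:f:", "DP:f:", "dp:i:")):
                        cov = float(opt.split(":", 2)[2])
                    elif opt.startswith("KC:i:") and cov is None and length:
                        cov = int(opt[5:]) / length
                if length is None:
                    length = 1
                header = parse_spades_header(name)
                if header is not None:
                    length, cov = header[0], header[1] if cov is None else cov
                segments[name] = (max(length, 1), cov)
            elif tag == "L":
                if len(fields) < 5:
                    raise GraphParseError(
                        f"{path}:{lineno}: L record needs 4 fields after the tag"
                    )
                links.append((fields[1], fields[3]))
    for lineno_check, (a, b) in enumerate(links):
        for seg in (a, b):
            if seg not in segments:
                raise GraphParseError(
                    f"{path}: L record references unknown segment {seg!r}"
                )
    return segments, links


def _parse_spades_paths(path: PathLike) -> Dict[str, Set[str]]:
    """Map each contig to the set of graph segments its path traverses.

    The SPAdes paths file alternates a contig name line with one or more
    path lines (``;``-terminated groups of signed segment ids).  Entries
    for reverse complements (names ending in ``'``) are folded into the
    forward contig.
    """
    path_line = re.compile(r"^[\w.-]+[+-]([,;]\s*[\w.-]+[+-])*;?$")
    contigs: Dict[str, Set[str]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if not path_line.match(line):
                # a name line; reverse-complement entries end in a quote
                name = line[:-1] if line.endswith("'") else line
                current = name
                contigs.setdefault(current, set())
            else:
                if current is None:
                    raise GraphParseError(
                        f"{path}: path line before any contig name"
                    )
                for part in line.replace(";", ",").split(","):
                    part = part.strip()
                    if part:
                        contigs[current].add(part.rstrip("+-"))
    return contigs


def read_gfa(
    path: PathLike,
    paths_file: Optional[PathLike] = None,
    abundance: Optional[Dict[str, float]] = None,
) -> ContigGraph:
    """Load a GFA 1.0 assembly graph as a contig graph.

    Without ``paths_file`` each S segment becomes a vertex and each L
    record an edge.  With a SPAdes contigs-paths file, vertices are the
    listed contigs; two contigs are joined when their segment paths share
    a segment or contain segments linked by an L record.  Coverage comes
    from SPAdes-style names or dp/KC tags where present; an ``abundance``
    map overrides both.
    """
    segments, links = _parse_gfa_records(path)
    g = ContigGraph()
    if paths_file is None:
        for name, (length, cov) in sorted(segments.items()):
            g.add_vertex(name, length, cov)
        for a, b in links:
            g.add_edge(a, b)
    else:
        contig_paths = _parse_spades_paths(paths_file)
        seg_to_contigs: Dict[str, Set[str]] = {}
        for contig, segs in contig_paths.items():
            header = parse_spades_header(contig)
            length, cov = header if header is not None else (1, None)
            g.add_vertex(contig, length, cov)
            for s in segs:
                seg_to_contigs.setdefault(s, set()).add(contig)
        # shared path segment => edge
        for s, cs in sorted(seg_to_contigs.items()):
            cs = sorted(cs)
            for i, a in enumerate(cs):
                for b in cs[i + 1:]:
                    g.add_edge(a, b)
        # segments linked in the graph => edge between their contigs
        for sa, sb in links:
            for a in seg_to_contigs.get(sa, ()):
                for b in seg_to_contigs.get(sb, ()):
                    if a != b:
                        g.add_edge(a, b)
    if abundance:
        for v, cov in abundance.items():
            if v in g:
                g.set_coverage(v, cov)
    return g


# ---------------------------------------------------------------------------
# ASQG (SGA)
# ---------------------------------------------------------------------------


def read_asqg(
    path: PathLike, abundance: Optional[Dict[str, float]] = None
) -> ContigGraph:
    """Load an SGA ASQG string-graph file.

    One vertex per VT record (length taken from the stored sequence), one
    edge per ED record.  ASQG stores no coverage, so refinement requires
    an abundance table.
    """
    g = ContigGraph()
    edges: List[Tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("HT"):
                continue
            fields = line.split("\t")
            if fields[0] == "VT":
                if len(fields) < 3:
                    raise GraphParseError(
                        f"{path}:{lineno}: VT record needs id and sequence"
                    )
                g.add_vertex(fields[1], max(len(fields[2]), 1))
            elif fields[0] == "ED":
                if len(fields) < 2:
                    raise GraphParseError(f"{path}:{lineno}: empty ED record")
                parts = fields[1].split()
                if len(parts) < 2:
                    raise GraphParseError(
                        f"{path}:{lineno}: ED record needs two vertex ids"
                    )
                edges.append((parts[0], parts[1], lineno))
    for a, b, lineno in edges:
        for v in (a, b):
            if v not in g:
                raise GraphParseError(
                    f"{path}:{lineno}: ED references unknown vertex {v!r}"
                )
        g.add_edge(a, b)
    if abundance:
        for v, cov in abundance.items():
            if v in g:
                g.set_coverage(v, cov)
    return g


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------


def read_abundance(path: PathLike) -> Dict[str, float]:
    """Tab-separated ``contig-id <tab> coverage`` table."""
    out: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'contig<TAB>coverage'"
                )
            cid, cov = parts[0], float(parts[1])
            if cid in out:
                raise ValueError(f"{path}:{lineno}: duplicate contig {cid!r}")
            if cov < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage")
            out[cid] = cov
    return out


def read_fasta_stats(path: PathLike) -> Dict[str, Tuple[int, Optional[float]]]:
    """Per-contig (length, coverage-or-None) from a FASTA file.

    Lengths come from the sequences; coverage from SPAdes-style headers
    when the name carries one.
    """
    from Bio import SeqIO

    out: Dict[str, Tuple[int, Optional[float]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = parse_spades_header(rec.id)
        cov = header[1] if header is not None else None
        out[rec.id] = (len(rec.seq), cov)
    return out


def read_initial_binning(
    path: PathLike, g: Optional[ContigGraph] = None
) -> Labelling:
    """Two-column CSV ``contig-id,bin-id`` as a one-bin-per-contig labelling.

    A contig listed under two different bins is an error (the input must
    be non-overlapped).  When a graph is given, records naming contigs
    absent from it are dropped with a warning.
    """
    assignment: Dict[str, str] = {}
    ignored = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'contig,bin'")
            cid, bid = row[0].strip(), row[1].strip()
            if cid in assignment:
                if assignment[cid] != bid:
                    raise ValueError(
                        f"{path}:{lineno}: contig {cid!r} assigned to both "
                        f"{assignment[cid]!r} and {bid!r}"
                    )
                continue
            if g is not None and cid not in g:
                ignored += 1
                continue
            assignment[cid] = bid
    if ignored:
        logger.warning(
            "%s: ignored %d record(s) for contigs absent from the graph",
            path,
            ignored,
        )
    return Labelling.from_single(assignment)


def write_binning(
    lab: Labelling,
    path: PathLike,
    g: Optional[ContigGraph] = None,
    unbinned_path: Optional[PathLike] = None,
) -> None:
    """Write a labelling as CSV, one row per (contig, bin) pair.

    Rows are sorted by contig id then bin id; a multi-binned contig
    produces one row per bin.  When a graph is given, contigs without any
    label are listed one-per-line in ``unbinned_path`` (default:
    ``<path>.unbinned.txt``).
    """
    rows = sorted(
        (v, x) for v, ls in lab.as_dict().items() for x in ls
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerows(rows)
    if g is not None:
        if unbinned_path is None:
            unbinned_path = str(path) + ".unbinned.txt"
        unbinned = sorted(v for v in g if not lab.is_labelled(v))
        with open(unbinned_path, "w") as fh:
            for v in unbinned:
                fh.write(v + "\n")


def read_binning(path: PathLike) -> Labelling:
    """Read a (possibly multi-bin) binning CSV back into a labelling."""
    lab = Labelling()
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: expected 'contig,bin' rows")
            lab.assign(row[0].strip(), row[1].strip())
    return lab
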