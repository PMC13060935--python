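"""Edge-labeled directed graph view of an assembly graph.

A GFA stores sequence on nodes (segments).  All downstream reasoning here —
tangle detection, multiplicity estimation, Eulerian traversal — wants sequence
on *edges*, with junctions between segments as vertices.  The transform is the
usual one for de Bruijn style graphs: every segment becomes one edge (two
oriented edges, one per strand), and segment ends connected by links are glued
into a shared junction vertex (transitively closed).

Junctions are kept strand-aware internally: each junction has two vertex
copies, one per reading direction, and an oriented edge's start/end vertices
live on the matching strand.  This is what makes walk legality sequence-exact
(A+ followed by C− at a shared junction is only legal if a link says so).
Public junction counts merge the two copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio.Seq import Seq

from .gfa import Link, Segment, SegmentGraph

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"


def _flip(orient: str) -> str:
    return REVERSE if orient == FORWARD else FORWARD


class OrientedEdge(NamedTuple):
    """A segment read in one direction; ``reverse`` flips the strand."""

    edge_id: str
    orient: str

    def reverse(self) -> "OrientedEdge":
        return OrientedEdge(self.edge_id, _flip(self.orient))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.edge_id}{self.orient}"


def reverse_walk(walk: Iterable[OrientedEdge]) -> list[OrientedEdge]:
    """The same walk read on the opposite strand."""
    return [oe.reverse() for oe in reversed(list(walk))]


class ValidationError(ValueError):
    pass


@dataclass
class EdgeRecord:
    sequence: str | None
    length: int
    coverage: float


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


# endpoint tokens: ("s"|"e", segment, orient); reverse twin of (s, seg, o) is (e, seg, -o)
def _rc_token(token):
    kind, seg, orient = token
    return ("e" if kind == "s" else "s", seg, _flip(orient))


class EdgeGraph:
    """Directed graph with sequence, length and coverage on edges.

    Edges are segments of the source GFA; vertices are junction classes (two
    strand copies each).  ``start``/``end`` give the strand-aware vertex of an
    oriented edge; ``junction_of`` maps a vertex to its strand-merged junction.
    """

    def __init__(self, segment_graph: SegmentGraph):
        self._source = segment_graph
        self.edges: dict[str, EdgeRecord] = {
            name: EdgeRecord(seg.sequence, seg.length, seg.coverage or 0.0)
            for name, seg in segment_graph.segments.items()
        }
        self._build_vertices(segment_graph.links)
        self._build_overlaps(segment_graph.links)
        self._build_adjacency()

    # -- construction ---------------------------------------------------
    def _build_vertices(self, links: list[Link]) -> None:
        uf = _UnionFind()
        tokens = []
        for name in sorted(self.edges):
            for kind in ("s", "e"):
                for orient in (FORWARD, REVERSE):
                    tokens.append((kind, name, orient))
                    uf.find((kind, name, orient))
        for link in links:
            uf.union(("e", link.from_seg, link.from_orient), ("s", link.to_seg, link.to_orient))
            uf.union(
                ("e", link.to_seg, _flip(link.to_orient)),
                ("s", link.from_seg, _flip(link.from_orient)),
            )
        self._vertex_of: dict = {}
        root_id: dict = {}
        for token in tokens:
            root = uf.find(token)
            if root not in root_id:
                root_id[root] = f"V{len(root_id)}"
            self._vertex_of[token] = root_id[root]
        # merge strand twins into junction ids
        self._junction_of: dict[str, str] = {}
        n_j = 0
        for token in tokens:
            v = self._vertex_of[token]
            if v in self._junction_of:
                continue
            twin = self._vertex_of[_rc_token(token)]
            jid = f"J{n_j}"
            n_j += 1
            self._junction_of[v] = jid
            self._junction_of[twin] = jid

    def _build_overlaps(self, links: list[Link]) -> None:
        self._pair_overlap: dict[tuple[OrientedEdge, OrientedEdge], int] = {}
        self._vertex_overlap: dict[str, int] = {}
        for link in links:
            a = OrientedEdge(link.from_seg, link.from_orient)
            b = OrientedEdge(link.to_seg, link.to_orient)
            self._pair_overlap[(a, b)] = link.overlap
            self._pair_overlap[(b.reverse(), a.reverse())] = link.overlap
            self._vertex_overlap[self.end(a)] = link.overlap
            self._vertex_overlap[self.end(b.reverse())] = link.overlap

    def _build_adjacency(self) -> None:
        self._out: dict[str, list[OrientedEdge]] = {}
        self._in: dict[str, list[OrientedEdge]] = {}
        for name in sorted(self.edges):
            for orient in (FORWARD, REVERSE):
                oe = OrientedEdge(name, orient)
                self._out.setdefault(self.start(oe), []).append(oe)
                self._in.setdefault(self.end(oe), []).append(oe)

    # -- vertices -------------------------------------------------------
    def start(self, oe: OrientedEdge) -> str:
        return self._vertex_of[("s", oe.edge_id, oe.orient)]

    def end(self, oe: OrientedEdge) -> str:
        return self._vertex_of[("e", oe.edge_id, oe.orient)]

    def junction_of(self, vertex: str) -> str:
        return self._junction_of[vertex]

    @property
    def junctions(self) -> set[str]:
        return set(self._junction_of.values())

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def vertices(self) -> set[str]:
        """Strand-aware vertex identifiers."""
        return set(self._vertex_of.values())

    def out_edges(self, vertex: str) -> list[OrientedEdge]:
        return list(self._out.get(vertex, []))

    def in_edges(self, vertex: str) -> list[OrientedEdge]:
        return list(self._in.get(vertex, []))

    def adjacent(self, a: OrientedEdge, b: OrientedEdge) -> bool:
        """True iff ``a`` can be immediately followed by ``b`` in a walk."""
        return self.end(a) == self.start(b)

    def segment_junctions(self, edge_id: str) -> set[str]:
        """Junctions touched by either end of a segment."""
        oe = OrientedEdge(edge_id, FORWARD)
        return {self.junction_of(self.start(oe)), self.junction_of(self.end(oe))}

    # -- edge attributes ------------------------------------------------
    def coverage(self, edge_id: str) -> float:
        return self.edges[edge_id].coverage

    def length(self, edge_id: str) -> int:
        return self.edges[edge_id].length

    def sequence(self, oe: OrientedEdge) -> str:
        seq = self.edges[oe.edge_id].sequence
        if seq is None:
            raise ValidationError(f"segment {oe.edge_id} carries no sequence")
        if oe.orient == FORWARD:
            return seq
        return str(Seq(seq).reverse_complement())

    def overlap(self, a: OrientedEdge, b: OrientedEdge) -> int:
        """Junction overlap (bp) between consecutive steps ``a`` then ``b``."""
        if (a, b) in self._pair_overlap:
            return self._pair_overlap[(a, b)]
        return self._vertex_overlap.get(self.end(a), 0)

    # -- export ---------------------------------------------------------
    def to_segment_graph(self) -> SegmentGraph:
        sg = SegmentGraph()
        for name in sorted(self.edges):
            rec = self.edges[name]
            sg.segments[name] = Segment(name, rec.sequence, rec.length, rec.coverage)
        sg.links = list(self._source.links)
        return sg


def to_edge_graph(segment_graph: SegmentGraph) -> EdgeGraph:
    """Junction-as-vertex transform of a node-sequence GFA graph."""
    return EdgeGraph(segment_graph)


def read_coverage_table(path: str | Path) -> dict[str, float]:
    """Read a 2-column (node, coverage) TSV; a header line is auto-detected."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"coverage table line {lineno}: need 2 columns")
            name, value = fields[0], fields[1]
            if lineno == 1 and name.lower() in ("node", "segment", "edge", "contig"):
                continue
            try:
                cov = float(value)
            except ValueError as exc:
                raise ValidationError(
                    f"coverage table line {lineno}: non-numeric coverage {value!r}"
                ) from exc
            if cov < 0:
                raise ValidationError(f"coverage table line {lineno}: negative coverage {cov}")
            table[name] = cov
    return table


def attach_coverage(
    graph: EdgeGraph, coverage: str | Path | dict[str, float] | None = None
) -> EdgeGraph:
    """Set per-edge coverage, mutating and returning ``graph``.

    An explicit table (path or dict) overrides coverage tags embedded in the
    GFA.  Edges absent from the table get coverage 0 with a warning.
    """
    if coverage is None:
        for name, rec in graph.edges.items():
            if rec.coverage < 0:
                raise ValidationError(f"segment {name}: negative embedded coverage")
        return graph
    table = coverage if isinstance(coverage, dict) else read_coverage_table(coverage)
    for value in table.values():
        if value < 0:
            raise ValidationError("negative coverage value in table")
    for name, rec in graph.edges.items():
        if name in table:
            rec.coverage = table[name]
        else:
            logger.warning("segment %s missing from coverage table; coverage set to 0", name)
            rec.coverage = 0.0
    return graph
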