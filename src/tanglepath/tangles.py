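"""Tangle detection from graph structure, edge length and coverage.

A tangle is a small connected cluster of short / repetitive edges delimited by
*unique* boundary edges — long edges whose coverage sits near the coverage of
a single genomic traversal.  ``n`` boundary pairs (x_i, y_i) delimit a tangle
when the boundary edges all belong to one undirected component, removing them
splits off a component C_t that is much smaller than the rest, and each x_i
ends (and each y_i starts) in C_t.  Tangles with one pair (one genomic path)
or two pairs (e.g. a repeat array shared by both haplotypes) are resolvable;
anything else is reported but flagged.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .graph import FORWARD, EdgeGraph, OrientedEdge

DEFAULT_MIN_UNIQUE_LEN = 100_000
DEFAULT_COV_WINDOW = (0.7, 1.3)
DEFAULT_MAX_TANGLE_FRACTION = 0.2


class TangleError(ValueError):
    pass


class InvertedRepeatError(TangleError):
    """A segment is reachable in both orientations inside one tangle.

    Traversals through inverted repeats (reverse-complement re-entry) are not
    supported; multiplicities of a segment and its reverse complement would
    have to be distinguished.
    """


@dataclass
class Tangle:
    tangle_id: str
    boundary_pairs: list[tuple[OrientedEdge, OrientedEdge]]
    tangle_edges: set[str]
    cov_u: float | None = None
    resolvable: bool = True
    reason: str = ""
    boundary_segments: set[str] = field(default_factory=set)

    @property
    def n_pairs(self) -> int:
        return len(self.boundary_pairs)

    def boundary_edge_ids(self) -> set[str]:
        ids = {x.edge_id for x, _ in self.boundary_pairs}
        ids |= {y.edge_id for _, y in self.boundary_pairs}
        return ids or set(self.boundary_segments)


def segment_adjacency(graph: EdgeGraph, segments: set[str] | None = None) -> nx.Graph:
    """Undirected segment-level adjacency: segments sharing a junction."""
    g = nx.Graph()
    junction_members: dict[str, list[str]] = {}
    names = sorted(segments) if segments is not None else sorted(graph.edges)
    for name in names:
        g.add_node(name)
        for j in graph.segment_junctions(name):
            junction_members.setdefault(j, []).append(name)
    for members in junction_members.values():
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    return g


def median_long_edge_coverage(graph: EdgeGraph, min_length: int) -> float:
    """Bootstrap the unique-coverage scale from all edges above the length floor."""
    covs = [graph.coverage(e) for e in graph.edges if graph.length(e) >= min_length]
    if not covs:
        raise TangleError(f"no edges of length >= {min_length} to estimate median coverage")
    return statistics.median(covs)


def classify_unique_edges(
    graph: EdgeGraph,
    min_length: int = DEFAULT_MIN_UNIQUE_LEN,
    cov_low: float = DEFAULT_COV_WINDOW[0],
    cov_high: float = DEFAULT_COV_WINDOW[1],
    median_cov: float | None = None,
) -> set[str]:
    """Edges long enough and covered near the single-traversal depth.

    ``median_cov`` is the coverage of a unique single-copy region; when not
    given it is bootstrapped as the median coverage of all edges above the
    length floor.
    """
    if median_cov is None:
        median_cov = median_long_edge_coverage(graph, min_length)
    if median_cov <= 0:
        raise TangleError("median coverage must be positive to classify unique edges")
    return {
        e
        for e in graph.edges
        if graph.length(e) >= min_length
        and cov_low * median_cov <= graph.coverage(e) <= cov_high * median_cov
    }


def _boundary_role_candidates(
    graph: EdgeGraph, tangle_junctions: set[str], seg: str
) -> tuple[OrientedEdge, OrientedEdge] | None:
    """(incoming, outgoing) oriented readings of a boundary segment.

    Returns None when the segment touches the tangle with both of its ends
    (it would not separate the tangle from the rest).
    """
    fwd = OrientedEdge(seg, FORWARD)
    end_in = graph.junction_of(graph.end(fwd)) in tangle_junctions
    start_in = graph.junction_of(graph.start(fwd)) in tangle_junctions
    if end_in and start_in:
        return None
    if end_in:
        return fwd, fwd.reverse()
    if start_in:
        return fwd.reverse(), fwd
    raise TangleError(f"segment {seg} does not touch the tangle")


def _forward_closure(
    graph: EdgeGraph, seeds: list[str], tangle_edges: set[str]
) -> tuple[set[OrientedEdge], set[str]]:
    """Oriented tangle edges reachable from seed vertices; also reached vertices."""
    reached_vertices = set(seeds)
    reached_edges: set[OrientedEdge] = set()
    stack = list(seeds)
    while stack:
        v = stack.pop()
        for oe in graph.out_edges(v):
            if oe.edge_id not in tangle_edges or oe in reached_edges:
                continue
            reached_edges.add(oe)
            w = graph.end(oe)
            if w not in reached_vertices:
                reached_vertices.add(w)
                stack.append(w)
    return reached_edges, reached_vertices


def _assign_boundary_roles(
    graph: EdgeGraph, tangle_edges: set[str], boundary_segs: list[str]
) -> list[tuple[OrientedEdge, OrientedEdge]] | str:
    """Pick incoming/outgoing roles, orientations, and x↔y pairing.

    Role assignments are tried in deterministic sorted order; the first whose
    strand-consistent forward reachability connects every incoming edge set to
    every outgoing edge wins.  Returns a reason string on failure.
    """
    tangle_junctions: set[str] = set()
    for e in tangle_edges:
        tangle_junctions |= graph.segment_junctions(e)
    candidates: dict[str, tuple[OrientedEdge, OrientedEdge]] = {}
    for seg in sorted(boundary_segs):
        cand = _boundary_role_candidates(graph, tangle_junctions, seg)
        if cand is None:
            return f"boundary edge {seg} touches the tangle on both sides"
        candidates[seg] = cand
    n = len(boundary_segs) // 2
    if len(boundary_segs) != 2 * n:
        return f"odd number of boundary edges ({len(boundary_segs)})"
    segs = sorted(boundary_segs)
    for incoming_segs in combinations(segs, n):
        xs = [candidates[s][0] for s in incoming_segs]
        ys = [candidates[s][1] for s in segs if s not in incoming_segs]
        seeds = [graph.end(x) for x in xs]
        reached_edges, reached_vertices = _forward_closure(graph, seeds, tangle_edges)
        if any(oe.reverse() in reached_edges for oe in reached_edges):
            continue  # inverted repeat under this reading; try another
        if not all(graph.start(y) in reached_vertices for y in ys):
            continue
        # pair x_i with a reachable y_i (lexicographically first perfect matching)
        pairing = _match_pairs(graph, tangle_edges, xs, ys)
        if pairing is not None:
            return pairing
    return "no strand-consistent incoming/outgoing assignment of boundary edges"


def _match_pairs(
    graph: EdgeGraph,
    tangle_edges: set[str],
    xs: list[OrientedEdge],
    ys: list[OrientedEdge],
) -> list[tuple[OrientedEdge, OrientedEdge]] | None:
    reach: dict[OrientedEdge, set[OrientedEdge]] = {}
    for x in xs:
        _, vertices = _forward_closure(graph, [graph.end(x)], tangle_edges)
        reach[x] = {y for y in ys if graph.start(y) in vertices}

    def backtrack(i: int, used: set[OrientedEdge]) -> list | None:
        if i == len(xs):
            return []
        for y in sorted(reach[xs[i]]):
            if y in used:
                continue
            rest = backtrack(i + 1, used | {y})
            if rest is not None:
                return [(xs[i], y)] + rest
        return None

    return backtrack(0, set())


def detect_tangles(
    graph: EdgeGraph,
    unique_edges: set[str],
    max_tangle_fraction: float = DEFAULT_MAX_TANGLE_FRACTION,
) -> list[Tangle]:
    """Find tangles: components of non-unique edges fenced in by unique edges.

    Grown by flood fill over non-unique segments; the unique edges on the
    frontier become the boundary.  Candidates whose total sequence length
    exceeds ``max_tangle_fraction`` of their full component, or whose boundary
    count is not 2 or 4, are returned flagged unresolvable.
    """
    if not graph.edges:
        return []
    full_adj = segment_adjacency(graph)
    component_of: dict[str, int] = {}
    component_len: dict[int, int] = {}
    for idx, comp in enumerate(sorted(nx.connected_components(full_adj), key=sorted)):
        for seg in comp:
            component_of[seg] = idx
        component_len[idx] = sum(graph.length(s) for s in comp)

    non_unique = set(graph.edges) - set(unique_edges)
    sub_adj = segment_adjacency(graph, non_unique)
    tangles: list[Tangle] = []
    for comp in sorted(nx.connected_components(sub_adj), key=sorted):
        tangle_edges = set(comp)
        tangle_junctions: set[str] = set()
        for e in tangle_edges:
            tangle_junctions |= graph.segment_junctions(e)
        boundary = sorted(
            u
            for u in unique_edges
            if graph.segment_junctions(u) & tangle_junctions
        )
        if not boundary:
            continue  # an isolated component, not a tangle
        tid = f"tangle{len(tangles)}"
        tangle = Tangle(tid, [], tangle_edges, boundary_segments=set(boundary))
        comp_id = component_of[next(iter(tangle_edges))]
        t_len = sum(graph.length(s) for s in tangle_edges)
        if t_len > max_tangle_fraction * component_len[comp_id]:
            tangle.resolvable = False
            tangle.reason = (
                f"tangle length {t_len} exceeds {max_tangle_fraction:.0%} of its component"
            )
            tangles.append(tangle)
            continue
        if len(boundary) not in (2, 4):
            tangle.resolvable = False
            tangle.reason = f"{len(boundary)} boundary edges (need 2 or 4)"
            tangles.append(tangle)
            continue
        assigned = _assign_boundary_roles(graph, tangle_edges, boundary)
        if isinstance(assigned, str):
            tangle.resolvable = False
            tangle.reason = assigned
        else:
            tangle.boundary_pairs = assigned
        tangles.append(tangle)
    return tangles


def manual_tangle(graph: EdgeGraph, boundary: list[OrientedEdge]) -> Tangle:
    """Build a tangle from user-named boundary edges (x1, y1[, x2, y2]).

    The tangle component is the flood fill from the boundary junctions over
    non-boundary segments; the named edges must separate it from the rest.
    """
    if len(boundary) % 2 != 0 or len(boundary) // 2 not in (1, 2):
        raise TangleError("boundary must list x1,y1 or x1,y1,x2,y2")
    pairs = [(boundary[2 * i], boundary[2 * i + 1]) for i in range(len(boundary) // 2)]
    boundary_segs = {oe.edge_id for oe in boundary}
    if len(boundary_segs) != len(boundary):
        raise TangleError("boundary edges must be distinct segments")
    adj = segment_adjacency(graph, set(graph.edges) - boundary_segs)
    seed_junctions = set()
    for x, y in pairs:
        seed_junctions.add(graph.junction_of(graph.end(x)))
        seed_junctions.add(graph.junction_of(graph.start(y)))
    components = [
        set(c)
        for c in nx.connected_components(adj)
        if any(graph.segment_junctions(s) & seed_junctions for s in c)
    ]
    if len(components) != 1:
        raise TangleError(
            "named boundary edges do not delimit a single tangle component "
            f"(found {len(components)})"
        )
    tangle_edges = components[0]
    tangle_junctions: set[str] = set()
    for e in tangle_edges:
        tangle_junctions |= graph.segment_junctions(e)
    for x, y in pairs:
        if graph.junction_of(graph.end(x)) not in tangle_junctions:
            raise TangleError(f"incoming boundary edge {x} does not end in the tangle")
        if graph.junction_of(graph.start(y)) not in tangle_junctions:
            raise TangleError(f"outgoing boundary edge {y} does not start in the tangle")
        if graph.junction_of(graph.start(x)) in tangle_junctions:
            raise TangleError(
                f"boundary edge {x} touches the tangle on both sides; it does not separate"
            )
        if graph.junction_of(graph.end(y)) in tangle_junctions:
            raise TangleError(
                f"boundary edge {y} touches the tangle on both sides; it does not separate"
            )
    return Tangle(
        "manual", pairs, tangle_edges, boundary_segments=boundary_segs
    )


def verify_separation(graph: EdgeGraph, tangle: Tangle) -> bool:
    """Independent flood-fill check: removing boundary edges isolates the tangle."""
    remaining = set(graph.edges) - tangle.boundary_edge_ids()
    adj = segment_adjacency(graph, remaining)
    for comp in nx.connected_components(adj):
        comp = set(comp)
        if comp & tangle.tangle_edges:
            if comp != tangle.tangle_edges:
                return False
    return True


def estimate_cov_u(
    tangle: Tangle, graph: EdgeGraph, user_value: float | None = None
) -> float:
    """Single-traversal coverage: the median coverage of the boundary edges."""
    if user_value is not None:
        if user_value <= 0:
            raise TangleError("user-supplied cov_u must be positive")
        return float(user_value)
    if not tangle.boundary_pairs and not tangle.boundary_segments:
        raise TangleError("tangle has no boundary edges")
    covs = [graph.coverage(seg) for seg in sorted(tangle.boundary_edge_ids())]
    med = statistics.median(covs)
    if med <= 0:
        raise TangleError("all boundary edge coverages are zero; cannot normalize")
    return float(med)


def oriented_tangle_subgraph(graph: EdgeGraph, tangle: Tangle) -> set[OrientedEdge]:
    """Orient every tangle edge consistently with the boundary reading.

    Forward closure from the incoming boundary ends, then backward closure
    from the outgoing boundary starts; any segment reachable in both
    orientations raises :class:`InvertedRepeatError`.  Stray edges reachable
    in neither direction (candidates for multiplicity 0) default to forward.
    """
    seeds = [graph.end(x) for x, _ in tangle.boundary_pairs]
    oriented, vertices = _forward_closure(graph, seeds, tangle.tangle_edges)
    # backward closure from outgoing starts
    back_stack = [graph.start(y) for _, y in tangle.boundary_pairs]
    seen_vertices = set(back_stack)
    while back_stack:
        v = back_stack.pop()
        for oe in graph.in_edges(v):
            if oe.edge_id not in tangle.tangle_edges or oe in oriented:
                continue
            oriented.add(oe)
            w = graph.start(oe)
            if w not in seen_vertices:
                seen_vertices.add(w)
                back_stack.append(w)
    if any(oe.reverse() in oriented for oe in oriented):
        raise InvertedRepeatError(
            f"tangle {tangle.tangle_id}: a segment is reachable in both orientations "
            "(inverted repeat); not supported"
        )
    covered = {oe.edge_id for oe in oriented}
    for seg in sorted(tangle.tangle_edges - covered):
        oriented.add(OrientedEdge(seg, FORWARD))
    return oriented
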