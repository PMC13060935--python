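"""Eulerian traversal of a tangle and read-guided path optimization.

The multiplicity assignment expands into a multigraph (an edge of
multiplicity n becomes n identical multiedges; multiplicity-0 edges vanish),
in which any traversal consistent with the copy numbers is an Eulerian path
from the incoming to the outgoing boundary.  One such path is drawn with a
seeded Hierholzer walk, then improved by local search: the *swap* move
exchanges two non-overlapping subpaths that start on the same vertex A and
end on the same vertex B — reordering repeat units while preserving both
multiplicities and adjacency.  The swap move set connects all Eulerian paths
with fixed endpoints, so the search space is complete; random restarts guard
against local optima.  A path's score is the number of reads whose
edge-label walk (either strand) occurs as an exact contiguous run in it.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .graph import FORWARD, REVERSE, EdgeGraph, OrientedEdge, reverse_walk
from .matching import AhoCorasick
from .multiplicity import MultiplicityAssignment
from .tangles import Tangle

logger = logging.getLogger(__name__)

DEFAULT_RESTARTS = 10
DEFAULT_SEED = 42
MAX_ACCEPTED_SWAPS = 10_000

_GAF_PATH_RE = re.compile(r"([><])([^><\s]+)")


class NoEulerianPathError(RuntimeError):
    """The multiplicity-positive multigraph admits no boundary-to-boundary path."""


@dataclass
class TraversalPath:
    steps: list[OrientedEdge]
    score: int = 0

    def edge_multiset(self) -> dict[OrientedEdge, int]:
        counts: dict[OrientedEdge, int] = {}
        for oe in self.steps:
            counts[oe] = counts.get(oe, 0) + 1
        return counts


@dataclass
class ReadWalk:
    read_id: str
    labels: list[OrientedEdge]


@dataclass
class Multigraph:
    """Expanded tangle: multiedge counts plus the forced start/end vertices."""

    counts: dict[OrientedEdge, int]
    start: str
    end: str

    @property
    def n_multiedges(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# GAF input


def load_gaf(path: str | Path, graph: EdgeGraph, tangle: Tangle) -> list[ReadWalk]:
    """Read GAF alignments, keeping each read's walk through the tangle.

    The path column is translated to oriented edges and clipped to the longest
    contiguous, adjacency-consistent run over tangle plus boundary edges;
    walks shorter than 2 labels constrain nothing and are dropped.
    """
    allowed = set(tangle.tangle_edges) | tangle.boundary_edge_ids()
    walks: list[ReadWalk] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                logger.warning("GAF line %d: fewer than 6 columns; skipped", lineno)
                continue
            read_id, path_col = fields[0], fields[5]
            tokens = _GAF_PATH_RE.findall(path_col)
            if not tokens or "".join(s + n for s, n in tokens) != path_col:
                logger.warning("GAF line %d: malformed path column; skipped", lineno)
                continue
            labels = []
            unknown = False
            for sign, name in tokens:
                if name not in graph.edges:
                    logger.warning(
                        "GAF line %d: unknown segment %s; record skipped", lineno, name
                    )
                    unknown = True
                    break
                labels.append(OrientedEdge(name, FORWARD if sign == ">" else REVERSE))
            if unknown:
                continue
            run = _best_run(graph, labels, allowed)
            if len(run) >= 2:
                walks.append(ReadWalk(read_id, run))
    return walks


def _best_run(
    graph: EdgeGraph, labels: list[OrientedEdge], allowed: set[str]
) -> list[OrientedEdge]:
    """Longest contiguous run inside ``allowed`` with consistent adjacency."""
    best: list[OrientedEdge] = []
    current: list[OrientedEdge] = []
    for oe in labels:
        if oe.edge_id in allowed and (not current or graph.adjacent(current[-1], oe)):
            current.append(oe)
        else:
            current = [oe] if oe.edge_id in allowed else []
        if len(current) > len(best):
            best = list(current)
    return best


# ---------------------------------------------------------------------------
# Multigraph expansion and Eulerian paths


def build_multigraph(
    graph: EdgeGraph, tangle: Tangle, assignment: MultiplicityAssignment, pair_index: int = 0
) -> Multigraph:
    """Expand a multiplicity assignment for one boundary pair.

    Checks the Eulerian degree condition (start out−in = 1, end in−out = 1,
    balanced elsewhere) and weak connectivity of multiplicity-positive edges.
    """
    x, y = tangle.boundary_pairs[pair_index]
    counts = {
        assignment.oriented[eid]: m for eid, m in assignment.mult.items() if m > 0
    }
    mg = Multigraph(counts, start=graph.end(x), end=graph.start(y))
    _check_eulerian_preconditions(graph, mg)
    return mg


def _check_eulerian_preconditions(graph: EdgeGraph, mg: Multigraph) -> None:
    balance: dict[str, int] = {mg.start: 0, mg.end: 0}
    und = nx.Graph()
    und.add_node(mg.start)
    und.add_node(mg.end)
    for oe, m in mg.counts.items():
        u, v = graph.start(oe), graph.end(oe)
        balance[u] = balance.get(u, 0) + m
        balance[v] = balance.get(v, 0) - m
        und.add_edge(u, v)
    for v, b in balance.items():
        expected = 1 if v == mg.start else (-1 if v == mg.end else 0)
        if mg.start == mg.end and v == mg.start:
            expected = 0
        if b != expected:
            raise NoEulerianPathError(
                f"degree imbalance {b} at vertex {v} (expected {expected})"
            )
    if und.number_of_nodes() and not nx.is_connected(und):
        raise NoEulerianPathError("multiplicity-positive edges are not connected")


def _hierholzer(
    graph: EdgeGraph,
    adjacency: dict[str, list],
    start: str,
    n_edges: int,
) -> list:
    """Seeded Hierholzer walk; ``adjacency`` lists are consumed in place."""
    stack: list[tuple[str, object]] = [(start, None)]
    out: list = []
    while stack:
        v, via = stack[-1]
        bucket = adjacency.get(v)
        if bucket:
            item = bucket.pop()
            stack.append((item[1], item[0]))
        else:
            stack.pop()
            if via is not None:
                out.append(via)
    out.reverse()
    if len(out) != n_edges:
        raise NoEulerianPathError("graph is disconnected; Hierholzer walk incomplete")
    return out


def find_eulerian_path(
    graph: EdgeGraph,
    multigraph: Multigraph,
    x: OrientedEdge,
    y: OrientedEdge,
    rng_seed: int | random.Random = DEFAULT_SEED,
) -> TraversalPath:
    """A random valid traversal: ``x``, an Eulerian run over the tangle, ``y``."""
    rng = rng_seed if isinstance(rng_seed, random.Random) else random.Random(rng_seed)
    adjacency: dict[str, list] = {}
    for oe in sorted(multigraph.counts):
        for _ in range(multigraph.counts[oe]):
            adjacency.setdefault(graph.start(oe), []).append((oe, graph.end(oe)))
    for bucket in adjacency.values():
        rng.shuffle(bucket)
    internal = _hierholzer(graph, adjacency, multigraph.start, multigraph.n_multiedges)
    return TraversalPath([x] + internal + [y])


def enumerate_eulerian_paths(
    graph: EdgeGraph, multigraph: Multigraph, cap: int | None = None
) -> list[list[OrientedEdge]]:
    """All Eulerian edge sequences from start to end (internal steps only).

    Exhaustive backtracking; intended for small instances (tests, oracles).
    """
    counts = dict(multigraph.counts)
    total = multigraph.n_multiedges
    paths: list[list[OrientedEdge]] = []
    prefix: list[OrientedEdge] = []

    def recurse(v: str) -> bool:
        if len(prefix) == total:
            if v == multigraph.end:
                paths.append(list(prefix))
                if cap is not None and len(paths) >= cap:
                    return True
            return False
        for oe in sorted(counts):
            if counts[oe] > 0 and graph.start(oe) == v:
                counts[oe] -= 1
                prefix.append(oe)
                stop = recurse(graph.end(oe))
                prefix.pop()
                counts[oe] += 1
                if stop:
                    return True
        return False

    recurse(multigraph.start)
    return paths


# ---------------------------------------------------------------------------
# Scoring


class WalkScorer:
    """Counts reads supported by a path; each read counts once, either strand."""

    def __init__(self, walks: list[ReadWalk]):
        patterns = []
        self._owner: list[int] = []
        for idx, walk in enumerate(walks):
            patterns.append(tuple(walk.labels))
            self._owner.append(idx)
            patterns.append(tuple(reverse_walk(walk.labels)))
            self._owner.append(idx)
        self._automaton = AhoCorasick(patterns) if patterns else None
        self.n_walks = len(walks)

    def supported(self, paths: list[list[OrientedEdge]]) -> set[int]:
        """Indices of reads matching any of the given step sequences."""
        if self._automaton is None:
            return set()
        found: set[int] = set()
        for steps in paths:
            found |= {self._owner[pid] for pid in self._automaton.search(steps)}
        return found

    def score(self, paths: list[list[OrientedEdge]]) -> int:
        return len(self.supported(paths))


def score_path(path: TraversalPath, walks: list[ReadWalk]) -> int:
    """Number of reads found as exact contiguous runs in the path."""
    return WalkScorer(walks).score([path.steps])


# ---------------------------------------------------------------------------
# Swaps

# a swap descriptor: (path_index_1, i1, j1, path_index_2, i2, j2); for the
# single-path operations path indices are both 0


def _intervals_by_endpoints(
    graph: EdgeGraph, steps: list[OrientedEdge], lo: int, hi: int
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i in range(lo, hi + 1):
        a = graph.start(steps[i])
        for j in range(i, hi + 1):
            b = graph.end(steps[j])
            groups.setdefault((a, b), []).append((i, j))
    return groups


def enumerate_swaps(graph: EdgeGraph, path: TraversalPath, lock_ends: bool = True):
    """All swaps on one path: non-overlapping same-endpoint interval pairs.

    With ``lock_ends`` the boundary steps (first and last) never move.
    """
    steps = path.steps if isinstance(path, TraversalPath) else path
    if len(steps) < 2:
        return
    lo, hi = (1, len(steps) - 2) if lock_ends else (0, len(steps) - 1)
    if hi < lo:
        return
    for group in _intervals_by_endpoints(graph, steps, lo, hi).values():
        for a in range(len(group)):
            i1, j1 = group[a]
            for b in range(len(group)):
                i2, j2 = group[b]
                if j1 < i2:
                    yield (0, i1, j1, 0, i2, j2)


def apply_swap(path: TraversalPath, swap) -> TraversalPath:
    """Exchange the two subpaths named by a swap descriptor."""
    steps = path.steps if isinstance(path, TraversalPath) else path
    _, i1, j1, _, i2, j2 = swap
    new = (
        steps[:i1]
        + steps[i2 : j2 + 1]
        + steps[j1 + 1 : i2]
        + steps[i1 : j1 + 1]
        + steps[j2 + 1 :]
    )
    if isinstance(path, TraversalPath):
        return TraversalPath(new, path.score)
    return new


def _enumerate_joint_swaps(graph: EdgeGraph, paths: list[list[OrientedEdge]]):
    """Swaps within each path plus cross-path exchanges of same-endpoint subpaths."""
    groups: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for p_idx, steps in enumerate(paths):
        if len(steps) < 3:
            continue
        for (a, b), ivals in _intervals_by_endpoints(
            graph, steps, 1, len(steps) - 2
        ).items():
            bucket = groups.setdefault((a, b), [])
            bucket.extend((p_idx, i, j) for i, j in ivals)
    for bucket in groups.values():
        for p1, i1, j1 in bucket:
            for p2, i2, j2 in bucket:
                if p1 == p2:
                    if j1 < i2:
                        yield (p1, i1, j1, p2, i2, j2)
                elif p1 < p2:
                    yield (p1, i1, j1, p2, i2, j2)


def _apply_joint_swap(paths: list[list[OrientedEdge]], swap) -> list[list[OrientedEdge]]:
    p1, i1, j1, p2, i2, j2 = swap
    if p1 == p2:
        return [
            apply_swap(steps, swap) if idx == p1 else steps
            for idx, steps in enumerate(paths)
        ]
    new = [list(steps) for steps in paths]
    seg1 = paths[p1][i1 : j1 + 1]
    seg2 = paths[p2][i2 : j2 + 1]
    new[p1] = paths[p1][:i1] + seg2 + paths[p1][j1 + 1 :]
    new[p2] = paths[p2][:i2] + seg1 + paths[p2][j2 + 1 :]
    return new


# ---------------------------------------------------------------------------
# Optimization


def _path_sort_key(paths: list[list[OrientedEdge]]):
    return tuple(tuple((oe.edge_id, oe.orient) for oe in steps) for steps in paths)


def _local_search(
    graph: EdgeGraph,
    paths: list[list[OrientedEdge]],
    scorer: WalkScorer,
    rng: random.Random,
    max_accepted: int = MAX_ACCEPTED_SWAPS,
) -> tuple[list[list[OrientedEdge]], int]:
    score = scorer.score(paths)
    accepted = 0
    while accepted < max_accepted:
        swaps = list(_enumerate_joint_swaps(graph, paths))
        rng.shuffle(swaps)
        for swap in swaps:
            candidate = _apply_joint_swap(paths, swap)
            s = scorer.score(candidate)
            if s > score:
                paths, score = candidate, s
                accepted += 1
                break
        else:
            break  # full scan without improvement: local optimum
    return paths, score


def _restart_seed(rng_seed: int, restart: int) -> int:
    return (rng_seed * 1_000_003 + restart) % (2**31 - 1)


def optimize_path(
    graph: EdgeGraph,
    multigraph: Multigraph,
    x: OrientedEdge,
    y: OrientedEdge,
    walks: list[ReadWalk],
    restarts: int = DEFAULT_RESTARTS,
    rng_seed: int = DEFAULT_SEED,
    stats: dict | None = None,
) -> TraversalPath:
    """Best-scoring traversal for a single boundary pair across random restarts.

    Each restart draws a fresh Eulerian path and descends by first-improvement
    swaps in randomly shuffled scan order until no swap improves the score.
    Ties between restarts break to the lexicographically smallest edge-id
    sequence, so identical inputs and seed give identical output.  ``stats``
    (a dict, if given) receives per-restart final scores.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    scorer = WalkScorer(walks)
    restart_scores: list[int] = []
    best: tuple | None = None
    for r in range(restarts):
        rng = random.Random(_restart_seed(rng_seed, r))
        initial = find_eulerian_path(graph, multigraph, x, y, rng)
        paths, score = _local_search(graph, [initial.steps], scorer, rng)
        restart_scores.append(score)
        key = (-score, _path_sort_key(paths))
        if best is None or key < best[0]:
            best = (key, paths[0], score)
    assert best is not None
    if stats is not None:
        stats["restart_scores"] = restart_scores
    return TraversalPath(best[1], best[2])


def optimize_tangle_paths(
    graph: EdgeGraph,
    tangle: Tangle,
    assignment: MultiplicityAssignment,
    walks: list[ReadWalk],
    restarts: int = DEFAULT_RESTARTS,
    rng_seed: int = DEFAULT_SEED,
    stats: dict | None = None,
) -> list[TraversalPath]:
    """Traversals for all boundary pairs of a tangle, optimized jointly.

    With two pairs, the multiedge budget is shared: each restart decomposes
    the joint multigraph into one walk per pair, and the local search allows
    swaps within a path and exchanges of same-endpoint subpaths between the
    two paths.  The score is the number of reads supported by either path.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if tangle.n_pairs == 1:
        x, y = tangle.boundary_pairs[0]
        mg = build_multigraph(graph, tangle, assignment)
        best = optimize_path(graph, mg, x, y, walks, restarts, rng_seed, stats=stats)
        return [best]
    scorer = WalkScorer(walks)
    restart_scores: list[int] = []
    best: tuple | None = None
    for r in range(restarts):
        rng = random.Random(_restart_seed(rng_seed, r))
        internals = _decompose_joint(graph, tangle, assignment, rng)
        paths = [
            [x] + internal + [y]
            for (x, y), internal in zip(tangle.boundary_pairs, internals)
        ]
        paths, score = _local_search(graph, paths, scorer, rng)
        restart_scores.append(score)
        key = (-score, _path_sort_key(paths))
        if best is None or key < best[0]:
            best = (key, paths, score)
    assert best is not None
    if stats is not None:
        stats["restart_scores"] = restart_scores
    per_path_scores = [
        len(scorer.supported([steps])) for steps in best[1]
    ]
    return [TraversalPath(steps, s) for steps, s in zip(best[1], per_path_scores)]


_SPLIT = object()  # artificial-edge marker used to decompose two-pair tangles


def _decompose_joint(
    graph: EdgeGraph,
    tangle: Tangle,
    assignment: MultiplicityAssignment,
    rng: random.Random,
) -> list[list[OrientedEdge]]:
    """Split the joint multigraph into one internal walk per boundary pair.

    An artificial edge from the end vertex of pair i to the start vertex of
    pair i+1 chains the pairs into a single Eulerian path problem; cutting at
    the artificial edges yields the per-pair walks.
    """
    pairs = tangle.boundary_pairs
    starts = [graph.end(x) for x, _ in pairs]
    ends = [graph.start(y) for _, y in pairs]
    adjacency: dict[str, list] = {}
    n_edges = 0
    for eid in sorted(assignment.mult):
        oe = assignment.oriented[eid]
        for _ in range(assignment.mult[eid]):
            adjacency.setdefault(graph.start(oe), []).append((oe, graph.end(oe)))
            n_edges += 1
    for i in range(len(pairs) - 1):
        adjacency.setdefault(ends[i], []).append((_SPLIT, starts[i + 1]))
        n_edges += 1
    for bucket in adjacency.values():
        rng.shuffle(bucket)
    walk = _hierholzer(graph, adjacency, starts[0], n_edges)
    internals: list[list[OrientedEdge]] = [[]]
    for item in walk:
        if item is _SPLIT:
            internals.append([])
        else:
            internals[-1].append(item)
    if len(internals) != len(pairs):
        raise NoEulerianPathError("joint decomposition failed to produce one walk per pair")
    return internals


# ---------------------------------------------------------------------------
# Swap connectivity (the move set reaches every Eulerian path)


def swap_sequence(
    graph: EdgeGraph, source: list[OrientedEdge], target: list[OrientedEdge]
) -> list[tuple]:
    """Swaps transforming ``source`` into ``target`` by common-prefix extension.

    At the first mismatch position i, the target's edge also occurs later in
    the source (same start vertex A, since all copies of an underlying edge
    share endpoints).  Either the source returns to A after that occurrence —
    then an adjacent-interval swap brings the edge to position i — or the
    loop hanging at A and the continuation share some vertex B, and swapping
    the A→B halves does.  Each swap strictly extends the common prefix.
    """
    if sorted(source) != sorted(target):
        raise ValueError("paths do not use the same multiset of edges")
    current = list(source)
    swaps: list[tuple] = []
    for i in range(len(target)):
        if current[i] == target[i]:
            continue
        j = next(k for k in range(i + 1, len(current)) if current[k] == target[i])
        vertex_a = graph.start(current[j])
        swap = None
        for m in range(j, len(current)):
            if graph.end(current[m]) == vertex_a:
                swap = (0, i, j - 1, 0, j, m)
                break
        if swap is None:
            ends_after = {}
            for m2 in range(j, len(current)):
                ends_after.setdefault(graph.end(current[m2]), m2)
            for m1 in range(i, j):
                b = graph.end(current[m1])
                if b in ends_after:
                    swap = (0, i, m1, 0, j, ends_after[b])
                    break
        if swap is None:  # cannot happen for Eulerian paths on one multiset
            raise RuntimeError("no prefix-extending swap found")
        current = apply_swap(current, swap)
        swaps.append(swap)
        assert current[i] == target[i]
    return swaps


def check_swap_connectivity(
    graph: EdgeGraph, multigraph: Multigraph, max_paths: int = 200
) -> dict[tuple[int, int], list[tuple]]:
    """Explicit swap sequences between every ordered pair of Eulerian paths.

    Every returned sequence is verified by replay.  Intended for small
    multigraphs (<= 8 multiedges).
    """
    paths = enumerate_eulerian_paths(graph, multigraph, cap=max_paths + 1)
    if len(paths) > max_paths:
        raise ValueError(f"more than {max_paths} Eulerian paths; instance too large")
    proof: dict[tuple[int, int], list[tuple]] = {}
    for a, p in enumerate(paths):
        for b, q in enumerate(paths):
            seq = swap_sequence(graph, p, q)
            replay = list(p)
            for swap in seq:
                replay = apply_swap(replay, swap)
            if replay != q:
                raise RuntimeError("swap sequence replay did not reach the target path")
            proof[(a, b)] = seq
    return proof
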