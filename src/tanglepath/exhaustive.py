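"""Exhaustive reference computations for validating the optimized code paths.

Everything here is deliberately brute force and independent of the solver /
automaton implementations it cross-checks: multiplicity vectors are
enumerated directly against the constraint definitions, and substring support
is counted by a sliding window.  Only usable at toy sizes.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from .graph import EdgeGraph
from .tangles import Tangle, oriented_tangle_subgraph
from .traversal import ReadWalk, reverse_walk


def brute_force_multiplicity_min(
    graph: EdgeGraph,
    tangle: Tangle,
    cov_u: float,
    e_rc: set[str],
    max_mult: int | dict[str, int] | None = None,
    require_rc: bool = True,
) -> tuple[float | None, dict[str, int] | None, int]:
    """Minimum absolute-deviation objective by enumerating multiplicity vectors.

    Entries range over 0..bound per edge (default ceil(2·max(cov)/cov_u),
    optionally a per-edge dict); a vector is feasible when flow conservation
    holds at every tangle vertex (boundary edges contributing 1) and, with
    ``require_rc``, every reasonably covered edge is used at least once.
    Returns (objective, argmin vector, number of optima), or (None, None, 0)
    when nothing is feasible.
    """
    edges = sorted(oriented_tangle_subgraph(graph, tangle))
    n = len(edges)
    c = np.array([graph.coverage(oe.edge_id) / cov_u for oe in edges])
    if max_mult is None:
        max_mult = max(1, math.ceil(2.0 * float(c.max())))
    if isinstance(max_mult, dict):
        per_edge = [int(max_mult[oe.edge_id]) for oe in edges]
    else:
        per_edge = [int(max_mult)] * n
    vertices = sorted({graph.start(oe) for oe in edges} | {graph.end(oe) for oe in edges})
    v_index = {v: i for i, v in enumerate(vertices)}
    flow = np.zeros((len(vertices), n))
    rhs = np.zeros(len(vertices))
    for j, oe in enumerate(edges):
        flow[v_index[graph.end(oe)], j] += 1
        flow[v_index[graph.start(oe)], j] -= 1
    for x, y in tangle.boundary_pairs:
        if graph.end(x) in v_index:
            rhs[v_index[graph.end(x)]] -= 1
        if graph.start(y) in v_index:
            rhs[v_index[graph.start(y)]] += 1

    grid = np.array(
        list(product(*(range(b + 1) for b in per_edge))), dtype=np.int64
    ).reshape(-1, n)
    ok = np.all(grid @ flow.T == rhs, axis=1)
    if require_rc:
        for j, oe in enumerate(edges):
            if oe.edge_id in e_rc:
                ok &= grid[:, j] >= 1
    if not ok.any():
        return None, None, 0
    objectives = np.abs(grid - c).sum(axis=1)
    objectives[~ok] = np.inf
    best = int(np.argmin(objectives))
    n_optima = int(np.sum(objectives <= objectives[best] + 1e-9))
    assignment = {oe.edge_id: int(grid[best, j]) for j, oe in enumerate(edges)}
    return float(objectives[best]), assignment, n_optima


def naive_substring_score(steps: list, walks: list[ReadWalk]) -> int:
    """Sliding-window count of reads occurring in ``steps`` (either strand)."""
    count = 0
    text = list(steps)
    for walk in walks:
        hit = False
        for pattern in (list(walk.labels), reverse_walk(walk.labels)):
            m = len(pattern)
            if m == 0 or m > len(text):
                continue
            for i in range(len(text) - m + 1):
                if text[i : i + m] == pattern:
                    hit = True
                    break
            if hit:
                break
        if hit:
            count += 1
    return count
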