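"""Integer multiplicity estimation for tangle edges.

Each tangle edge is assigned an integer copy number ``mult(e)`` so that the
multiplicities are as consistent as possible with coverage — ``cov(e)/Cov_u``
where ``Cov_u`` is the depth of one genomic traversal — subject to flow
conservation (what enters a junction leaves it), boundary edges being
traversed exactly once, and every *reasonably covered* edge (coverage at
least half of ``Cov_u``) being used at least once.  The objective is the
total absolute deviation

    min Σ_e | cov(e)/Cov_u − mult(e) |

which linearizes with one continuous deviation variable per edge, giving a
mixed-integer linear program.  When the at-least-once requirement on
reasonably covered edges makes the program infeasible (e.g. a boundary edge
followed by two well-covered alternatives that cannot both be used), it is
dropped and the solve repeats with ``relaxed=True``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import EdgeGraph, OrientedEdge
from .tangles import Tangle, oriented_tangle_subgraph

logger = logging.getLogger(__name__)

DEFAULT_RC_THRESHOLD = 0.5
DEFAULT_TIME_LIMIT = 300.0
SOLVER_TOLERANCE = 1e-6


class UnsolvableTangleError(RuntimeError):
    """Both the strict and the relaxed multiplicity programs are infeasible."""


@dataclass
class MultiplicityAssignment:
    mult: dict[str, int]
    objective_value: float
    relaxed: bool
    cov_u: float
    oriented: dict[str, OrientedEdge] = field(default_factory=dict)

    def oriented_multiset(self) -> list[OrientedEdge]:
        out: list[OrientedEdge] = []
        for eid in sorted(self.mult):
            out.extend([self.oriented[eid]] * self.mult[eid])
        return out


def reasonably_covered(
    tangle: Tangle,
    graph: EdgeGraph,
    threshold_factor: float = DEFAULT_RC_THRESHOLD,
    cov_u: float | None = None,
) -> set[str]:
    """Tangle edges with coverage at least ``threshold_factor * cov_u`` (E_rc)."""
    if cov_u is None:
        cov_u = tangle.cov_u
    if cov_u is None or cov_u <= 0:
        raise ValueError("cov_u must be set and positive")
    return {
        e for e in tangle.tangle_edges if graph.coverage(e) >= threshold_factor * cov_u
    }


def _flow_system(
    graph: EdgeGraph, tangle: Tangle, edges: list[OrientedEdge]
) -> tuple[np.ndarray, np.ndarray]:
    """Flow-conservation rows: (in − out) · mult == (boundary out − boundary in)."""
    vertices = sorted({graph.start(oe) for oe in edges} | {graph.end(oe) for oe in edges})
    v_index = {v: i for i, v in enumerate(vertices)}
    a = np.zeros((len(vertices), len(edges)))
    rhs = np.zeros(len(vertices))
    for j, oe in enumerate(edges):
        a[v_index[graph.end(oe)], j] += 1.0
        a[v_index[graph.start(oe)], j] -= 1.0
    for x, y in tangle.boundary_pairs:
        vx = graph.end(x)
        vy = graph.start(y)
        if vx in v_index:
            rhs[v_index[vx]] -= 1.0  # boundary edge delivers one unit in
        if vy in v_index:
            rhs[v_index[vy]] += 1.0  # boundary edge removes one unit
    return a, rhs


def solve_multiplicities(
    tangle: Tangle,
    graph: EdgeGraph,
    e_rc: set[str] | None = None,
    solver_time_limit: float = DEFAULT_TIME_LIMIT,
    cov_u: float | None = None,
    max_mult: int | dict[str, int] | None = None,
    tune_cov_u: bool = False,
) -> MultiplicityAssignment:
    """Solve the multiplicity MILP for one tangle.

    Falls back to the relaxed program (no at-least-once requirement on E_rc)
    when the strict one is infeasible.  With ``tune_cov_u`` the solve is
    repeated over {0.9, 1.0, 1.1} × cov_u and the lowest objective kept.
    """
    if cov_u is None:
        cov_u = tangle.cov_u
    if cov_u is None or cov_u <= 0:
        raise ValueError("cov_u must be set and positive")
    if e_rc is None:
        e_rc = reasonably_covered(tangle, graph, cov_u=cov_u)
    factors = (1.0, 0.9, 1.1) if tune_cov_u else (1.0,)
    best: MultiplicityAssignment | None = None
    for factor in factors:
        assignment = _solve_at_cov_u(
            tangle, graph, e_rc, cov_u * factor, solver_time_limit, max_mult
        )
        if best is None or assignment.objective_value < best.objective_value:
            best = assignment
    assert best is not None
    return best


def _solve_at_cov_u(
    tangle: Tangle,
    graph: EdgeGraph,
    e_rc: set[str],
    cov_u: float,
    time_limit: float,
    max_mult: int | dict[str, int] | None,
) -> MultiplicityAssignment:
    edges = sorted(oriented_tangle_subgraph(graph, tangle))
    n = len(edges)
    if n == 0:
        raise ValueError("tangle has no edges")
    c = np.array([graph.coverage(oe.edge_id) / cov_u for oe in edges])
    if max_mult is None:
        max_mult = max(2, math.ceil(4.0 * float(c.max())))
    if isinstance(max_mult, dict):
        ub = np.array([float(max_mult[oe.edge_id]) for oe in edges])
    else:
        ub = np.full(n, float(max_mult))
    a_flow, rhs = _flow_system(graph, tangle, edges)

    for relaxed in (False, True):
        lb = np.zeros(n)
        if not relaxed:
            for j, oe in enumerate(edges):
                if oe.edge_id in e_rc:
                    lb[j] = 1.0
        solution = _run_milp(c, a_flow, rhs, lb, ub, time_limit)
        if solution is None:
            continue
        mult = {oe.edge_id: int(round(solution[j])) for j, oe in enumerate(edges)}
        objective = float(
            sum(abs(c[j] - mult[oe.edge_id]) for j, oe in enumerate(edges))
        )
        if relaxed:
            logger.warning(
                "tangle %s: strict program infeasible; relaxed solve used",
                tangle.tangle_id,
            )
        return MultiplicityAssignment(
            mult=mult,
            objective_value=objective,
            relaxed=relaxed,
            cov_u=cov_u,
            oriented={oe.edge_id: oe for oe in edges},
        )
    raise UnsolvableTangleError(
        f"tangle {tangle.tangle_id}: strict and relaxed multiplicity programs "
        "are both infeasible"
    )


def _run_milp(
    c: np.ndarray,
    a_flow: np.ndarray,
    rhs: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    time_limit: float,
) -> np.ndarray | None:
    """Minimize Σ d_e with d_e >= |c_e − m_e|; returns m or None if infeasible."""
    n = len(c)
    # variables: [m_0..m_{n-1}, d_0..d_{n-1}]
    objective = np.concatenate([np.zeros(n), np.ones(n)])
    integrality = np.concatenate([np.ones(n), np.zeros(n)])
    bounds = Bounds(
        lb=np.concatenate([lb, np.zeros(n)]),
        ub=np.concatenate([ub, np.full(n, np.inf)]),
    )
    flow = LinearConstraint(
        np.hstack([a_flow, np.zeros_like(a_flow)]), rhs, rhs
    )
    eye = np.eye(n)
    # d + m >= c  and  d − m >= −c
    dev = LinearConstraint(
        np.vstack([np.hstack([eye, eye]), np.hstack([-eye, eye])]),
        np.concatenate([c, -c]),
        np.full(2 * n, np.inf),
    )
    res = milp(
        objective,
        integrality=integrality,
        bounds=bounds,
        constraints=[flow, dev],
        options={"time_limit": time_limit},
    )
    if res.status == 1 and res.x is not None:
        logger.warning("MILP time limit reached; using best incumbent")
        return res.x[:n]
    if not res.success or res.x is None:
        return None
    return res.x[:n]
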