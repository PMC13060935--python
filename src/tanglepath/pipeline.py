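"""End-to-end tangle resolution: detect → Cov_u → MILP → Eulerian → optimize → emit.

Tangles are processed in isolation: a failure in any stage is recorded in
that tangle's report (with the failing stage) and never aborts the batch.
The JSON report is always written, including for unsupported or failed
tangles, and embeds the run configuration verbatim for reproducibility.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

from .gfa import load_gfa
from .graph import EdgeGraph, OrientedEdge, attach_coverage, to_edge_graph
from .metrics import (
    TangleReport,
    coverage_divergence,
    emit_sequence,
    path_line,
    unsupported_fraction,
    write_bundle,
)
from .multiplicity import (
    DEFAULT_RC_THRESHOLD,
    DEFAULT_TIME_LIMIT,
    UnsolvableTangleError,
    reasonably_covered,
    solve_multiplicities,
)
from .tangles import (
    DEFAULT_COV_WINDOW,
    DEFAULT_MAX_TANGLE_FRACTION,
    DEFAULT_MIN_UNIQUE_LEN,
    Tangle,
    TangleError,
    classify_unique_edges,
    detect_tangles,
    estimate_cov_u,
    manual_tangle,
)
from .traversal import (
    DEFAULT_RESTARTS,
    DEFAULT_SEED,
    NoEulerianPathError,
    WalkScorer,
    load_gaf,
    optimize_tangle_paths,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    graph: str
    coverage: str | None = None
    alignments: str | None = None
    out_dir: str = "tanglepath_out"
    boundary: list[str] | None = None  # manual mode: x1+,y1-[,x2+,y2-]
    min_unique_len: int = DEFAULT_MIN_UNIQUE_LEN
    unique_cov_window: tuple[float, float] = DEFAULT_COV_WINDOW
    max_tangle_fraction: float = DEFAULT_MAX_TANGLE_FRACTION
    cov_u: float | None = None
    rc_threshold: float = DEFAULT_RC_THRESHOLD
    milp_time_limit: float = DEFAULT_TIME_LIMIT
    tune_cov_u: bool = False
    restarts: int = DEFAULT_RESTARTS
    seed: int = DEFAULT_SEED
    trim_boundary: bool = False
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["unique_cov_window"] = list(self.unique_cov_window)
        return d


@dataclass
class TangleResult:
    tangle: Tangle
    report: TangleReport
    paths: list = field(default_factory=list)
    ok: bool = False


def _parse_boundary(spec: list[str]) -> list[OrientedEdge]:
    out = []
    for token in spec:
        token = token.strip()
        if not token or token[-1] not in "+-":
            raise TangleError(f"boundary token {token!r} must end in + or -")
        out.append(OrientedEdge(token[:-1], token[-1]))
    return out


def select_tangles(graph: EdgeGraph, config: RunConfig) -> list[Tangle]:
    """Auto-detect tangles, or build one from user-named boundary edges."""
    if config.boundary:
        return [manual_tangle(graph, _parse_boundary(config.boundary))]
    unique = classify_unique_edges(
        graph,
        min_length=config.min_unique_len,
        cov_low=config.unique_cov_window[0],
        cov_high=config.unique_cov_window[1],
    )
    return detect_tangles(graph, unique, config.max_tangle_fraction)


def load_inputs(config: RunConfig) -> EdgeGraph:
    graph = to_edge_graph(load_gfa(config.graph))
    attach_coverage(graph, config.coverage)
    return graph


def resolve_tangle(
    graph: EdgeGraph, tangle: Tangle, config: RunConfig
) -> TangleResult:
    """Run the full per-tangle stage chain; failures become report records."""
    timings: dict[str, float] = {}
    stage = "cov_u"
    try:
        t0 = time.perf_counter()
        tangle.cov_u = estimate_cov_u(tangle, graph, config.cov_u)
        timings[stage] = time.perf_counter() - t0

        stage = "milp"
        t0 = time.perf_counter()
        e_rc = reasonably_covered(tangle, graph, config.rc_threshold)
        assignment = solve_multiplicities(
            tangle,
            graph,
            e_rc,
            solver_time_limit=config.milp_time_limit,
            tune_cov_u=config.tune_cov_u,
        )
        timings[stage] = time.perf_counter() - t0

        stage = "alignments"
        t0 = time.perf_counter()
        walks = (
            load_gaf(config.alignments, graph, tangle) if config.alignments else []
        )
        timings[stage] = time.perf_counter() - t0

        stage = "traversal"
        t0 = time.perf_counter()
        stats: dict = {}
        paths = optimize_tangle_paths(
            graph,
            tangle,
            assignment,
            walks,
            restarts=config.restarts,
            rng_seed=config.seed,
            stats=stats,
        )
        timings[stage] = time.perf_counter() - t0

        stage = "metrics"
        cov_div = coverage_divergence(assignment, tangle, graph)
        unsupported, no_aln = unsupported_fraction(paths, walks)
        total_score = len(WalkScorer(walks).supported([p.steps for p in paths]))
        restart_scores = stats.get("restart_scores", [])
        best_score = max(restart_scores) if restart_scores else total_score
        report = TangleReport(
            tangle_id=tangle.tangle_id,
            coverage_divergence=cov_div,
            unsupported_read_fraction=unsupported,
            path_length_bp=0,
            relaxed_milp=assignment.relaxed,
            score=total_score,
            restarts_agreeing=sum(1 for s in restart_scores if s == best_score),
            n_walks=len(walks),
            no_alignments=no_aln,
            n_pairs=tangle.n_pairs,
            status="resolved",
            extra={
                "milp_objective": assignment.objective_value,
                "cov_u": tangle.cov_u,
                "mult": assignment.mult,
                "timings_s": {k: round(v, 4) for k, v in timings.items()},
                "config": config.as_dict(),
            },
        )
        return TangleResult(tangle, report, paths, ok=True)
    except (TangleError, UnsolvableTangleError, NoEulerianPathError, ValueError) as exc:
        logger.error("tangle %s failed at stage %s: %s", tangle.tangle_id, stage, exc)
        report = TangleReport(
            tangle_id=tangle.tangle_id,
            coverage_divergence=0.0,
            unsupported_read_fraction=0.0,
            path_length_bp=0,
            relaxed_milp=False,
            score=0,
            n_pairs=tangle.n_pairs,
            status="failed",
            reason=f"{stage}: {exc}",
            extra={"config": config.as_dict()},
        )
        return TangleResult(tangle, report, [], ok=False)


def run(config: RunConfig) -> list[TangleResult]:
    """Resolve every selected tangle and write the per-tangle output bundles.

    Returns one result per tangle; the process-level convention is success
    when at least one tangle resolved.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    graph = load_inputs(config)
    if config.boundary:
        # manual boundaries are a user contract: validation errors propagate
        tangles = select_tangles(graph, config)
    else:
        try:
            tangles = select_tangles(graph, config)
        except TangleError as exc:
            logger.error("tangle detection failed: %s", exc)
            report = TangleReport(
                tangle_id="detection",
                coverage_divergence=0.0,
                unsupported_read_fraction=0.0,
                path_length_bp=0,
                relaxed_milp=False,
                score=0,
                status="failed",
                reason=f"detection: {exc}",
                extra={"config": config.as_dict()},
            )
            write_bundle(config.out_dir, "detection", [], report, [])
            dummy = Tangle("detection", [], set(), resolvable=False, reason=str(exc))
            return [TangleResult(dummy, report, [], ok=False)]
    logger.info("selected %d tangle(s)", len(tangles))
    results: list[TangleResult] = []
    for tangle in tangles:
        if not tangle.resolvable:
            report = TangleReport(
                tangle_id=tangle.tangle_id,
                coverage_divergence=0.0,
                unsupported_read_fraction=0.0,
                path_length_bp=0,
                relaxed_milp=False,
                score=0,
                n_pairs=tangle.n_pairs,
                status="unsupported",
                reason=tangle.reason,
                extra={"config": config.as_dict()},
            )
            results.append(TangleResult(tangle, report, [], ok=False))
            write_bundle(config.out_dir, tangle.tangle_id, [], report, [])
            continue
        result = resolve_tangle(graph, tangle, config)
        records, lines = [], []
        if result.ok:
            total_bp = 0
            for pair_idx, path in enumerate(result.paths):
                rid = f"{tangle.tangle_id}_pair{pair_idx}"
                desc = (
                    f"score={path.score} cov_div={result.report.coverage_divergence:.4f} "
                    f"unsupported={result.report.unsupported_read_fraction:.4f}"
                )
                rec = emit_sequence(
                    path, graph, rid, desc, trim_boundary=config.trim_boundary
                )
                total_bp += len(rec.seq)
                records.append(rec)
                lines.append(path_line(tangle.tangle_id, path))
            result.report.path_length_bp = total_bp
        write_bundle(config.out_dir, tangle.tangle_id, records, result.report, lines)
        results.append(result)
    return results
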