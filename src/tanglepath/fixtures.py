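"""Synthetic ground-truth tangles: genome, graph, coverage and reads.

Emulates the situation the traverser is built for: a repeat array of
near-identical units flanked by long unique sequence.  A genome is simulated,
its de Bruijn graph (exact k-mer collapse, unitig-compressed) is written as a
GFA with sequence on nodes and k−1 overlaps, per-node coverage is planted as
(multiplicity in the true traversal) × Cov_u × (1 + ε) with bounded
multiplicative noise, and reads are sampled as exact subwalks of the true
traversal and written as GAF.  Higher unit divergence yields less tangled
graphs (homogeneous arrays are the hard case); the generator is
forward-strand only and read walks carry no base-level errors — the pipeline
consumes aligner output, not raw reads.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .gfa import Link, Segment, SegmentGraph, write_gfa
from .graph import FORWARD, EdgeGraph, OrientedEdge, attach_coverage, to_edge_graph
from .traversal import ReadWalk

DEFAULT_K = 21
DEFAULT_COV_U = 30.0
DEFAULT_NOISE = 0.1
DEFAULT_FLANK_LEN = 800
ALPHABET = "ACGT"


@dataclass
class PlantedTangle:
    genome: str
    true_path: list[OrientedEdge]
    segment_graph: SegmentGraph
    graph: EdgeGraph
    cov_u_true: float
    noise: float
    mult_true: dict[str, int]
    unit_seqs: list[str]
    mutation_windows: list[str]
    k: int
    walks: list[ReadWalk] = field(default_factory=list)


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(length))


def random_flow_tangle(
    rng_seed: int,
    n_vertices: int = 4,
    walk_len: int = 8,
    parallel_prob: float = 0.3,
    n_decoys: int = 0,
    cov_u: float = DEFAULT_COV_U,
    noise: float = DEFAULT_NOISE,
    seg_len: int = 50,
):
    """Small tangle with a planted traversal, for oracle cross-checks.

    A random walk of ``walk_len`` steps over ``n_vertices`` junctions from a
    source to a sink junction plants a flow-feasible traversal; each step
    either reuses the segment already connecting that junction pair or (with
    ``parallel_prob``) creates a parallel segment.  ``n_decoys`` extra
    segments between random junctions get multiplicity 0 and coverage well
    below the reasonably-covered threshold.  Returns
    ``(graph, tangle, mult_true, true_internal_walk)``; the tangle has one
    boundary pair and ``cov_u`` set, coverage is multiplicity × cov_u × (1+ε).
    """
    from .tangles import Tangle  # local import: avoid module cycle

    rng = random.Random(rng_seed)
    n_vertices = max(2, n_vertices)
    # vertices 0..n-1; walk from 0 to n-1
    walk_vertices = [0]
    while len(walk_vertices) <= walk_len:
        remaining = walk_len - (len(walk_vertices) - 1)
        v = walk_vertices[-1]
        if remaining == 1:
            nxt = n_vertices - 1
        else:
            nxt = rng.randrange(n_vertices)
        walk_vertices.append(nxt)
    seg_between: dict[tuple[int, int], list[str]] = {}
    names: list[str] = []

    def new_segment(u: int, v: int) -> str:
        name = f"e{len(names)}"
        names.append(name)
        seg_between.setdefault((u, v), []).append(name)
        return name

    walk_segments: list[str] = []
    for u, v in zip(walk_vertices, walk_vertices[1:]):
        existing = seg_between.get((u, v), [])
        if existing and rng.random() >= parallel_prob:
            walk_segments.append(rng.choice(existing))
        else:
            walk_segments.append(new_segment(u, v))
    mult_true = {name: walk_segments.count(name) for name in names}
    seg_vertices = {
        name: pair for pair, segs in seg_between.items() for name in segs
    }
    for _ in range(n_decoys):
        u = rng.randrange(n_vertices)
        v = rng.randrange(n_vertices)
        name = new_segment(u, v)
        mult_true[name] = 0
        seg_vertices[name] = (u, v)

    sg = SegmentGraph()
    sg.segments["x"] = Segment("x", _random_dna(rng, seg_len), seg_len)
    sg.segments["y"] = Segment("y", _random_dna(rng, seg_len), seg_len)
    for name in names:
        sg.segments[name] = Segment(name, _random_dna(rng, seg_len), seg_len)
    ends_at: dict[int, list[str]] = {0: ["x"]}
    starts_at: dict[int, list[str]] = {n_vertices - 1: ["y"]}
    for name in names:
        u, v = seg_vertices[name]
        starts_at.setdefault(u, []).append(name)
        ends_at.setdefault(v, []).append(name)
    for v in range(n_vertices):
        for a in ends_at.get(v, []):
            for b in starts_at.get(v, []):
                sg.links.append(Link(a, "+", b, "+", 0))
    graph = to_edge_graph(sg)
    coverage = {"x": cov_u * (1 + rng.uniform(-noise, noise)),
                "y": cov_u * (1 + rng.uniform(-noise, noise))}
    for name in names:
        m = mult_true[name]
        if m > 0:
            coverage[name] = m * cov_u * (1 + rng.uniform(-noise, noise))
        else:
            coverage[name] = 0.25 * cov_u * (1 + rng.uniform(-noise, noise))
    attach_coverage(graph, coverage)
    tangle = Tangle(
        "rand",
        [(OrientedEdge("x", FORWARD), OrientedEdge("y", FORWARD))],
        set(names),
        cov_u=cov_u,
        boundary_segments={"x", "y"},
    )
    true_walk = [OrientedEdge(s, FORWARD) for s in walk_segments]
    return graph, tangle, mult_true, true_walk


def planted_assignment(graph: EdgeGraph, tangle, mult_true: dict[str, int]):
    """Wrap planted multiplicities as an assignment (for traversal-only tests)."""
    from .multiplicity import MultiplicityAssignment
    from .tangles import oriented_tangle_subgraph

    oriented = {oe.edge_id: oe for oe in oriented_tangle_subgraph(graph, tangle)}
    cov_u = tangle.cov_u or DEFAULT_COV_U
    objective = sum(
        abs(graph.coverage(e) / cov_u - mult_true.get(e, 0)) for e in tangle.tangle_edges
    )
    return MultiplicityAssignment(
        mult=dict(mult_true),
        objective_value=objective,
        relaxed=False,
        cov_u=cov_u,
        oriented=oriented,
    )


def _mutate(rng: random.Random, seq: str, n_mut: int) -> tuple[str, list[int]]:
    positions = sorted(rng.sample(range(len(seq)), n_mut)) if n_mut else []
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in ALPHABET if b != out[p]])
    return "".join(out), positions


def _compress_dbg(genome: str, k: int) -> tuple[SegmentGraph, list[str], dict[str, int]]:
    """Unitig-compressed de Bruijn graph of one strand of ``genome``.

    Returns the segment graph (overlaps k−1), the genome's traversal as a
    list of segment names, and true multiplicities (counts in the traversal).
    """
    if len(genome) < k:
        raise ValueError("genome shorter than k")
    kmer_walk = [genome[i : i + k] for i in range(len(genome) - k + 1)]
    kmers = sorted(set(kmer_walk))
    out_of: dict[str, list[str]] = {}
    in_of: dict[str, list[str]] = {}
    for km in kmers:
        out_of.setdefault(km[:-1], []).append(km)
        in_of.setdefault(km[1:], []).append(km)

    def linear(vertex: str) -> bool:
        return len(out_of.get(vertex, [])) == 1 and len(in_of.get(vertex, [])) == 1

    unitig_of: dict[str, tuple[int, int]] = {}  # kmer -> (unitig index, offset)
    chains: list[list[str]] = []
    for km in kmers:
        if km in unitig_of:
            continue
        if linear(km[:-1]):
            continue  # not a unitig start
        chain = [km]
        while True:
            end_v = chain[-1][1:]
            if not linear(end_v):
                break
            nxt = out_of[end_v][0]
            if nxt in unitig_of or nxt == chain[0]:
                break
            chain.append(nxt)
        for off, member in enumerate(chain):
            unitig_of[member] = (len(chains), off)
        chains.append(chain)
    for km in kmers:  # pure cycles of linear vertices (rare; repeat-only loops)
        if km in unitig_of:
            continue
        chain = [km]
        while True:
            nxt = out_of[chain[-1][1:]][0]
            if nxt == chain[0] or nxt in unitig_of:
                break
            chain.append(nxt)
        for off, member in enumerate(chain):
            unitig_of[member] = (len(chains), off)
        chains.append(chain)

    # deterministic names by first occurrence in the genome walk
    order: list[int] = []
    seen: set[int] = set()
    for km in kmer_walk:
        idx = unitig_of[km][0]
        if idx not in seen:
            seen.add(idx)
            order.append(idx)
    for idx in range(len(chains)):
        if idx not in seen:
            order.append(idx)
    width = len(str(max(len(chains) - 1, 1)))
    names = {}
    for rank, idx in enumerate(order):
        names[idx] = f"u{rank:0{width}d}"

    sg = SegmentGraph()
    for idx, chain in enumerate(chains):
        seq = chain[0] + "".join(member[-1] for member in chain[1:])
        sg.segments[names[idx]] = Segment(names[idx], seq, len(seq))
    link_seen = set()
    for idx, chain in enumerate(chains):
        end_v = chain[-1][1:]
        for nxt in out_of.get(end_v, []):
            jdx, off = unitig_of[nxt]
            if off != 0:
                continue
            key = (names[idx], names[jdx])
            if key not in link_seen:
                link_seen.add(key)
                sg.links.append(Link(names[idx], "+", names[jdx], "+", k - 1))
    sg.links.sort(key=lambda ln: (ln.from_seg, ln.to_seg))

    walk_names: list[str] = []
    for km in kmer_walk:
        idx, off = unitig_of[km]
        if off == 0 or not walk_names:
            walk_names.append(names[idx])
    mult: dict[str, int] = {}
    for name in walk_names:
        mult[name] = mult.get(name, 0) + 1
    return sg, walk_names, mult


def plant_repeat_tangle(
    n_units: int,
    unit_len: int = 200,
    divergence: float = 0.02,
    rng_seed: int = 0,
    k: int = DEFAULT_K,
    flank_len: int = DEFAULT_FLANK_LEN,
    cov_u: float = DEFAULT_COV_U,
    noise: float = DEFAULT_NOISE,
) -> PlantedTangle:
    """Simulate a repeat-array tangle with known traversal and coverage.

    ``divergence`` is the per-unit point-mutation fraction; 0 gives a single
    collapsed repeat edge of multiplicity ``n_units``.  Coverage noise is
    multiplicative uniform ±``noise``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = random.Random(rng_seed)
    base_unit = _random_dna(rng, unit_len)
    n_mut = round(divergence * unit_len)
    if divergence > 0:
        n_mut = max(1, n_mut)
    units: list[str] = []
    mutation_windows: list[str] = []
    offsets: list[tuple[int, list[int]]] = []
    for _ in range(n_units):
        unit, positions = _mutate(rng, base_unit, n_mut)
        units.append(unit)
        offsets.append((len(units) - 1, positions))
    flank_l = _random_dna(rng, flank_len)
    flank_r = _random_dna(rng, flank_len)
    genome = flank_l + "".join(units) + flank_r
    for unit_idx, positions in offsets:
        for p in positions:
            absolute = flank_len + unit_idx * unit_len + p
            mutation_windows.append(genome[absolute - (k - 1) : absolute + k])

    sg, walk_names, mult = _compress_dbg(genome, k)
    coverage = {
        name: mult.get(name, 0) * cov_u * (1.0 + rng.uniform(-noise, noise))
        for name in sg.segments
    }
    graph = attach_coverage(to_edge_graph(sg), coverage)
    true_path = [OrientedEdge(name, FORWARD) for name in walk_names]
    return PlantedTangle(
        genome=genome,
        true_path=true_path,
        segment_graph=sg,
        graph=graph,
        cov_u_true=cov_u,
        noise=noise,
        mult_true=mult,
        unit_seqs=units,
        mutation_windows=mutation_windows,
        k=k,
    )


def sample_read_walks(
    planted: PlantedTangle,
    n_reads: int,
    min_len: int = 2,
    max_len: int = 6,
    rng_seed: int = 0,
) -> list[ReadWalk]:
    """Uniform random subwalks of the true traversal, ``min_len..max_len`` steps.

    Walks are stored on ``planted.walks`` (replacing any previous sample) and
    returned; each is an exact substring of the true path by construction.
    """
    if len(planted.true_path) < 2:
        raise ValueError("true path too short to sample read walks")
    rng = random.Random(rng_seed)
    min_len = max(2, min_len)
    walks: list[ReadWalk] = []
    for idx in range(n_reads):
        length = rng.randint(min_len, max(min_len, max_len))
        length = min(length, len(planted.true_path))
        start = rng.randint(0, len(planted.true_path) - length)
        labels = list(planted.true_path[start : start + length])
        walks.append(ReadWalk(f"read{idx}", labels))
    planted.walks = walks
    return walks


def _walk_length_bp(planted: PlantedTangle, labels: list[OrientedEdge]) -> int:
    total = 0
    for i, oe in enumerate(labels):
        total += planted.graph.length(oe.edge_id)
        if i > 0:
            total -= planted.graph.overlap(labels[i - 1], oe)
    return total


def write_gaf(planted: PlantedTangle, walks: list[ReadWalk], path: str | Path) -> None:
    with open(path, "w") as fh:
        for walk in walks:
            length = _walk_length_bp(planted, walk.labels)
            path_col = "".join(
                (">" if oe.orient == FORWARD else "<") + oe.edge_id for oe in walk.labels
            )
            fh.write(
                f"{walk.read_id}\t{length}\t0\t{length}\t+\t{path_col}"
                f"\t{length}\t0\t{length}\t{length}\t{length}\t60\n"
            )


def write_fixture(planted: PlantedTangle, out_dir: str | Path) -> dict[str, Path]:
    """Write graph.gfa, coverage.tsv, reads.gaf and truth.json (byte-stable per seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gfa": out / "graph.gfa",
        "coverage": out / "coverage.tsv",
        "gaf": out / "reads.gaf",
        "truth": out / "truth.json",
    }
    write_gfa(planted.segment_graph, paths["gfa"])
    with open(paths["coverage"], "w") as fh:
        fh.write("node\tcoverage\n")
        for name in sorted(planted.graph.edges):
            fh.write(f"{name}\t{planted.graph.coverage(name):.4f}\n")
    write_gaf(planted, planted.walks, paths["gaf"])
    truth = {
        "genome": planted.genome,
        "true_path": [f"{oe.edge_id}{oe.orient}" for oe in planted.true_path],
        "mult": planted.mult_true,
        "cov_u": planted.cov_u_true,
        "k": planted.k,
        "units": planted.unit_seqs,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
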