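"""Reference-free quality metrics and model-sequence output.

Model sequences are deliberately emitted standalone (FASTA), never patched
into a scaffold: a traversal is a plausible, data-consistent reconstruction,
not a verified assembly, and downstream users must decide how to incorporate
it.  Two metrics accompany every traversal, reported but never gated (no
threshold separates plausible from implausible values):

* coverage divergence — mean over tangle edges of |cov(e)/Cov_u − mult(e)|,
  the residual of the multiplicity fit;
* unsupported read fraction — the share of tangle read walks that are not
  exact substrings of any output path.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .graph import EdgeGraph
from .multiplicity import MultiplicityAssignment
from .tangles import Tangle
from .traversal import ReadWalk, TraversalPath, WalkScorer


@dataclass
class TangleReport:
    tangle_id: str
    coverage_divergence: float
    unsupported_read_fraction: float
    path_length_bp: int
    relaxed_milp: bool
    score: int
    restarts_agreeing: int = 0
    n_walks: int = 0
    no_alignments: bool = False
    n_pairs: int = 1
    status: str = "resolved"
    reason: str = ""
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TangleReport":
        return cls(**json.loads(text))


def coverage_divergence(
    assignment: MultiplicityAssignment, tangle: Tangle, graph: EdgeGraph
) -> float:
    """Mean absolute deviation between coverage-implied and assigned copy numbers."""
    edges = sorted(tangle.tangle_edges)
    if not edges:
        raise ValueError("tangle has no edges")
    total = sum(
        abs(graph.coverage(e) / assignment.cov_u - assignment.mult.get(e, 0))
        for e in edges
    )
    return total / len(edges)


def unsupported_fraction(
    paths: list[TraversalPath], walks: list[ReadWalk]
) -> tuple[float, bool]:
    """(fraction of walks matching no output path, no-alignments flag).

    A walk is supported when its label sequence (either strand) is an exact
    contiguous run in at least one of the paths; with no walks the fraction
    is defined as 0 and the flag is set.
    """
    if not walks:
        return 0.0, True
    scorer = WalkScorer(walks)
    supported = scorer.supported([p.steps for p in paths])
    return 1.0 - len(supported) / len(walks), False


def path_sequence(path: TraversalPath, graph: EdgeGraph) -> str:
    """Concatenate step sequences, removing each junction overlap once.

    Reverse-oriented steps contribute their reverse complement; the stored
    link overlap is trimmed from the start of every step after the first.
    """
    parts: list[str] = []
    for idx, oe in enumerate(path.steps):
        seq = graph.sequence(oe)
        if idx > 0:
            trim = graph.overlap(path.steps[idx - 1], oe)
            seq = seq[trim:]
        parts.append(seq)
    return "".join(parts)


def emit_sequence(
    path: TraversalPath,
    graph: EdgeGraph,
    record_id: str,
    description: str = "",
    trim_boundary: bool = False,
) -> SeqRecord:
    """Model sequence of one traversal as a FASTA record.

    Boundary edges are included in full by default so the patch anchors are
    present for downstream alignment; ``trim_boundary`` drops them, leaving
    tangle-internal sequence only.
    """
    steps = path.steps
    if trim_boundary:
        if len(steps) <= 2:
            raise ValueError("path has no internal steps to emit")
        trimmed = TraversalPath(steps[1:-1], path.score)
        seq = path_sequence(trimmed, graph)
    else:
        seq = path_sequence(path, graph)
    return SeqRecord(Seq(seq), id=record_id, description=description)


def path_line(tangle_id: str, path: TraversalPath) -> str:
    """GFA-P-line-like rendering: ``tangleID<TAB>x1+,e3+,e1-,...,y1+``."""
    return f"{tangle_id}\t" + ",".join(f"{oe.edge_id}{oe.orient}" for oe in path.steps)


def write_bundle(
    out_dir: str | Path,
    tangle_id: str,
    records: list[SeqRecord],
    report: TangleReport,
    lines: list[str],
) -> None:
    """Per-tangle output bundle: FASTA, JSON report, path lines."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records:
        SeqIO.write(records, out / f"{tangle_id}.fasta", "fasta")
    (out / f"{tangle_id}.json").write_text(report.to_json() + "\n")
    if lines:
        (out / f"{tangle_id}.paths.tsv").write_text("\n".join(lines) + "\n")
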