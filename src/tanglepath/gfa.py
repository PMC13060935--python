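"""GFA 1.x reading and writing (S and L lines).

Assembly graphs arrive with sequence stored on nodes (segments); this module
parses them into a minimal in-memory segment graph that the junction-as-vertex
transform in :mod:`tanglepath.graph` consumes.  Only the dialect produced by
de Bruijn / multiplex-DBG assemblers is supported: S lines (optionally with a
coverage tag), L lines whose overlap is ``<int>M`` or ``*``.  P/W lines are
ignored with a log message; anything else malformed raises
:class:`GfaParseError` naming the offending line.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"^(\d+)M$")

# GFA tags that carry per-segment depth of coverage, in precedence order.
COVERAGE_TAGS = ("dp", "DP", "rd", "ll")


class GfaParseError(ValueError):
    """Raised on a malformed or unsupported GFA line; message names the line number."""


@dataclass
class Segment:
    name: str
    sequence: str | None
    length: int
    coverage: float | None = None


@dataclass
class Link:
    """One L line: oriented segment ``from`` followed by oriented segment ``to``."""

    from_seg: str
    from_orient: str
    to_seg: str
    to_orient: str
    overlap: int


@dataclass
class SegmentGraph:
    """Node-sequence graph exactly as read from a GFA file."""

    segments: dict[str, Segment] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_links(self) -> int:
        return len(self.links)


def _parse_overlap(cigar: str, lineno: int) -> int:
    if cigar == "*":
        return 0
    m = _CIGAR_RE.match(cigar)
    if m is None:
        raise GfaParseError(
            f"line {lineno}: unsupported link overlap CIGAR {cigar!r} "
            "(only '<int>M' or '*' are handled)"
        )
    return int(m.group(1))


def _parse_coverage_tag(fields: list[str], lineno: int) -> float | None:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise GfaParseError(f"line {lineno}: malformed tag field {f!r}")
        tags[parts[0]] = (parts[1], parts[2])
    for tag in COVERAGE_TAGS:
        if tag in tags:
            typ, val = tags[tag]
            try:
                return float(val)
            except ValueError as exc:
                raise GfaParseError(
                    f"line {lineno}: coverage tag {tag}:{typ}:{val} is not numeric"
                ) from exc
    return None


def load_gfa(path: str | Path) -> SegmentGraph:
    """Parse a GFA 1.x file into a :class:`SegmentGraph`.

    An empty file yields an empty graph.  Both orientations of every segment
    are representable downstream; links are stored as written.
    """
    graph = SegmentGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            rec = fields[0]
            if rec == "H":
                continue
            if rec == "S":
                if len(fields) < 3:
                    raise GfaParseError(f"line {lineno}: S line needs name and sequence")
                name, seq = fields[1], fields[2]
                cov = _parse_coverage_tag(fields[3:], lineno)
                length = None
                for f in fields[3:]:
                    if f.startswith("LN:i:"):
                        length = int(f[5:])
                if seq == "*":
                    if length is None:
                        raise GfaParseError(
                            f"line {lineno}: segment {name} has no sequence and no LN tag"
                        )
                    graph.segments[name] = Segment(name, None, length, cov)
                else:
                    graph.segments[name] = Segment(name, seq, len(seq), cov)
            elif rec == "L":
                if len(fields) < 6:
                    raise GfaParseError(f"line {lineno}: L line needs 5 fields")
                fr, fo, to, too, cigar = fields[1:6]
                if fo not in "+-" or too not in "+-":
                    raise GfaParseError(f"line {lineno}: bad orientation in L line")
                graph.links.append(Link(fr, fo, to, too, _parse_overlap(cigar, lineno)))
            elif rec in ("P", "W"):
                logger.info("ignoring %s line %d (paths are not used)", rec, lineno)
            elif rec == "C":
                raise GfaParseError(f"line {lineno}: containment (C) lines are unsupported")
            else:
                raise GfaParseError(f"line {lineno}: unknown record type {rec!r}")
    for link in graph.links:
        for seg in (link.from_seg, link.to_seg):
            if seg not in graph.segments:
                raise GfaParseError(f"link references unknown segment {seg!r}")
    return graph


def write_gfa(graph: SegmentGraph, path: str | Path, coverage_tag: str | None = None) -> None:
    """Write a :class:`SegmentGraph` back to GFA 1.x (fixtures and debugging)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name in sorted(graph.segments):
            seg = graph.segments[name]
            seq = seg.sequence if seg.sequence is not None else "*"
            extra = ""
            if seg.sequence is None:
                extra += f"\tLN:i:{seg.length}"
            if coverage_tag and seg.coverage is not None:
                extra += f"\t{coverage_tag}:f:{seg.coverage:g}"
            fh.write(f"S\t{name}\t{seq}{extra}\n")
        for link in graph.links:
            fh.write(
                f"L\t{link.from_seg}\t{link.from_orient}\t{link.to_seg}"
                f"\t{link.to_orient}\t{link.overlap}M\n"
            )
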