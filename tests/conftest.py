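"""Shared builders for hand-made assembly graphs and tangles."""

from __future__ import annotations

import pytest

from tanglepath.gfa import Link, Segment, SegmentGraph
from tanglepath.graph import OrientedEdge, attach_coverage, to_edge_graph
from tanglepath.tangles import Tangle


def F(name: str) -> OrientedEdge:
    return OrientedEdge(name, "+")


def R(name: str) -> OrientedEdge:
    return OrientedEdge(name, "-")


def make_segment_graph(
    segments: dict[str, str] | list[str],
    links: list[tuple],
    default_seq: str = "ACGTACGTAC",
) -> SegmentGraph:
    """Segments as {name: seq} or [names]; links as (a, b) for +/+ 0M, or
    (a, oa, b, ob[, overlap])."""
    sg = SegmentGraph()
    if isinstance(segments, dict):
        for name, seq in segments.items():
            sg.segments[name] = Segment(name, seq, len(seq))
    else:
        for name in segments:
            sg.segments[name] = Segment(name, default_seq, len(default_seq))
    for link in links:
        if len(link) == 2:
            sg.links.append(Link(link[0], "+", link[1], "+", 0))
        else:
            overlap = link[4] if len(link) > 4 else 0
            sg.links.append(Link(link[0], link[1], link[2], link[3], overlap))
    return sg


def make_edge_graph(segments, links, coverage=None, **kw):
    graph = to_edge_graph(make_segment_graph(segments, links, **kw))
    if coverage is not None:
        attach_coverage(graph, coverage)
    return graph


@pytest.fixture
def bubble_graph():
    """Source, two parallel variants, sink; unique flanks x and y."""
    graph = make_edge_graph(
        ["x", "a", "b", "y"],
        [("x", "a"), ("x", "b"), ("a", "y"), ("b", "y")],
        coverage={"x": 30, "a": 15, "b": 16, "y": 31},
    )
    tangle = Tangle(
        "bubble",
        [(F("x"), F("y"))],
        {"a", "b"},
        cov_u=30.0,
        boundary_segments={"x", "y"},
    )
    return graph, tangle


@pytest.fixture
def figure1_graph():
    """Boundary edges x1, y1 and six tangle edges over internal junctions.

    A repeat-array shape: terminals S and T, internal junctions A-D, with
    the central repeat edge traversed twice in the planted traversal
    x1, e1, e2, e3, e4, e2, e5, e6, y1 (e2 has multiplicity 2).
    """
    links = [
        ("x1", "e1"),  # S
        ("e1", "e2"),  # A
        ("e2", "e3"), ("e2", "e5"),  # B
        ("e3", "e4"),  # C
        ("e4", "e2"),  # A again via back edge
        ("e5", "e6"),  # D
        ("e6", "y1"),  # T
    ]
    coverage = {
        "x1": 30, "y1": 30,
        "e1": 31, "e2": 62, "e3": 29, "e4": 30, "e5": 28, "e6": 33,
    }
    graph = make_edge_graph(
        ["x1", "e1", "e2", "e3", "e4", "e5", "e6", "y1"], links, coverage
    )
    tangle = Tangle(
        "fig",
        [(F("x1"), F("y1"))],
        {"e1", "e2", "e3", "e4", "e5", "e6"},
        cov_u=30.0,
        boundary_segments={"x1", "y1"},
    )
    true_walk = [F(e) for e in ["e1", "e2", "e3", "e4", "e2", "e5", "e6"]]
    return graph, tangle, true_walk
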