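"""Eulerian expansion, swap moves, read scoring and the local-search optimizer."""

import random

import pytest

from tanglepath.exhaustive import naive_substring_score
from tanglepath.fixtures import (
    plant_repeat_tangle,
    planted_assignment,
    random_flow_tangle,
    sample_read_walks,
    write_fixture,
)
from tanglepath.graph import OrientedEdge
from tanglepath.tangles import Tangle
from tanglepath.traversal import (
    NoEulerianPathError,
    ReadWalk,
    TraversalPath,
    apply_swap,
    build_multigraph,
    check_swap_connectivity,
    enumerate_eulerian_paths,
    enumerate_swaps,
    find_eulerian_path,
    load_gaf,
    optimize_path,
    score_path,
    swap_sequence,
)

from conftest import F, R, make_edge_graph


def _replay_is_eulerian(graph, mg, path):
    counts = {}
    for oe in path.steps[1:-1]:
        counts[oe] = counts.get(oe, 0) + 1
    if counts != mg.counts:
        return False
    return all(graph.adjacent(a, b) for a, b in zip(path.steps, path.steps[1:]))


class TestLoadGaf:
    def _setup(self, tmp_path, lines):
        g = make_edge_graph(
            ["x1", "e1", "e2", "y1", "far"],
            [("x1", "e1"), ("e1", "e2"), ("e2", "y1")],
            coverage={"x1": 30, "e1": 30, "e2": 30, "y1": 30, "far": 30},
        )
        t = Tangle("t", [(F("x1"), F("y1"))], {"e1", "e2"}, cov_u=30.0,
                   boundary_segments={"x1", "y1"})
        p = tmp_path / "reads.gaf"
        p.write_text("".join(lines))
        return g, t, p

    def test_direct_translation(self, tmp_path):
        g, t, p = self._setup(
            tmp_path, ["r1\t40\t0\t40\t+\t>x1>e1>e2>y1\t40\t0\t40\t40\t40\t60\n"]
        )
        walks = load_gaf(p, g, t)
        assert len(walks) == 1
        assert walks[0].labels == [F("x1"), F("e1"), F("e2"), F("y1")]

    def test_outside_alignment_dropped(self, tmp_path):
        g, t, p = self._setup(tmp_path, ["r1\t10\t0\t10\t+\t>far\t10\t0\t10\t10\t10\t60\n"])
        assert load_gaf(p, g, t) == []

    def test_clipping_to_tangle_run(self, tmp_path):
        g, t, p = self._setup(
            tmp_path, ["r1\t50\t0\t50\t+\t>far>x1>e1>e2\t50\t0\t50\t50\t50\t60\n"]
        )
        walks = load_gaf(p, g, t)
        assert walks[0].labels == [F("x1"), F("e1"), F("e2")]

    def test_unknown_segment_skipped(self, tmp_path):
        g, t, p = self._setup(
            tmp_path, ["r1\t10\t0\t10\t+\t>x1>nope>e1\t10\t0\t10\t10\t10\t60\n"]
        )
        assert load_gaf(p, g, t) == []

    def test_short_walks_dropped_and_duplicates_kept(self, tmp_path):
        g, t, p = self._setup(
            tmp_path,
            [
                "r1\t10\t0\t10\t+\t>e1\t10\t0\t10\t10\t10\t60\n",
                "r2\t20\t0\t20\t+\t>e1>e2\t20\t0\t20\t20\t20\t60\n",
                "r3\t20\t0\t20\t+\t>e1>e2\t20\t0\t20\t20\t20\t60\n",
            ],
        )
        walks = load_gaf(p, g, t)
        assert [w.read_id for w in walks] == ["r2", "r3"]

    def test_fixture_round_trip(self, tmp_path):
        planted = plant_repeat_tangle(n_units=3, unit_len=180, divergence=0.02, rng_seed=6)
        sample_read_walks(planted, n_reads=25, min_len=2, max_len=5, rng_seed=6)
        paths = write_fixture(planted, tmp_path)
        t = Tangle(
            "t",
            [(planted.true_path[0], planted.true_path[-1])],
            {oe.edge_id for oe in planted.true_path[1:-1]},
            cov_u=planted.cov_u_true,
            boundary_segments={planted.true_path[0].edge_id,
                               planted.true_path[-1].edge_id},
        )
        walks = load_gaf(paths["gaf"], planted.graph, t)
        assert [w.labels for w in walks] == [w.labels for w in planted.walks]


class TestMultigraph:
    def test_counts_match_assignment(self):
        for seed in range(5):
            g, t, mult, _ = random_flow_tangle(seed, walk_len=7, n_decoys=1)
            asg = planted_assignment(g, t, mult)
            mg = build_multigraph(g, t, asg)
            for oe, n in mg.counts.items():
                assert n == mult[oe.edge_id] > 0

    def test_self_loop_multiedges(self):
        g = make_edge_graph(["x", "r", "y"],
                            [("x", "r"), ("r", "r"), ("r", "y")],
                            coverage={"x": 30, "r": 90, "y": 30})
        t = Tangle("t", [(F("x"), F("y"))], {"r"}, cov_u=30.0)
        asg = planted_assignment(g, t, {"r": 3})
        mg = build_multigraph(g, t, asg)
        assert mg.counts == {F("r"): 3}

    def test_disconnected_positive_edges_error(self):
        g = make_edge_graph(
            ["x", "a", "b", "c", "y"],
            [("x", "a"), ("a", "y"), ("b", "c"), ("c", "b")],
            coverage={"x": 30, "a": 30, "b": 30, "c": 30, "y": 30},
        )
        t = Tangle("t", [(F("x"), F("y"))], {"a", "b", "c"}, cov_u=30.0)
        asg = planted_assignment(g, t, {"a": 1, "b": 1, "c": 1})
        with pytest.raises(NoEulerianPathError):
            build_multigraph(g, t, asg)


class TestEulerian:
    def test_linear_chain_unique_path(self):
        g = make_edge_graph(["x", "a", "b", "y"],
                            [("x", "a"), ("a", "b"), ("b", "y")],
                            coverage={"x": 30, "a": 30, "b": 30, "y": 30})
        t = Tangle("t", [(F("x"), F("y"))], {"a", "b"}, cov_u=30.0)
        mg = build_multigraph(g, t, planted_assignment(g, t, {"a": 1, "b": 1}))
        p = find_eulerian_path(g, mg, F("x"), F("y"), 0)
        assert p.steps == [F("x"), F("a"), F("b"), F("y")]
        assert enumerate_eulerian_paths(g, mg) == [[F("a"), F("b")]]

    def test_figure_eight_two_orderings(self):
        # two loops hanging off the central junction, entered and left once
        g = make_edge_graph(
            ["x", "p", "q", "y"],
            [("x", "p"), ("x", "q"), ("p", "p"), ("q", "q"),
             ("p", "q"), ("q", "p"), ("p", "y"), ("q", "y")],
            coverage={"x": 30, "p": 30, "q": 30, "y": 30},
        )
        t = Tangle("t", [(F("x"), F("y"))], {"p", "q"}, cov_u=30.0)
        mg = build_multigraph(g, t, planted_assignment(g, t, {"p": 1, "q": 1}))
        paths = enumerate_eulerian_paths(g, mg)
        assert sorted(paths) == sorted([[F("p"), F("q")], [F("q"), F("p")]])
        found = {tuple(find_eulerian_path(g, mg, F("x"), F("y"), s).steps[1:-1])
                 for s in range(20)}
        assert found == {tuple(p) for p in paths}

    def test_replay_validity_many_seeds(self):
        for seed in range(10):
            g, t, mult, _ = random_flow_tangle(seed, n_vertices=5, walk_len=8)
            mg = build_multigraph(g, t, planted_assignment(g, t, mult))
            x, y = t.boundary_pairs[0]
            for s in range(10):
                p = find_eulerian_path(g, mg, x, y, seed * 1000 + s)
                assert _replay_is_eulerian(g, mg, p)


class TestScoring:
    def test_whole_path_walk_scores_one(self):
        g, t, mult, walk = random_flow_tangle(1, walk_len=6)
        x, y = t.boundary_pairs[0]
        full = [x] + walk + [y]
        assert score_path(TraversalPath(full), [ReadWalk("r", full)]) == 1

    def test_absent_edge_scores_zero(self):
        g, t, mult, walk = random_flow_tangle(1, walk_len=6)
        x, y = t.boundary_pairs[0]
        full = [x] + walk + [y]
        ghost = [F("x"), OrientedEdge("nosuch", "+")]
        assert score_path(TraversalPath(full), [ReadWalk("r", ghost)]) == 0

    def test_reverse_strand_walk_counts_once(self):
        g, t, mult, walk = random_flow_tangle(2, walk_len=6)
        x, y = t.boundary_pairs[0]
        full = [x] + walk + [y]
        rc = [oe.reverse() for oe in reversed(full[:3])]
        assert score_path(TraversalPath(full), [ReadWalk("r", rc)]) == 1

    def test_matches_naive_oracle(self):
        rng = random.Random(7)
        for seed in range(25):
            g, t, mult, walk = random_flow_tangle(seed, n_vertices=5, walk_len=8)
            x, y = t.boundary_pairs[0]
            full = [x] + walk + [y]
            walks = []
            for i in range(20):
                length = rng.randint(2, 5)
                st = rng.randint(0, len(full) - length)
                lab = full[st : st + length]
                if rng.random() < 0.3:
                    lab = [oe.reverse() for oe in reversed(lab)]
                if rng.random() < 0.3:
                    rng.shuffle(lab)
                walks.append(ReadWalk(f"r{i}", list(lab)))
            assert score_path(TraversalPath(full), walks) == naive_substring_score(
                full, walks
            )


class TestSwaps:
    def test_no_repeated_vertex_pairs_no_swaps(self):
        g = make_edge_graph(["x", "a", "b", "y"],
                            [("x", "a"), ("a", "b"), ("b", "y")],
                            coverage={"x": 1, "a": 1, "b": 1, "y": 1})
        path = TraversalPath([F("x"), F("a"), F("b"), F("y")])
        assert list(enumerate_swaps(g, path)) == []

    def test_parallel_repeat_swap_found(self):
        # A->B twice via two parallel edges, traversed p then q
        g = make_edge_graph(
            ["x", "p", "q", "back", "y"],
            [("x", "p"), ("x", "q"), ("p", "back"), ("q", "back"),
             ("back", "p"), ("back", "q"), ("p", "y"), ("q", "y")],
            coverage={"x": 1, "p": 1, "q": 1, "back": 1, "y": 1},
        )
        path = TraversalPath([F("x"), F("p"), F("back"), F("q"), F("y")])
        swaps = list(enumerate_swaps(g, path))
        assert (0, 1, 1, 0, 3, 3) in swaps
        swapped = apply_swap(path, (0, 1, 1, 0, 3, 3))
        assert swapped.steps == [F("x"), F("q"), F("back"), F("p"), F("y")]

    def test_swaps_match_brute_force_and_preserve_validity(self):
        for seed in range(8):
            g, t, mult, walk = random_flow_tangle(seed, n_vertices=4, walk_len=7)
            x, y = t.boundary_pairs[0]
            path = TraversalPath([x] + walk + [y])
            steps = path.steps
            brute = []
            for i1 in range(1, len(steps) - 1):
                for j1 in range(i1, len(steps) - 1):
                    for i2 in range(j1 + 1, len(steps) - 1):
                        for j2 in range(i2, len(steps) - 1):
                            if (
                                g.start(steps[i1]) == g.start(steps[i2])
                                and g.end(steps[j1]) == g.end(steps[j2])
                            ):
                                brute.append((0, i1, j1, 0, i2, j2))
            got = sorted(enumerate_swaps(g, path))
            assert got == sorted(brute)
            mg = build_multigraph(g, t, planted_assignment(g, t, mult))
            for swap in got:
                assert _replay_is_eulerian(g, mg, apply_swap(path, swap))

    def test_swapping_identical_subpaths_is_identity(self):
        g, t, mult, walk = random_flow_tangle(11, walk_len=8)
        x, y = t.boundary_pairs[0]
        path = TraversalPath([x] + walk + [y])
        for swap in enumerate_swaps(g, path):
            _, i1, j1, _, i2, j2 = swap
            if path.steps[i1 : j1 + 1] == path.steps[i2 : j2 + 1]:
                assert apply_swap(path, swap).steps == path.steps
                break

    def test_block_exchange_shape(self):
        """Two same-endpoint blocks swap; flanking subpaths are untouched."""
        g = make_edge_graph(
            ["x", "g1", "g2", "b1", "b2", "mid", "y"],
            [("x", "g1"), ("g1", "g2"), ("g2", "mid"), ("mid", "b1"),
             ("b1", "b2"), ("b2", "y"),
             ("x", "b1"), ("b2", "mid"), ("mid", "g1"), ("g2", "y")],
            coverage={s: 1 for s in ["x", "g1", "g2", "b1", "b2", "mid", "y"]},
        )
        path = TraversalPath(
            [F("x"), F("g1"), F("g2"), F("mid"), F("b1"), F("b2"), F("y")]
        )
        swap = (0, 1, 2, 0, 4, 5)  # green block [g1,g2] vs blue block [b1,b2]
        assert swap in list(enumerate_swaps(g, path))
        new = apply_swap(path, swap)
        assert new.steps == [F("x"), F("b1"), F("b2"), F("mid"), F("g1"), F("g2"), F("y")]


class TestOptimize:
    def test_no_walks_score_zero(self):
        g, t, mult, _ = random_flow_tangle(3, walk_len=6)
        mg = build_multigraph(g, t, planted_assignment(g, t, mult))
        x, y = t.boundary_pairs[0]
        best = optimize_path(g, mg, x, y, [], restarts=3, rng_seed=1)
        assert best.score == 0
        assert _replay_is_eulerian(g, mg, best)

    def test_planted_path_recovered_with_decisive_walks(self):
        for seed in range(6):
            g, t, mult, walk = random_flow_tangle(seed, n_vertices=5, walk_len=8)
            x, y = t.boundary_pairs[0]
            full = [x] + walk + [y]
            # walks covering every junction decision: all 3-step windows
            walks = [
                ReadWalk(f"w{i}", full[i : i + 3]) for i in range(len(full) - 2)
            ]
            mg = build_multigraph(g, t, planted_assignment(g, t, mult))
            best = optimize_path(g, mg, x, y, walks, restarts=10, rng_seed=seed)
            assert best.score == len(walks)
            assert best.steps == full

    def test_global_optimum_on_enumerable_instances(self):
        from tanglepath.traversal import WalkScorer

        rng = random.Random(5)
        for seed in range(12):
            g, t, mult, walk = random_flow_tangle(seed, n_vertices=4, walk_len=7)
            mg = build_multigraph(g, t, planted_assignment(g, t, mult))
            if mg.n_multiedges > 8:
                continue
            x, y = t.boundary_pairs[0]
            full = [x] + walk + [y]
            walks = []
            for i in range(10):
                length = rng.randint(2, 4)
                st = rng.randint(0, len(full) - length)
                walks.append(ReadWalk(f"r{i}", full[st : st + length]))
            scorer = WalkScorer(walks)
            global_best = max(
                scorer.score([[x] + p + [y]])
                for p in enumerate_eulerian_paths(g, mg)
            )
            got = optimize_path(g, mg, x, y, walks, restarts=10, rng_seed=seed)
            assert got.score == global_best

    def test_restart_determinism(self):
        g, t, mult, walk = random_flow_tangle(9, n_vertices=5, walk_len=8)
        x, y = t.boundary_pairs[0]
        walks = [ReadWalk("r", walk[:3])]
        mg = build_multigraph(g, t, planted_assignment(g, t, mult))
        a = optimize_path(g, mg, x, y, walks, restarts=5, rng_seed=123)
        b = optimize_path(g, mg, x, y, walks, restarts=5, rng_seed=123)
        assert a.steps == b.steps and a.score == b.score


class TestSwapConnectivity:
    def test_identical_paths_empty_sequence(self):
        g, t, mult, walk = random_flow_tangle(4, walk_len=6)
        assert swap_sequence(g, walk, list(walk)) == []

    def test_figure_eight_single_swap(self):
        g = make_edge_graph(
            ["x", "p", "q", "y"],
            [("x", "p"), ("x", "q"), ("p", "p"), ("q", "q"),
             ("p", "q"), ("q", "p"), ("p", "y"), ("q", "y")],
            coverage={"x": 30, "p": 30, "q": 30, "y": 30},
        )
        t = Tangle("t", [(F("x"), F("y"))], {"p", "q"}, cov_u=30.0)
        mg = build_multigraph(g, t, planted_assignment(g, t, {"p": 1, "q": 1}))
        proof = check_swap_connectivity(g, mg)
        assert len(proof) == 4  # 2 paths, all ordered pairs
        assert len(proof[(0, 1)]) == 1

    def test_all_pairs_connected_on_random_corpus(self):
        checked = 0
        for seed in range(15):
            g, t, mult, _ = random_flow_tangle(seed, n_vertices=4, walk_len=6)
            mg = build_multigraph(g, t, planted_assignment(g, t, mult))
            if mg.n_multiedges > 8:
                continue
            check_swap_connectivity(g, mg)  # raises on any failure
            checked += 1
        assert checked >= 10
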