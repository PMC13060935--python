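# Methods

## Problem and model

A tangle is what remains when an assembler cannot phase a long, highly
similar repeat: a small connected cluster of short edges between long,
well-behaved flanks, corresponding to a gap in the scaffolded assembly.  The
package models a tangle traversal as two decoupled optimizations — integer
copy numbers first, then an ordering of the implied multiedges — both driven
only by data that survive in assembler output: graph topology, per-node
depth of coverage, and read-to-graph alignments.

The single modeling assumption that everything rests on is **local coverage
uniformity**: each genomic path through the tangle contributes the same
depth Cov_u.  Uniformity is required only within one tangle, not across the
genome, which is why Cov_u is estimated per tangle as the median coverage of
its boundary edges (a user override exists).  Where the assumption fails —
satellite-induced coverage bias, coverage holes — copy numbers can be wrong;
the coverage-divergence metric is designed to expose exactly that residual.

## Graph representation

GFA stores sequence on nodes; all reasoning here wants sequence on edges.
Segments become edges and link-joined segment ends become junction vertices
(transitively closed, the only consistent reading of junction identity).
Junctions are kept strand-aware: each has two vertex copies, one per reading
direction, so that walk legality is sequence-exact — at a junction shared by
edges A and C (both pointing in), A+ followed by C− is *not* traversable,
because the two strands of the junction are different vertices.  Merged
(strandless) junction counts are what the API reports.

Within one tangle the simplifying assumption is that only one of e and
reverse_complement(e) is reachable from the boundary; a violation (an
inverted repeat inside the tangle) raises a dedicated not-supported error
rather than producing a wrong multiplicity for a strand pair.

## Multiplicity MILP

Variables: one bounded integer mult(e) per tangle edge plus one continuous
deviation d_e ≥ |cov(e)/Cov_u − mult(e)| (the standard linearization of the
absolute-deviation objective).  Constraints: flow conservation at every
tangle vertex with boundary edges contributing a fixed unit; mult ≥ 1 on
reasonably covered edges (cov ≥ 0.5·Cov_u, the threshold exposed as
`--rc-threshold`); upper bound ceil(4·max(cov)/Cov_u) by default (callers
may pass a scalar or per-edge bound).  The backend is the HiGHS solver via
`scipy.optimize.milp`; the formulation is solver-agnostic and a per-tangle
time limit (default 300 s, `--milp-time-limit`) returns the incumbent with
a warning if reached.

Infeasibility of the strict program is a real phenomenon, not an edge case:
with two boundary pairs, a vertex fed by two unit-coverage edges and drained
by one forces the outgoing multiplicity to 2 at objective cost ≈ 1 (the
program handles it); with one boundary pair, two parallel reasonably covered
alternatives cannot both be used, the at-least-once constraints are dropped,
and the result is flagged `relaxed`.  If even the relaxed program is
infeasible the tangle is reported as unsolvable and skipped — batch runs
never abort.

Cov_u may optionally be re-tuned by a grid re-solve over
{0.9, 1.0, 1.1}×estimate keeping the lowest objective (`--tune-cov-u`, off
by default; the conservative default avoids chasing noise).

Ties among MILP optima are accepted as the solver reports them; path-level
determinism is provided downstream by the optimizer's lexicographic
tie-break, and which optimum is "right" is decidable only by alignments.

## Traversal optimization

Multiplicity-n edges expand to n multiedges; flow conservation plus
undirected connectivity guarantee an Eulerian path from the incoming to the
outgoing boundary, drawn by a Hierholzer walk whose adjacency lists are
shuffled by the restart's seeded RNG.  Scoring counts *reads*, not
occurrences: a read walk (clipped from GAF to its longest
adjacency-consistent run over tangle∪boundary edges; walks of one label
constrain nothing and are dropped) counts once if its label sequence or its
reverse-complement occurs as a contiguous run in any output path.  Matching
uses a hand-built Aho–Corasick automaton over hashable edge labels, because
the alphabet is oriented-edge identifiers, not characters.

The move set is the swap: exchange two non-overlapping subpaths that share
their start vertex A and end vertex B.  Swaps preserve both adjacency and
the edge multiset, and they connect the whole Eulerian path space — the
package carries an executable proof (`swap_sequence`) that extends the
common prefix of any two paths one position per swap: either an
adjacent-interval swap when the path returns to A, or an exchange of the
A→B halves of the pending loop and the continuation otherwise.  The search
is first-improvement over a randomly shuffled swap scan (cheaper than
best-improvement and faithful to "random swaps, accept if better"),
terminating at a local optimum, with a 10 000-accepted-swap safety valve.
Default 10 restarts (seeds derived from `--seed` + restart index); the best
final score wins, ties broken by lexicographically smallest edge-id
sequence so identical inputs give identical outputs.

Two-boundary-pair tangles (a repeat array shared by two haplotypes) share
one multiplicity budget: each restart chains the pairs with an artificial
edge, draws one Eulerian path, and cuts it into one walk per pair; the local
search then allows swaps within each path and exchanges of same-endpoint
subpaths across paths, scoring each read at most once against either path.
This is the minimal joint extension consistent with the flow constraints;
pairing of boundary edges in auto-detection is chosen as the first
reachability-consistent assignment in sorted order (scaffold-based pairing
is out of scope).

## Outputs and metrics

Per tangle: a FASTA model sequence (steps concatenated, the stored link
overlap trimmed once per junction, reverse steps reverse-complemented;
boundary edges included in full by default so the patch has alignment
anchors, `--trim-boundary` to drop them), a P-line-like path rendering, and
a JSON report embedding the run configuration.  The two metrics —
coverage divergence (mean over tangle edges of |cov/Cov_u − mult|) and
unsupported read fraction (1 − supported/total, 0 with a flag when no
alignments exist) — are reported, never thresholded: they conflate
traversal quality with intrinsic problem difficulty, so no pass/fail cut is
defensible.

## Synthetic data generator

`plant_repeat_tangle` emulates the hard case: n near-identical units
(per-unit point mutations at the `divergence` rate; 0 gives a single
collapsed edge of multiplicity n) between unique random flanks, collapsed by
an exact k-mer de Bruijn construction (default k = 21) with unitig
compression, k−1 overlaps, and forward-strand links.  Coverage is planted as
multiplicity × Cov_u × (1+ε), ε uniform in ±10% — enough to exercise MILP
rounding without breaking the coverage model.  Defaults: Cov_u = 30 (typical
HiFi depth), unit length 200 bp and flanks 800 bp, sized so a laptop-scale
graph still has the real structure (shared repeat unitigs of multiplicity n,
variant unitigs of multiplicity 1).  Reads are exact subwalks of the true
traversal written as GAF; base-level errors are deliberately absent because
the pipeline consumes aligner output, not raw reads.  Consequently, passing
tests demonstrate correctness of the optimization machinery under the
stated coverage model — they do not demonstrate robustness to aligner
artifacts, chimeric reads, strong coverage bias, haplotype-imbalanced
coverage, or inverted repeats, which real data can present.

A second generator, `random_flow_tangle`, plants a random boundary-to-
boundary walk over a handful of junctions to produce arbitrary
flow-feasible topologies (with optional low-coverage decoy edges) for
oracle cross-checks.

## Parameters at fixture scale

Unique-edge classification defaults (min length 100 kbp, coverage window
[0.7, 1.3]× the median long-edge coverage, tangle ≤ 20% of its component)
are genome-scale conventions; all are CLI-exposed.  Tests and the acceptance
script run the same pipeline at generator scale with
`--min-unique-len 300 --max-tangle-fraction 0.6`, matching the ~800 bp
flanks and ~1 kbp tangles the generator plants.

Acceptance-scale problem sizes, chosen to keep exhaustive oracles exact:
random tangles of ≤ 10 edges with per-edge multiplicity bounds
ceil(2·cov/Cov_u) shared by the MILP and the enumeration oracle; multigraph
corpus of ≤ 8 multiedges where all Eulerian paths are enumerable; 50
end-to-end planted fixtures of 3–5 units.

## Numerical and degenerate-input choices

Objective values are recomputed from the returned integer assignment
(solver tolerance 1e-6).  Empty GFA files load as empty graphs; an empty
walk list gives unsupported fraction 0 with a `no_alignments` flag; edges
missing from a coverage table get coverage 0 with a warning, negative
coverage is a validation error; a coverage table overrides embedded GFA
tags.  Detection sorts all iteration by edge id, so results are independent
of input file ordering.

## Known limitations

Inter-chromosomal repeats (boundary pairs in different components) and
inverted repeats inside a tangle are not supported; gaps caused by missing
coverage rather than repeat structure cannot be traversed; coverage bias
directly corrupts copy numbers (single-technology coverage only); a
traversal with few or no spanning reads may be one of many score-equivalent
orderings — the model sequence is plausible, not verified, which is why it
is never patched into a scaffold automatically.
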