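# tanglepath

Evidence-based traversal of assembly-graph **tangles** — the small clusters of
short, repetitive edges that telomere-to-telomere (T2T) assemblers leave
unresolved, appearing as gaps between scaffolded contigs.  Instead of leaving
a gap or a pile of short contigs, `tanglepath` produces a single continuous
**model sequence** through the tangle that is most consistent with the
sequencing data, together with reference-free quality metrics.  It is aimed
at assembly curators closing residual gaps (e.g. collapsed ampliconic gene
arrays) from an assembly graph, per-node coverage, and long-read-to-graph
alignments.

## Method

Work happens on the edge-labeled view of the graph: GFA segments become
edges, link-joined segment ends become junction vertices.  A tangle is a
small component C_t of non-unique edges fenced in by *unique* boundary edge
pairs (x_i, y_i) — long edges with coverage near the single-traversal depth.
Resolution is a two-stage optimization:

1. **Copy numbers by MILP.**  With Cov_u the coverage of one genomic
   traversal (median of boundary-edge coverages), find integer
   multiplicities minimizing

       min Σ_e | cov(e)/Cov_u − mult(e) |

   subject to flow conservation Σ_in mult = Σ_out mult at every tangle
   vertex, mult(e) = 1 on boundary edges, mult(e) ≥ 0, and mult(e) ≥ 1 for
   every *reasonably covered* edge (cov(e) ≥ 0.5·Cov_u).  If the last
   requirement makes the program infeasible it is dropped and the solve is
   flagged `relaxed`.

2. **Path by swap local search.**  Each edge of multiplicity n expands into
   n multiedges; any valid traversal is an Eulerian path from x to y, found
   by a seeded Hierholzer walk.  The path's score is the number of reads
   whose edge-label walk (either strand) occurs as an exact contiguous run
   in it, counted with an Aho–Corasick automaton over the edge-label
   alphabet.  A *swap* exchanges two non-overlapping subpaths sharing start
   and end vertices — reordering repeat units while preserving
   multiplicities; the swap move set provably connects all Eulerian paths,
   and first-improvement descent with 10 random restarts optimizes the
   score.

The output is deliberately a standalone FASTA (never auto-patched into a
scaffold) plus two reported-not-gated metrics: the coverage divergence
Σ_e |cov(e)/Cov_u − mult(e)| / |E| and the fraction of tangle read walks not
supported by the traversal.

## Worked example

Generate a synthetic ground-truth tangle — 3 near-identical 200 bp repeat
units between unique flanks — then resolve it:

```bash
tanglepath fixtures --units 3 --unit-len 200 --divergence 0.02 \
    --reads 50 --max-read-len 40 --seed 11 --out demo
tanglepath detect  --graph demo/graph.gfa --coverage demo/coverage.tsv \
    --min-unique-len 300 --max-tangle-fraction 0.6
tanglepath resolve --graph demo/graph.gfa --coverage demo/coverage.tsv \
    --alignments demo/reads.gaf --min-unique-len 300 \
    --max-tangle-fraction 0.6 --out demo/out --seed 42
```

which prints

```
wrote demo: 25 segments, 50 reads, genome 2200 bp
tangle0	23 edges	1 pair(s)	u00+->u24+	resolvable
1/1 tangle(s) resolved; output in demo/out
```

`demo/out/tangle0.fasta` starts

```
>tangle0_pair0 score=50 cov_div=0.0819 unsupported=0.0000
TTGAGGCCCGTTCGTGCTCCTCGCCCTGAAGCATTGCTTTGTGAAGAGGGACTTCAGCCA...
```

All 50 read walks support the traversal (`score=50`,
`unsupported=0.0000`); the residual coverage divergence 0.0819 reflects the
±10% multiplicative coverage noise the generator plants.  The emitted 2200 bp
sequence is byte-identical to the simulated genome, and
`demo/out/tangle0.json` records the multiplicities (e.g. the collapsed
repeat edges at `mult = 3`), the MILP objective, per-stage timings and the
full run configuration; `tangle0.paths.tsv` holds the traversal as a
P-line-like list of oriented edges.

Real inputs follow the same shape: a GFA 1.x graph from a (multiplex-)DBG
assembler, a 2-column node/coverage TSV (or embedded `dp` tags), and GAF
alignments from a sequence-to-graph aligner such as GraphAligner.  Boundary
edges can also be named explicitly with
`--boundary x1+,y1-[,x2+,y2-]`.

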