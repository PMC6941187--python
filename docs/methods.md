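# Methods

## Model

The package combines two exact, deterministic computations.

**Venn partition.** Each experiment `E_j` is a set of gene symbols (the
DEG list collapsed over transcripts). A gene's region index is the bitmask
`i = Σ_j 2^(j−1)·[g ∈ E_j]`, so region `C_i` is the intersection of the
`E_j` with bit set and of the complements of the others. `b_1` is the
least-significant bit and `j` is fixed by file order; `C_0` (membership in
nothing) does not exist because only genes appearing in at least one list
are considered. All `2^n − 1` regions are materialized even when empty, so
region expressions never fail on sparse data. Region arithmetic supports
only union (`+`): regions are pairwise disjoint, making intersection and
difference of regions degenerate.

**Restart random walk.** On the DEG-induced subnetwork the walk iterates
`p^{t+1} = (1−r) A′ p^t + r p^0`. This is the deterministic power
iteration of the expected-visit recurrence — no Monte-Carlo walkers — and
its fixed point solves `(I − (1−r)A′) p = r p^0`. That linear system is
strictly column-diagonally dominant for `r > 0`, hence nonsingular; the
package carries both routes, using the solve (`closed_form`) purely as an
independent oracle against the iterative path in tests. Convergence is
geometric with factor `1 − r` in L1, so at the defaults (`r = 0.5`,
`tol = 10⁻⁴`) the stop rule fires within ~20 iterations; the suite asserts
≤ 25 across random graphs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 700 | keep edges with combined score strictly greater; the conventional high-confidence cut on STRING's 0–1000 confidence scale |
| `r` | 0.5 | restart rate; fraction of mass returned to the seed distribution each step, controls locality of the propagation |
| `tol` | 1e-4 | L1 stop rule on consecutive iterates (absolute, no relative variant) |
| `max_iter` | 10000 | safety cap only; unreachable for column-stochastic inputs given the contraction |

Seed mass is uniform, `1/k` on each of the `k` seed genes present in the
network; seeds named but absent from the network are dropped with a logged
warning, and an entirely absent seed set is an analysis error.

## Numerical and degenerate-input choices

- **Dangling nodes.** A zero column in `A` would leak probability mass
  under column normalization. Isolated nodes therefore receive a self-loop
  before normalizing, which preserves column-stochasticity without
  redirecting flow through other nodes: a non-seed isolate's score decays
  to 0, a seed isolate retains its restart mass. Isolated DEGs are kept as
  nodes at all so that the ranked output covers every candidate gene.
- **Node ordering** is lexicographic by symbol, making matrices, ranks and
  output files byte-reproducible; the whole pipeline contains no random
  number generator.
- **Ties** in propagation score break lexicographically on the gene
  symbol; ranks are strict ordinals `1..m`.
- **Zero-score genes** (unreachable isolates) stay at the bottom of the
  table rather than being dropped.
- Accumulation is in double precision; scores are printed at 6 significant
  digits but never rounded internally.
- Duplicate transcript IDs annotating the same symbol collapse silently;
  the same ID annotating two different symbols is an input error rather
  than resolved by precedence, since any precedence rule would silently
  hide an annotation conflict.
- Header detection in DEG files (`--header auto`) drops the first row iff
  its second cell never recurs as a gene symbol in the file; a
  single-row file is always treated as data. Files written by the fixture
  generator carry an explicit header and are detected correctly; for
  headerless files whose first symbol is unique, pass `--header no`.

## Synthetic data generator

The generator emulates the three inputs — per-experiment DEG files, a
STRING-dialect scored edge list over opaque protein IDs (both directions
listed, header line present), and the ID→symbol alias table — with full
ground truth. Genes are assigned to Venn regions by a weight vector
(remainder = non-DEG background); each DEG appears in exactly the files
its region bits dictate, under 1–3 synthetic transcript IDs; the graph is
a planted-partition model in which a "linked" fraction of the target
region attaches to the seed region with elevated probability.

Defaults: 2 experiments, 300-gene universe, region weights
C1 = 0.30, C2 = 0.25, C3 = 0.20 (background 0.25), linked fraction 0.5 of
C1 toward seeds C2, module edge probability 0.08 within, 0.02 between.
The within-module probability is chosen so a linked gene's expected module
degree (0.08 × ~75 ≈ 6) matches its expected background degree
(0.02 × 299 ≈ 6): with a much denser module, linked genes top the ranking
under *any* seed set by degree alone and the benchmark stops
discriminating seed choice; at parity, recovering the linked genes
requires propagating from the right seeds, which is the property worth
testing. Edge scores are uniform on [400, 1000] for module edges and
[0, 1000] for background, so the strict >700 filter keeps about half and
a quarter of them respectively and is exercised nontrivially.

What the generator does **not** emulate: realistic degree distributions
(real PPI networks are heavy-tailed, Erdős–Rényi background here), hub
proteins, expression magnitudes or fold-change directions, annotation
noise, or incomplete alias coverage. Passing tests therefore demonstrate
correctness of the partition/propagation machinery and recoverability of
a planted diffusion signal — not performance on any real interactome.

## Design choices where the design was open

- Delimiter and header handling of DEG files are explicit flags because
  the input dialect in the wild varies; tab and auto-detection are the
  defaults.
- Symbol matching is case-sensitive by default (mouse vs human symbol
  conventions differ meaningfully), with an opt-in fold to upper case.
- When no target-region restriction is given, all non-seed DEGs are
  ranked; restriction is the focused variant, not the default.
- Seed genes are never ranked: they hold the restart mass by construction
  and would only pad the top of the table.
- Up/down regulation is not modeled; a direction-split analysis is done by
  supplying direction-filtered files, which composes cleanly with the
  region encoding.

## Problem sizes

The test suite and the acceptance script size their simulations at
1000 random partition instances (n ≤ 6, universe ≤ 200), 50 random
propagation graphs of up to 500 nodes, and the default 300-gene fixture
for the end-to-end enrichment benchmark; these sizes make every oracle
comparison exact or near-exact while keeping the full suite around a few
seconds.

## Known limitations

- Propagation is unweighted: the confidence score gates edge existence but
  does not weight the walk.
- No statistical significance is attached to propagation scores or ranks.
- The enrichment benchmark is a synthetic stand-in; rank numbers on real
  DEG lists depend on the PPI snapshot used and are not reproducible
  without fixing one.
- GO-term analysis and any visualization are out of scope; the outputs
  are plain TSV tables designed to feed such tools.
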