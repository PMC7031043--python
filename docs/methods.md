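# Methods

## Model and procedure

`mediatornet` identifies genes that mediate the functional connection
between a source gene *s* (in the motivating application, the 5-HT2A
serotonin receptor gene) and a target gene set *T* (a stress-responsive,
treatment-normalized expression program) on a tissue-specific functional
gene network.

1. **Edge filtering.** The input network carries a functional linkage score
   in (0, 1] per gene pair. Only the top fraction of edges by score is kept
   (default 1%). With *m* edges and cutoff rank *c* = ⌈fraction·*m*⌉, every
   edge scoring at least the *c*-th largest score is retained; ties at the
   boundary are all kept, so the result is deterministic and independent of
   input order. Duplicate unordered pairs collapse to their maximum score
   (conservative toward connectivity) and self-loops are dropped.
2. **Reciprocal weighting.** Each retained edge gets distance weight
   1/score, so strong functional links are short. The graph is undirected
   and may be disconnected; unreachable targets simply contribute nothing.
3. **Restricted betweenness.** For every gene *g*,
   BC(*g*) = Σ_{t∈T} σ(s,t|g)/σ(s,t), with σ(s,t) the number of
   minimum-total-weight s–t paths and σ(s,t|g) the number passing through
   *g* as an interior node. Endpoints of a pair contribute zero to that
   pair's term (the standard betweenness endpoint convention, declared
   explicitly because centrality conventions differ); genes inside *T* are
   scored like any other gene and flagged in the output.
4. **Permutation significance.** The null draws target sets of size |T|
   uniformly without replacement from all network genes except the source
   (degree-matched sampling by decile is available behind a flag, off by
   default). p(*g*) is the plain fraction of permuted sets whose score for
   *g* reaches the observed BC(*g*); it may be exactly 0, and add-one
   smoothing ((k+1)/(n+1)) is available behind a flag. The reference
   setting is 100,000 permutations.
5. **FDR and mediator calls.** Benjamini–Hochberg step-up across all
   network genes (zero-centrality genes enter the family with p = 1; the
   family size is recorded). Genes at FDR ≤ 0.1 are mediator calls.
6. **Enrichment.** Mediators are tested for over-representation in GMT
   pathway sets with the upper hypergeometric tail P(X ≥ k); the universe
   defaults to the filtered network's node set — the space in which
   mediators are discoverable — and BH runs across all pathways with at
   least one gene in the universe.

Target sets are built as the intersection of two differential-expression
contrasts: genes significant under stress (isolated vs group-housed) and
genes significant under treatment (isolated vs treated), thresholded on
BH-adjusted p ≤ 0.05 by default (the cutoff is exposed because published
tables rarely state it). An optional direction filter additionally
requires the same fold-change sign in both contrasts under the
first-named-condition-positive convention; it is off by default because
the motivating analysis describes a plain two-set overlap.

Behavioral classification implements two rules: homecage anxiety when
shelter time strictly exceeds the control mean plus twice the control SEM
(sd with n−1 over √n), and open-field anxiety when the center-to-periphery
time ratio is strictly below 0.25. The "±" in mean ± 2·SEM is read as the
upper bound, since anxiety manifests as *more* shelter time.

## Numerical choices

- **Tie tolerance.** Reciprocal-score weights are floats, so shortest-path
  ties are recognized with a relative tolerance: an edge (u, v) lies on a
  shortest path into v iff |dist(u) + w(u,v) − dist(v)| ≤ 1e-9·max(1,
  dist(v)). Exact equality would under-count multiplicities on tied routes.
- **Implementation.** Dijkstra distances come from networkx; the
  shortest-path DAG, path multiplicities, and the per-target contribution
  matrix C[g, t] = σ(s,t|g)/σ(s,t) are computed here. Because the DAG does
  not depend on the target set, every permutation reduces to a column sum
  over C — the permutation test is exact relative to re-running the graph
  algorithm per draw, and fast enough for the 100,000-draw setting.
- **Count overflow.** σ counts are doubles; a warning is logged if they
  exceed 2^53 (dense tied graphs), past which multiplicities lose
  integer exactness.
- **Score comparisons.** "Permuted BC ≥ observed BC" uses a 1e-12 relative
  slack so equal scores reached by different summation orders still tie.
- **Reproducibility.** One integer seed drives a single numpy Generator;
  identical (seed, n_permutations) gives identical p-vectors, and two
  pipeline runs with the same configuration write byte-identical outputs.
  The run manifest therefore records configuration, versions, input
  checksums and stage counts but no wall-clock timings (those go to the
  log), and its configuration echo omits the output directory.

## Verification oracles

The fast path is checked against independent re-derivations rather than
against itself: brute-force enumeration of all simple paths (graphs up to
14 nodes) for the centrality; exhaustive enumeration of every size-|T|
subset (guarded at 10,000 combinations) for permutation p-values; the
statsmodels step-up implementation for BH; and direct enumeration of all
possible query draws for the hypergeometric tail. Two spec-level
"invariants" were corrected during design: top-fraction filtering is not
idempotent under its own definition (the cutoff rank ⌈f·m⌉ shrinks when
recomputed on the filtered list), so the tests assert the true nesting
property instead; and permutation p-values conditioned on positive
observed centrality are anti-conservative by construction (the
conditioning selects exactly the draws that favored the gene), so validity
is asserted unconditionally.

## What the synthetic generator emulates — and what it does not

`generate_network` emulates a functional network already reduced to its
strong edges: a uniform-random (or preferential-attachment) background of
400 genes and 2,000 edges with Beta-distributed scores in [0.2, 0.9],
bounded away from zero so reciprocal weights stay finite and tame. A
planted layer wires the source to 5 mediators and each of 25 targets to
exactly one mediator at score 0.95, giving a two-hop route of length
2/0.95 ≈ 2.105 that is strictly shorter than any background alternative
(≥ 2/0.9 ≈ 2.22 for two hops; direct source–target background edges are
excluded).

Two structural choices make the planted signal *specific*, which is what
the permutation test actually detects. Mediators participate in no
background edges: if they did, the cheap source–mediator edges would be
the source's best exits and mediators would sit on shortest paths to much
of the graph, so random target sets would score them as highly as the real
one and the permutation p-values would be large. Targets attach to the
background only through bottom-third scores: otherwise the cheap planted
gateway would also be the best route into each target's neighborhood,
again inflating mediator centrality under the null. With both choices a
mediator's centrality mass concentrates on its own targets (5–7 units),
and the null distribution over random sets is driven by how many of those
targets a random draw happens to contain.

The DE-table generator plants three significant sets with designed Venn
region sizes (default: |A∩B| = 50 against a 2,000-gene pool). Designed
genes receive p ≤ 1e-7; null p-values are uniform on (alpha, 1) when a
design is present — uniform-(0, 1) nulls would let BH promote an
occasional null past the threshold and break the exact-recovery guarantee
the designed overlaps exist to provide — and uniform on (0, 1) for the
pure-null design, where raw-p thresholding shows the expected alpha·n
false positives. Fold-change signs are drawn so a configurable fraction
(default 0.8) of the A∩B genes move consistently across the two contrasts.

The behavior generator plants group structure (controls at a 150 s shelter
baseline, sd 30; stressed animals +250 s; treated animals split into an
anxious subgroup at the stressed level with open-field ratios below 0.25,
default 13 of 24). Normalized treated animals sit 90 s (three control sd)
*below* baseline with tightened spread: the shelter cutoff (control mean +
2·SEM) lies only ~0.6 control sd above the control mean at n = 11, inside
the control distribution itself, so animals drawn from the control
distribution would cross it at the null upper-tail rate and planted labels
could never be recovered exactly. Recovery is therefore assessed on the
treated group; applied to the controls the rule flags their own upper tail,
which is a property of the published rule, not of this implementation.

None of this emulates real expression data: no count noise, no
library-size or batch structure, no correlation between expression and
network degree, and the background topology does not match a real
functional network's degree distribution. Passing the planted-recovery
tests shows the statistic, the permutation machinery and the FDR gate work
as specified — not that mediator calls on real networks are biologically
correct.

## Problem sizes and defaults

Published-setting defaults (top 1% of edges, 100,000 permutations,
FDR ≤ 0.1, DE alpha 0.05) are the package defaults in `AnalysisConfig` /
`PermutationConfig`. The test suite and the acceptance script run the
synthetic scale the package adopts for routine verification: 400-gene
networks, 2,000 permutations, 10–20 replicate seeds — enough for the
permutation grid (minimum nonzero p = 5e-4) to clear the 0.1 FDR gate for
five true mediators with room to spare. The full-scale configuration is a
matter of the config file, not of code.

## Known limitations

- Path counts, not flow: the statistic sees only strictly shortest paths;
  near-shortest alternatives contribute nothing, and the tie tolerance is
  the only concession to float geometry.
- The permutation null ignores target-set structure (co-expression,
  degree); degree-matched sampling is a coarse correction and is off by
  default to match the reference procedure.
- BH is applied over all network genes including the p = 1 mass at zero
  centrality; this is conservative for the nonzero-centrality genes.
- The hypergeometric universe choice materially changes enrichment
  p-values; the network node set is a defensible default, not the only one.
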