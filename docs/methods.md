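# Methods

## Model

The pipeline treats gene prioritization as diffusion on a weighted,
undirected PPI network `G`. Edge weights are STRING-style combined
confidence scores, integers in [150, 999]. The transition operator is the
column-stochastic matrix `A` obtained by dividing each column of the
score-weighted adjacency by its sum, so a walker on node `j` steps to
neighbor `i` with probability proportional to the edge score. Isolated
nodes receive a unit self-loop: this keeps `A` column-stochastic (so mass
conservation is a testable invariant) and is harmless, since an isolated
node can only ever hold the restart mass it is given.

Propagation is random walk with restart:

    P_{i+1} = (1 - c) A P_i + c P_0,        c = 0.8

iterated until `||P_{i+1} - P_i||_1 < 1e-6` (hard cap 10,000 iterations,
with an explicit non-convergence error carrying the last gap). The fixed
point is `P* = c (I - (1-c) A)^{-1} P_0`, which a dense-solve oracle
(`solve_rwr_direct`, guarded to ≤ 2,000 nodes) computes directly; the test
suite requires the two routes to agree to 1e-8 in L1. An undamped
"literal" update `P_{i+1} = Aᵀ P_i + c P_0` is retained behind
`update_rule="literal"` for comparison only: it is not a stochastic
update, its L1 norm grows without bound on regular graphs (a property
test documents this), and only the damped form returns probabilities.
The spectral radius of `(1-c)A` is at most `1-c = 0.2`, so the iteration
contracts geometrically and typically converges in under ten iterations.

Multi-isoform handling: a seed gene whose identifier maps to several
protein nodes (e.g. `3702.AT1G01010.1/.2`) has its `1/|S|` restart share
split equally among those nodes.

## Permutation screen

Null model: `N` seed sets of the observed size drawn uniformly without
replacement from all network nodes, each propagated with the identical
RWR configuration (batched as columns of one matrix, which is
bit-identical to per-set runs). For gene `g`,
`p(g) = Θ/N` where `Θ` counts null sets whose probability for `g`
strictly exceeds the observed one; ties do not count against
significance, and `p = 0` is displayed as `< 1/N`.

A null set that contains `g` itself is excluded from `Θ`: as a seed of
that null run, `g` holds restart mass `≥ c/|S|`, orders of magnitude
above any non-seed probability, so counting those sets would impose a
p-value floor of about `|S|/n` on every gene regardless of signal. With
the floor removed the screen is calibrated: when the observed seed set is
itself a uniform draw, the p-values over all scored genes are uniform
(checked by a KS test on a 200-node featureless network with 200 null
sets; the `Θ/N` denominator leaves a slight conservative deficit of order
`|S|/n` at the top of the unit interval, well inside the KS tolerance at
these sizes). The count-everything variant remains available as
`PermutationConfig(count_self_seed_sets=True)`.

Per-set RNG streams are spawned from one base seed
(`numpy.random.SeedSequence.spawn`), so results are reproducible and
independent of execution order. Candidates are genes with `p < alpha`
(strict; default 0.05, resolution `1/N`).

## Linkage scores

`MIS(g)` is the maximum edge score between `g` and any seed node; absent
(reported `NA`, automatic fail) when `g` has no seed neighbor. The
threshold 900 is inclusive, matching STRING's "highest confidence" floor.

`MFS(g)` is the maximum cosine similarity between annotation vectors of
`g` and each seed, compared at the protein-node level. Two vectorizers
over the sorted GO∪KEGG term universe:

* `binary` — component `t` is 1 iff the gene is annotated to `t`;
* `enrichment` (default) — component `t` is `-log10` of the
  hypergeometric upper-tail probability of the overlap between the
  annotations of the gene's network neighborhood and term `t` (0 when no
  neighbor carries `t`), with the annotated gene catalog as background.

The enrichment form is the default because a gene's functional context in
this style of screen is its interaction neighborhood, and because it
behaves well for module genes: neighborhood aggregation concentrates the
vectors, giving near-1 MFS inside a co-annotated module, whereas binary
cosines between two module genes concentrate near the per-term sharing
rate and are brittle at the exclusive 0.9 cutoff. A gene with an all-zero
vector gets `MFS = NA` and fails the filter rather than erroring; cosine
against a zero vector is defined as 0. The MFS threshold 0.9 is
exclusive. Putative genes satisfy both filters and are reported sorted by
descending propagation probability (ties broken lexicographically).

## Synthetic benchmark

The generator emulates the real inputs with a planted-partition graph:
`n_nodes = 300` genes, a `module_size = 30` planted module, within-module
edge probability `p_in = 0.6` with scores uniform in [900, 999],
background probability `p_out = 0.01` with scores in [150, 400]. Module
genes carry each of 10 designated module terms with probability
`share_in = 0.9` (background genes: `share_out = 0.02`); all genes carry
each of the 40 remaining terms at rate 0.01, a sparse GO-like background
chosen once so that off-module annotations add noise without creating
spurious similarity. The term universe (50 terms, 10 in the module block)
keeps per-gene annotation counts in the range of curated plant GO slims.
Half the module seeds the walk (`seed_fraction = 0.5`); the other half
are held-out positives. All randomness flows from one seed through named
substreams (edges, scores, annotations, split), so each component is
independently reproducible, and writers emit the exact input dialects of
the real parsers (prefixed STRING links, gene lists, annotation TSV) so
synthetic runs exercise the full I/O path.

What the benchmark does not emulate: scale-free degree structure,
STRING's evidence-channel score calibration, ontology depth (terms are
flat), and realistic annotation sparsity. Passing it shows the funnel's
statistics and filters behave as designed on a clean module signal; it
does not certify performance on real interactomes, where hubs,
annotation bias and incomplete seed lists add difficulty.

## Benchmark study sizes

The shipped studies are deliberately desk-scale: recovery uses 10
generator replicates at 200 permutation sets each, and calibration uses a
200-node network with 200 null sets — large enough for 1/200 p-value
resolution and stable KS statistics, small enough that the entire
analysis suite re-runs in seconds. Under the strong-signal design the
pipeline attains precision 1.0 and mean recall ≈ 0.87; the missed
positives are almost entirely permutation-stage losses, i.e. genes whose
exceedance count lands on the wrong side of the `p < 0.05` cutoff at
`N = 200` resolution, not linkage failures. Because background edges in
the benchmark are capped at score 400, no background gene can reach
`MIS ≥ 900`, which is why measured precision is 1; real networks will not
be this forgiving.

## Numerical and degenerate-input choices

* All thresholds follow their stated strictness exactly: probability
  `> 1e-5`, p-value `< 0.05`, `MIS ≥ 900`, `MFS > 0.9`.
* Duplicate directed STRING rows collapse to one undirected edge; on
  conflicting scores the maximum is kept (an asymmetric pair is a data
  defect; the maximum is the conservative choice for MIS). Self-pairs are
  dropped; zero surviving edges is an error, not an empty network.
* Identifier joining is a two-step strip (leading all-digit organism
  prefix, trailing all-digit transcript suffix), each switchable; the
  mapping report lists unmapped seeds rather than guessing.
* Ontology closures traverse both `is_a` and `part_of` (plant anatomy
  attaches parts like pericarp via `part_of`); obsolete terms are
  excluded; a parent reference to an undefined term is dropped with a
  warning.
* `restart_probability = 1` degenerates to `P* = P_0` and is allowed;
  `c = 0` is not (no seed information).
* Hypergeometric tails are clamped at the smallest positive double before
  the `-log10`, bounding enrichment components at ≈ 308.
* Run manifests carry a wall-clock timestamp, but timestamps are kept out
  of all data tables so that identical configs reproduce every table byte
  for byte; the manifest JSON is the one file allowed to differ.

## Known limitations

* The permutation screen holds the whole `n_nodes × N` null matrix in
  memory (~200 MB at STRING scale with N = 1000); a streaming Θ counter
  would be needed for much larger networks.
* Enrichment vectors require the scored entity to be a network node;
  gene-level seed identifiers are therefore vectorized through their
  mapped protein nodes, and an entity absent from the network falls back
  to a zero vector (automatic MFS fail) rather than borrowing a
  neighborhood.
* No multiple-testing correction is applied after the permutation screen,
  by design; the downstream linkage filters are the false-positive
  control.
* The planted-module recovery numbers are specific to the stated
  generator conditions; they are not estimates of sensitivity on real
  data.
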