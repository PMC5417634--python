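# fruitwalk

Network-propagation prioritization of fruit-related genes in *Arabidopsis
thaliana* — and, more generally, of any gene set that forms a functional
module in a weighted protein–protein interaction (PPI) network.

Given a set of validated seed genes (e.g. genes annotated to the Plant
Ontology "fruit" branch), the package ranks every other gene in a
STRING-style weighted PPI network by propagation proximity to the seeds,
screens out genes favored merely by network topology with a permutation
null, and keeps only genes with strong direct and functional links back to
the seeds. It is aimed at computational biologists who have a trusted gene
list and want a ranked, statistically screened list of new candidates.

## Method

**1. Random walk with restart (RWR).** With `A` the column-normalized
score-weighted adjacency of the PPI network and `P_0` the restart vector
(each of the `|S|` seed genes gets mass `1/|S|`), iterate

    P_{i+1} = (1 - c) · A · P_i + c · P_0

with restart probability `c = 0.8` until `||P_{i+1} - P_i||_L1 < 1e-6`.
Non-seed genes with stationary probability above `1e-5` are the **RWR
genes**. (The undamped variant `P_{i+1} = Aᵀ P_i + c P_0` is available as
`update_rule="literal"`; it does not conserve probability mass and is kept
only for comparison.)

**2. Permutation screen.** Re-run the identical propagation from `N`
random seed sets of the same size (default `N = 1000`). Each RWR gene `g`
gets the empirical p-value

    p(g) = Θ / N

where `Θ` counts null sets giving `g` a strictly higher probability than
the real seeds did. Null sets that happen to contain `g` itself do not
count toward `Θ` — in those runs `g` holds restart mass by construction,
so its score is a seed artifact, not a prediction. Genes with `p < 0.05`
are the **candidate genes**.

**3. Linkage tests.** Each candidate is scored against the seeds two ways:

* `MIS(g) = max { S_I(g, g') : g' ∈ S }` — the strongest direct edge to
  any seed (STRING combined score, 150–999);
* `MFS(g) = max { Γ(g, g') : g' ∈ S }` with
  `Γ(g, g') = V(g)·V(g') / (‖V(g)‖·‖V(g')‖)` — the best cosine similarity
  of functional-annotation vectors `V(·)` built from GO terms and KEGG
  pathways (neighborhood hypergeometric-enrichment vectors by default,
  binary incidence optionally).

Candidates with `MIS ≥ 900` (STRING's highest-confidence floor, inclusive)
and `MFS > 0.9` (exclusive) are the final **putative genes**.

Because real STRING + ontology inputs are large external downloads, the
package ships a planted-module synthetic benchmark: a densely connected,
co-annotated module embedded in a sparse background, with half the module
as seeds and half held out, so end-to-end recovery is measurable.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic benchmark and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_propagate.py
python analysis/03_permutation_test.py
python analysis/04_linkage_filters.py
python analysis/05_recovery_benchmark.py
```

Output of the run shipped with this repository:

```
planted-module benchmark written to results/synthetic_inputs
  network: 300 nodes, 683 edges (13 isolated)
  module: 30 genes -> 15 seeds + 15 held-out positives
  annotations: 50 terms (10 shared module terms)
seed mapping: 15 mapped, 0 unmapped
propagation converged in 7 iterations
125 RWR genes above 1e-5 -> results/rwr_genes.tsv
top gene: 3702.G0005.1 (p = 8.297e-03)
125 RWR genes screened against 200 random seed sets
18 candidate genes at p < 0.05 -> results/permutation.tsv
funnel: 125 RWR genes -> 18 candidates -> 13 putative genes
putative genes that are held-out module members: 13 of 13
10-replicate recovery: precision 1.000, recall 0.867
null calibration: KS p = 0.260 over 190 genes
```

Reading: propagation from 15 seeds flags 125 of 300 genes; the
permutation screen cuts those to 18; the two linkage filters cut those to
13, every one of which is a true held-out module member. Averaged over 10
generator seeds the pipeline recovers 87% of held-out positives with no
false positives, and when the "observed" seed set is itself a random draw
the p-values are uniform (no anti-conservative bias).

The same stages are available as a CLI (`fruitwalk simulate | rwr |
permute | linkage | run | compare`) for file-based inputs — real STRING
links files (gzip transparent, organism-code filter), OBO ontologies with
term-closure seed selection, and two-column annotation tables.

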