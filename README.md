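# ldgraphs

Estimation and visualization of chromosome-wide, fine-scale linkage
disequilibrium (LD) structure as decomposable (chordal) graphical models of
SNP data.

Given a complete matrix of unphased genotypes (coded 0/1/2) or phased
haplotypes (coded 0/1) with SNPs in physical order, the package selects a
decomposable graphical model by penalized likelihood (BIC by default,
`IC(G) = -2 loglik + alpha * dim(G)`):

- **Standard search** — greedy forward search starting from the *skeleton*
  (edges between physically adjacent SNPs), adding the decomposability-
  preserving edge with the largest IC reduction, followed by greedy backward
  pruning in which skeleton edges may also be removed.
- **Fast search** — the same forward step applied independently to
  overlapping blocks of `L` SNPs (overlap `K`; defaults 100/20), combined
  left-to-right with the m\* stitching rule that discards boundary-
  contaminated edges, triangulated by maximum cardinality search, then
  pruned. Runtime is linear in the number of SNPs at fixed sample size.

Also included: interval **height/width** complexity profiles, sliding-window
**haplotype entropy** (natural log), **sample trees** (prefix tries of
observed haplotypes, DOT export), pairwise-LD r² matrices and triangular
heatmaps, a smoothed LD-graph **layout/plot**, union-of-graphs edge-frequency
displays, **sampling** from fitted models via the junction forest, a random
sparse-model **generator**, and undershoot/overshoot **graph comparison**.

## CLI

The `ldgraphs` command (or `python -m ldgraphs.cli`) exposes the pipeline;
exit codes: 0 ok, 1 data error, 2 usage error. Every run writes a JSON
manifest next to its outputs.

```sh
# simulate a 200-SNP data set from a random sparse decomposable model
ldgraphs simulate --random --p 200 --n-extra 40 --max-width 6 \
    --n 4000 --seed 1 --out data.tsv --out-graph true.graphml

# fit an LD graph (fast blockwise search, BIC)
ldgraphs fit --data data.tsv --kind haplotype --fast --criterion bic \
    --out-graph fitted.tsv --trace trace.tsv

# compare against the generating graph
ldgraphs compare --true true.graphml --est fitted.tsv

# complexity/diversity metrics and plots
ldgraphs metrics --graph fitted.tsv --data data.tsv --kind haplotype --window 7
ldgraphs plot --graph fitted.tsv --out graph.png
ldgraphs sampletree --data data.tsv --from 10 --to 16 --out tree.dot
ldgraphs heatmap --data data.tsv --from 1 --to 26 --out ld.png
```

Graphs are written as TSV edge lists (1-based pairs `i < j`) or GraphML
(`.graphml` extension; preserves isolated vertices). VCF input (biallelic
SNPs, no missing calls; phased GT required for haplotype mode) is detected
by the `.vcf` extension.

## Library overview

| module      | contents |
|-------------|----------|
| `data_io`   | `MarkerMatrix`, VCF/table readers, validation, graph round-trip |
| `graphcore` | `ChromGraph`, chordality (MCS), triangulation, clique forests, single-edge addability/removability |
| `scoring`   | count tables, decomposable log-likelihood, model dimension (nominal/observed), conditional mutual information, score deltas |
| `selection` | skeleton, forward/backward greedy search, block bounds, m\* stitching, `fit_standard`, `fit_fast` |
| `metrics`   | heights/widths, window entropy, entropy-by-complexity, sample trees, pairwise LD |
| `simulate`  | model fitting, junction-forest sampling, random generators, graph comparison |
| `viz`       | smoothed layout, LD-graph plots, union-of-graphs frequency maps, heatmaps |
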