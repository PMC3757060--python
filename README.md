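# fflnet

Discovery of miRNA–TF feed-forward-loop (FFL) co-regulatory networks from
two-group expression data.

## The problem

MicroRNAs repress genes post-transcriptionally; transcription factors (TFs)
control them transcriptionally. The two regulator families frequently act
together in small recurring circuits: a **3-node FFL** in which a miRNA and
a TF share a common target gene, and a **4-node FFL** in which the miRNA's
target (the *primary* target) physically interacts with a gene bound by the
TF (the *secondary* target). Mapping which miRNA–TF pairs form such circuits
more often than chance — and merging the significant motifs into typed
networks — gives a systems-level picture of how a phenotype such as tumor
cell proliferation is co-regulated. `fflnet` implements this analysis as a
tested, reusable pipeline for anyone with a two-group (e.g. high- vs
low-proliferative) expression study, predicted miRNA targets, conserved
TF-binding sites and a protein-interaction network. A synthetic-data
generator with planted ground truth makes every stage testable without any
external download.

## The method

Given log2 expression matrices for miRNAs and mRNAs over samples split into
`high` and `low` groups:

1. **Differential expression.** After keeping the top 75 % most variable
   miRNA probes, each feature is tested with an empirical-Bayes moderated t:
   the pooled two-group variance s² (d residual df) is shrunk toward a prior,
   s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) estimated from the marginal
   distribution of s² by moment matching on log s², and
   t = log2FC / (s̃·√(1/n₁+1/n₂)) referred to a t distribution on d₀+d df.
   Filters: miRNAs at BH-FDR < 0.05 & |log2FC| ≥ 1, mRNAs (deliberately
   loose, since miRNA effects are subtle) at raw p < 0.05 & |log2FC| ≥ 0.7.
2. **Functional targets.** Predicted targets with TargetScan-style context
   score ≤ −0.1 that are DE in the direction *opposite* to their miRNA.
   A miRNA is kept only if its predicted targets are over-represented among
   DE genes (upper-tail hypergeometric, BH across miRNAs, FDR < 0.05); a
   1,000-draw permutation of the DE list recomputes the enrichment score
   ES = −log10 p to confirm that target-set size does not drive the result.
3. **GO clustering.** Targets are compared by Resnik semantic similarity
   (information content of the maximum-IC common ancestor, best-match
   averaged over term sets) and clustered with FANNY fuzzy clustering on the
   derived dissimilarities. The fuzziness exponent is the smallest value in
   1.1–1.5 whose normalized Dunn coefficient exceeds 0.5 for every candidate
   k; the cluster number in 2–15 maximizes the Dunn index.
4. **FFL motif tests**, per cluster: for each (miRNA, TF) pair an
   upper-tail hypergeometric test on the overlap between the miRNA's DE
   targets and the TF's promoter-bound genes (3-node; the null universe is
   the miRNA's predicted target set) or between the DE members and TF-bound
   members of the miRNA targets' first-neighbor PPI network (4-node).
   A TF's targets are genes with a binding site *completely* inside the
   ±2000 nt promoter window of their TSS; only TFs expressed at log2
   intensity ≥ 8 in at least one group are considered. Pairs at BH-FDR < 0.2
   within each (cluster × motif-type) family are kept, and the coexpression
   of co-regulated genes is checked against random gene pairs with a
   one-sided two-sample Kolmogorov–Smirnov test.
5. **Networks.** Significant motifs merge into one typed graph per cluster
   (miRNA / TF / primary / secondary nodes; miRNA-target, TF-target, PPI
   edges). Degree and exact betweenness are computed; hubs are the top 25 %
   of miRNAs and TFs and the top 5 % of targets by within-type degree;
   walktrap (4-step random walks, cut at maximum modularity) yields modules,
   each labeled by its top enriched gene set.

## Worked example

```python
from fflnet import SimulationParams, PipelineConfig, generate, run_pipeline

bundle, truth = generate(SimulationParams(seed=1))   # planted ground truth
result = run_pipeline(bundle, PipelineConfig(seed=1))

de = result.de_mirnas
print(f"DE miRNAs: {len(de)} ({(de.direction == 'down').sum()} down, "
      f"{(de.direction == 'up').sum()} up)")
print(f"DE mRNAs: {len(result.de_genes)}")
print(f"miRNAs with enriched targets: {len(result.retained_mirnas)}")
print(f"selected clusters: k* = {result.clustering.k}")
sig = result.pair_table[result.pair_table.fdr < 0.2]
print(f"significant miRNA-TF pairs: {len(sig)} "
      f"({(sig.motif_type == 'ffl3').sum()} 3-node, "
      f"{(sig.motif_type == 'ffl4').sum()} 4-node)")
print(f"FFL records: {len(result.records)}")
for cid, net in result.networks.items():
    print(f"network {cid}: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges, "
          f"{len(result.modules[cid])} walktrap modules")
```

On the default synthetic study (7 samples: 4 high- vs 3 low-proliferative;
2,000-gene platform; 17 planted DE miRNAs of which 12 carry inversely
regulated targets; 8 planted 3-node and 6 planted 4-node FFL pairs) this
prints, stage by stage:

```
DE miRNAs: 16 (8 down, 8 up)
DE mRNAs: 314
miRNAs with enriched targets: 12
selected clusters: k* = 2
significant miRNA-TF pairs: 24 (8 3-node, 16 4-node)
FFL records: 178
network C1: 98 nodes, 181 edges, 13 walktrap modules
network C2: 93 nodes, 175 edges, 16 walktrap modules
```

16 of the 17 planted DE miRNAs pass the strict filter at this seed, exactly
the 12 planted enriched miRNAs survive the target-enrichment screen, the
two planted GO branches are recovered (k\* = 2), and all 14 planted
miRNA–TF pairs are among the significant ones (the additional pairs arise
from real cross-talk between planted motifs sharing DE, TF-bound genes).

The same run is available from the shell:

```bash
fflnet --seed 1 --outdir data simulate
fflnet --seed 1 --outdir out all data
```

`out/` then contains every stage table (DE tables, enrichment, cluster
memberships and diagnostics, FFL records, pair summaries, coexpression
statistics, per-network centralities/hubs/modules) plus GraphML and SIF
exports of the networks.

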