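# xsigmeta

Cross-study differential-expression signature meta-analysis, exercised
end-to-end on synthetic signature collections with planted ground truth.

Starting from per-dataset gene-level DE summaries (gene, log2FC, p, FDR),
the pipeline provides:

- **signature_io** — data model, TSV readers/writers with validation,
  ortholog harmonization onto human symbols, per-dataset DEG counting.
- **normalization** — rank-based normalization of log2 fold changes onto
  [-1, 1], gene presence filtering (default: present in >= 70% of datasets),
  top-variable-gene selection (default 2,500), median/kNN imputation.
- **clustering** — pairwise Spearman correlation of normalized signatures,
  dendrogram cluster calling (distance 1 - rho, average linkage) with a
  minimum-size and positive-correlation-dominance rule, optional UMAP
  embedding.
- **meta** — robust rank aggregation implemented from its beta
  order-statistic definition (Bonferroni-corrected score, robust at < 0.05),
  directional recurrence with the > 70% consistency rule, and a two-sample
  KS comparison with exact small-sample enumeration.
- **enrichment** — one-sided Fisher/hypergeometric over-representation
  against GMT libraries with BH control (significant at FDR < 5% and >= 5
  overlapping genes), targeted-panel p-value tiers, pathway recurrence.
- **msea** — marker-set enrichment: markers map to genes within 50 kb, a
  quantile-threshold chi-square-like statistic is calibrated against
  size-matched permuted gene sets (default 10,000) with a Gaussian tail
  and BH correction.
- **network_kda** — weighted key-driver analysis: candidate hubs scored by
  the weighted overlap of their immediate neighborhood with a DEG set,
  against an exactly size-matched membership-permutation null, BH at 5%.
- **synthetic** — generators for signature collections, gene-set libraries,
  weighted networks and marker tables with planted clusters, consistent
  genes, enriched sets, hub drivers and trait associations.

## CLI

```bash
# simulate a collection with planted truth
xsigmeta simulate --config sim.yaml --out signatures/ --seed 1

# full pipeline (simulate or ingest, then all downstream stages)
xsigmeta run-all --config run.yaml --out run/ --seed 1

# individual stages
xsigmeta normalize --in signatures/ --out matrix.tsv
xsigmeta cluster --matrix matrix.tsv --out clust/
xsigmeta rra --in signatures/ --out rra.tsv
xsigmeta enrich --in signatures/ --gmt sets.gmt --out enrich/
xsigmeta msea --markers markers.tsv --gene-models genes.tsv \
    --deg-list degs.txt --out msea.tsv
xsigmeta wkda --network edges.tsv --deg-list degs.txt --out wkda.tsv
```

`run-all` writes every stage's TSV outputs plus a deterministic
`summary.json` run report; identical config and seed give identical
outputs. Config files are YAML mirroring `xsigmeta.pipeline.RunConfig`
(thresholds default to: DEG FDR 0.05, pathway FDR 0.05 with min overlap 5,
RRA score 0.05, consistency 0.70, presence 0.70, top-k 2500, MSEA
permutations 10,000, wKDA FDR 0.05).

## File formats

All plain TSV with headers: signatures (`gene, log2fc, pvalue, fdr`),
metadata (one row per dataset), normalized matrix (gene x dataset, blank =
missing), correlation matrix, cluster assignments, edge lists
(`node_a, node_b, weight`), marker tables (`marker_id, chrom, pos, score`),
BED-like gene models (`chrom, start, end, gene`; 0-based half-open), and
standard GMT for gene-set libraries.

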