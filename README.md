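# silacnet

Weighted correlation network analysis of mixed-reference SILAC peptide-pulldown
proteomics, with a forward simulator for planted reader complexes.

The pipeline mirrors a histone-tail peptide-capture experiment: nine pulldown
conditions (eight modified/unmodified H3-tail peptides plus a beads-only
control) in duplicate, quantified as heavy/light ratios against a pooled
light reference split into nine equal aliquots. From a protein-groups table it

1. filters contaminants/decoys and under-quantified ratios (ratio count >= 2),
2. removes proteins quantified in fewer than 4 of 18 samples, imputes the rest
   to zero (keeping the observation mask),
3. builds a signed weighted correlation network (`a = ((1 + cor) / 2) ** 15`),
   computes the topological overlap matrix, clusters with average linkage and
   cuts the dendrogram into modules of minimum size 5 (unassigned proteins are
   pooled as `grey`),
4. summarizes modules by eigenproteins (first principal component),
   intramodular connectivity (`kWithin`, normalized per module) and hubs,
5. tests each module for binding over the beads control with a paired
   two-tailed t-test and scores per-protein outliers with z-scores against a
   no-enrichment null,
6. turns reciprocal SILAC immunoprecipitations into a bait-normalized,
   weighted interaction network (TSV / GraphML export).

A first-class synthetic-data module generates datasets with known ground
truth: planted complexes that bind as units with condition-specific affinity
signatures, multiplicative lognormal noise, a per-replicate pooled reference,
and abundance-dependent missingness under a logistic detection model. In a
noiseless dataset with heavy = light the per-protein ratio sums over the nine
conditions equal nine exactly — the analytic prediction of the mixed-reference
design.

## CLI

All stages run from one YAML config (see `configs/example.yaml`):

```bash
silacnet simulate --config configs/example.yaml --seed 7 --out out/fixture
silacnet run      --config configs/example.yaml --out out
silacnet stats    --matrix out/ratio_matrix.tsv --modules out/modules.tsv --out out/stats
silacnet export-network --ip-table Atrx ip/atrx.tsv --ip-table Daxx ip/daxx.tsv \
    --connectivity out/connectivity.tsv --out out/ip_net --format graphml
```

`run` writes `ratio_matrix.tsv`, `modules.tsv`, `eigenproteins.tsv`,
`connectivity.tsv`, `module_enrichment.tsv`, `outliers.tsv`,
`dendrogram.newick` and a `manifest.json` (config hash, versions, seed, stage
counts) that makes simulate-mode runs bit-reproducible.

## Package layout

| module | contents |
| --- | --- |
| `silacnet.design` | sample design (conditions x replicates, beads control) |
| `silacnet.synthetic` | signature library, forward simulator, fixture writer |
| `silacnet.ingest` | protein-groups parsing, quality/missingness filters, zero imputation |
| `silacnet.network` | correlation, signed adjacency, soft-threshold scan, TOM, clustering, dynamic tree cut |
| `silacnet.characterize` | eigenproteins, intramodular connectivity, hubs |
| `silacnet.stats` | replicate-mean log2 enrichment, paired t-tests, outlier z-scores, optional BH-FDR |
| `silacnet.ipnet` | bait-normalized IP networks and export |
| `silacnet.pipeline` / `silacnet.cli` | YAML-configured orchestration and CLI |
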