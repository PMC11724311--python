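# qclus

Metric-based clustering QC for single-nuclei RNA-seq droplets: detection
and removal of empty, ambient-contaminated and doublet droplets.

## The problem

Single-nuclei RNA-seq of tissues with large, RNA-rich cells — the human
heart is the canonical case — produces droplet data in which ambient
(cell-free, cytoplasmic) RNA is abundant. Cardiomyocyte cytoplasm dominates
the ambient pool, so empty droplets and contaminated nuclei carry a
convincing cardiomyocyte-like expression profile and slip through standard
count-based filters, ending up annotated as cell types. This package
filters droplets on a small set of contamination-aware QC metrics instead
of on expression itself.

## The method

For every droplet six clustering features are computed:

- **fraction_unspliced** — unspliced reads / (spliced + unspliced +
  ambiguous). Nuclear RNA is intron-rich; cytoplasmic ambient RNA is
  spliced, so empty droplets sit low.
- **pct_mito** — percent of counts on the 13 mitochondrially encoded genes
  (`MT-ND1` … `MT-CYB`). Mitochondria are cytoplasmic: a contamination
  tracker, computed on raw counts.
- **nuclear_fraction** — fraction of counts on 30 nuclear-retained,
  MALAT1-correlated genes, computed on log1p-transformed counts.
- **pct_cm_nuclear** / **pct_cm_cyto** — percent of counts on
  cardiomyocyte markers enriched in nuclei (23 genes, `RBM20` …) versus in
  cytoplasm/ambient RNA (8 genes, `TTN`, `RYR2` …).
- **pct_nonCM_max** — the maximum percent of counts over 11 non-CM
  cell-type marker sets.

The pipeline then runs five steps:

1. **Initial filter** — keep droplets with 500 ≤ detected genes ≤ 6000 and
   mitochondrial percentage ≤ 40 (all bounds inclusive).
2. **Scaling** — min-max scale the features to [0, 1] over survivors.
3. **Quality clustering** — k-means (k = 4) on the scaled features; the
   cluster with the lowest mean unspliced fraction is removed as empty
   droplets (any number of clusters can be removed).
4. **Outlier filter** — with a reference cluster (highest mean
   `pct_nonCM_max`), remove droplets with unspliced fraction below
   Q1(reference) − 0.1 **and** mitochondrial percentage above
   Q3(reference) + 5.
5. **Doublet filter** — simulated-doublet nearest-neighbour scoring;
   droplets whose score exceeds 0.1 are removed (this also catches
   contaminated "pseudo-doublets").

Other tissues swap gene sets and features: the packaged brain
configuration drops the two CM features, uses k = 3, a 400-gene floor and
anchors the outlier filter on the highest-mean-unspliced cluster.

## Worked example

```python
import qclus

matrix, truth, registry = qclus.generate_population(qclus.SyntheticParams(), seed=11)
cfg = qclus.synthetic_pipeline_config(seed=11)
result = qclus.run_qclus(matrix, registry, cfg)
for step, mask in result.masks.items():
    print(f"after {step:15s}: {int(mask.sum()):5d} droplets retained")
```

prints

```
after splicing_info  :  5000 droplets retained
after initial_filter :  5000 droplets retained
after cluster_removal:  3483 droplets retained
after outlier_filter :  2889 droplets retained
after doublet_filter :  2568 droplets retained
```

On this synthetic population the 1517 droplets removed in the clustering
step are exactly the 1517 planted empty droplets (precision and recall
1.0); the outlier step removes 594 of the 598 planted contaminated nuclei
and the doublet step 316 of the 415 planted doublets, while 2465 of 2470
clean nuclei are retained. `result.report` holds the per-droplet metric
values, cluster labels and removal reasons; `qclus.write_results` writes
the retained-barcode list, a TSV report and a YAML manifest from which the
run can be reproduced exactly.

Real data enters through `qclus.read_matrix` (MTX directory or `.h5ad`),
`qclus.attach_layers` (loom-style spliced/unspliced/ambiguous container)
or `qclus.read_unspliced_table` (precomputed per-barcode fractions), and
the same pipeline is available from the shell:

```bash
qclus run --matrix filtered_feature_bc_matrix/ --layers sample.loom --out qc/
qclus simulate --preset heart --n-droplets 5000 --seed 0 --out sim/
qclus evaluate --summaries summaries.tsv --out eval/
```

The `examples/` directory contains one short narrative script per
capability.

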