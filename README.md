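# fibrosig

Myocardial fibrosis — excess extracellular-matrix (ECM) deposition by
activated cardiac fibroblasts — is a hallmark of end-stage heart failure
(HF) and of the healing infarct. `fibrosig` is a Python toolkit for the
transcriptomic side of that problem, for researchers who want to connect
three kinds of data:

1. **Patient gene panels** (nCounter-style counts for ~82 fibrosis-related
   genes): housekeeping normalization, age correction, and selection of an
   *optimal* informative gene subset by the **projection score** — the
   variance fraction captured by the top *d* principal components of a
   candidate subset, minus its expectation over random subsets of equal
   size, scanned over variance-filter thresholds. Ward clustering on the
   selected signature splits HF patients into subclusters and
   clinical-feature enrichment ratios describe them.
2. **Cultured cardiac-cell scRNA-seq** with spliced/unspliced counts:
   QC, simulated-doublet scoring, Louvain clustering, t-test markers,
   marker-rule cell typing (endothelial / macrophage / fibroblast with
   double-positive flags), fibroblast state calls (matrix-producing vs
   contractile), cell-cycle phases, a 17-gene proliferation score, and
   steady-state **RNA velocity**: per-gene degradation/splicing ratios
   γ fit on extreme-quantile cells, per-cell velocity v = u − γs, a
   cosine velocity graph, and arrows projected into a 2-D embedding to
   read off the branched fibroblast activation path (FB2 → FB3/FB4 →
   FB5 → FB6).
3. **Bulk infarct time courses**: one-way ANOVA across disease stages
   with Benjamini–Hochberg q-values, hypergeometric marker–DE overlap
   tests (log-factorial tail sums), marker-set PCA with silhouette
   stage-separation scores, and stage × marker-set z-score heatmaps.

A patient signature is matched to fibroblast subpopulations by Pearson
correlation of per-group z-scored profiles, across species via a bundled
human↔mouse symbol map.

Because the study's raw data are not deposited, the package ships a
first-class synthetic-data module (`fibrosig.synth`) that generates all
dataset kinds with ground truth: a 10-donor / 65-patient cohort with two
HF subclusters driven by a 12-gene block (ACE2 moving opposite to the
rest), an ~8000-cell culture with six fibroblast subpopulations on a
branched trajectory with two-state splicing kinetics, a cell-type
reference that round-trips the gene-assignment rule, and stage-mixed
bulk time courses.

## Worked example

```python
from fibrosig import panel, projscore, synth

cohort = synth.generate_patient_cohort(synth.CohortConfig(seed=0))
norm = panel.normalize_reference_genes(cohort)           # GAPDH, GUSB, ...
norm = panel.correct_age(norm, cohort.metadata["age"])
values = norm.values.loc[norm.nonreference_genes]
result = projscore.select_optimal_subset(
    values.T, projscore.ProjectionScoreConfig(d=2, B=100, seed=0)
)
print(f"best threshold: {result.best_threshold:.2f}")
print(f"selected {len(result.best_subset)} genes: {sorted(result.best_subset)}")

clus = panel.cluster_patients(norm, result.best_subset, cohort.metadata, k=2)
hf = cohort.metadata["group"] == "HF"
flags = cohort.metadata.loc[hf, ["ischemic", "diabetes", "high_bmi", "female"]]
print(panel.enrichment_ratio(clus["labels"][hf], flags).round(2).to_string())
```

prints

```
best threshold: 0.85
selected 12 genes: ['ACE2', 'CCL2', 'COL12A1', 'COL14A1', 'COL15A1', 'COL1A1',
 'COL1A2', 'COL3A1', 'COL6A1', 'FBN1', 'TGFB1', 'TIMP3']
          pct_cluster1  pct_cluster2  ratio  undefined
feature
ischemic         38.89         79.31   2.04      False
diabetes         11.11         48.28   4.34      False
high_bmi         44.44         34.48   0.78      False
female           36.11         27.59   0.76      False
```

The threshold scan recovered exactly the 12-gene fibrosis block planted
by the generator (seven collagens, FBN1, TIMP3, TGFB1, CCL2 and ACE2);
clustering HF patients on it yields a severe subcluster (cluster 2, the
one with higher signature expression) in which ischemic disease and
diabetes are enriched — the `ratio` column is pct(cluster 2)/pct(cluster 1).

The same objects drive the single-cell and staging stages; see
`fibrosig sc`, `fibrosig velocity`, `fibrosig match` and `fibrosig stage`
(each CLI command is a thin wrapper over one module), or the test suite
for library-level chains.

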