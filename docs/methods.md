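# Methods

This note documents the models, the numerical choices and the synthetic
data the test suite runs on, and what passing those tests does and does
not demonstrate.

## Panel normalization and age correction

nCounter-style counts are normalized against five housekeeping genes
(GAPDH, GUSB, PGK1, POLR2A, RPLP0): each sample's scale is the geometric
mean of its reference counts, and counts are multiplied by
(cohort-median scale / sample scale) before log2(x+1). Anchoring at the
cohort median keeps values on the original count scale, which is the
whole content of our "reference-gene grouping" correction; no further
adjustment is attempted because the upstream description of that step is
not specific enough to reimplement. The +1 pseudocount is needed because
panel zeros occur. Age correction is per-gene OLS of the normalized
value on age; the output is the residual plus the fit at the cohort mean
age, so values stay on the normalized scale and the post-correction age
slope is zero by construction.

Welch's unequal-variance t-test (two-sided) is the two-group statistic;
the HF and donor groups differ 6.5-fold in size and there is no reason
to assume equal variances.

## Variance filter and projection score

The variance filter keeps the top `round((1 - t) * n_genes)` genes by
sample variance (at least one; ties broken by gene id). We read the
threshold as a count-quantile rather than an interpolated value-quantile
because only the count form makes the scan's subset sizes well defined
on small panels (an interpolated cutoff on 82 genes can never yield a
12-gene subset on a 0.05-step grid).

For a subset S, α(S, d) = sqrt(Σ_{i≤d} λ_i / Σ_j λ_j) over eigenvalues
of the correlation matrix of S (per-gene z-scoring first, because panel
genes differ in scale by orders of magnitude). The projection score
τ = α(S) − mean α over B random subsets of size |S| drawn from the full
gene universe. Defaults d = 2 (the downstream embedding is 2-D) and
B = 100. The noise scale of τ is the *null standard deviation* (α of
one subset is a single draw from the null, not an average), so a scan
result is flagged uninformative when best τ < 2·sd_null. Scan ties
prefer the larger subset, then the lower threshold.

## Gene-to-cell-type assignment

Reference cell types are pooled into three groups (cardiomyocyte;
fibroblast + pericyte; everything else) and specificity fractions
s_c = group mean / Σ group means computed per gene. Thresholds
θ_dom = 0.5 and θ_both = 0.3 are explicit choices: dominant means "at
least half of the pooled signal with the other group below 0.3"; "both"
means both focal groups reach 0.3. All-zero genes fall to "other" with
a flag. Note that a perfectly uniform gene has fractions 1/3 ≥ θ_both
in both focal groups and is therefore "both" under this rule; only
genes whose signal concentrates outside the two focal groups are
"other".

## Single-cell stage

Gene QC requires ≥ 20 total spliced *and* ≥ 20 total unspliced counts.
Doublet scoring simulates `ceil(sim_ratio·n)` synthetic doublets as
random cell-pair count sums, co-embeds observed and synthetic cells by
PCA of log depth-normalized counts, and scores each observed cell by
the synthetic fraction among its k = 30 co-embedded neighbors, rescaled
by the synthetic proportion (1 = at chance); cells above the 0.99 score
quantile are removed. This is a deliberately simple detector: it flags
heterotypic doublets well and homotypic doublets poorly, like all
simulation-based detectors.

Normalization scales each cell's spliced counts to the median total,
then log1p; PCA (30 components) and a Euclidean kNN graph (k = 30)
follow. Optional per-batch mean-centering of PCs is the only batch
handling — full integration is out of scope, and the generator's batch
effects are mild by design so the option is exercisable. Louvain
community detection (igraph multilevel, seeded through Python's RNG)
takes a resolution parameter; a scan helper picks the resolution
maximizing ARI against an annotation when one exists.

Cell typing is rule-based on per-gene z-scores of the normalized layer:
Emcn z > 1 → endothelial, else Lyz2 z > 1 → macrophage, else
fibroblast. Double positives are *flags*, not labels, and use a softer
cutoff (z > 0.5): with a single threshold a Lyz2-high fibroblast would
be unreachable, since Lyz2-high forces the macrophage label by rule
precedence. Fibroblast states compare the z-scored Col1a1/Col1a2 set
against the Acta2/Tpm2 set within fibroblasts; ties break to
contractile. Cell-cycle phase is argmax of mean z-scored S and G2M set
scores when positive, else G1. The proliferation score is the
unweighted mean of 17 z-scored genes (Ccnd1, Ccnd2, Mki67, Pcna plus 13
standard cycle genes — the full published list is not printed, so the
remainder is our documented choice); score > 0 counts as proliferating,
a symmetric null.

## Steady-state RNA velocity

We implement the deterministic first-moment model rather than a
second-moment ("stochastic") variant: after first-order kNN averaging
of depth-normalized spliced (s) and unspliced (u) layers, each gene's
γ is fit by regression through the origin, Σus/Σs², over the union of
cells in the bottom and top q = 0.05 quantiles of s (ties included, so
a constant gene uses all cells; genes with fewer than 4 extreme cells
fall back to all cells; all-zero genes are flagged unfitted). Velocity
is v = u − γs. The velocity graph holds cosine similarities between v_i
and the displacement to each kNN neighbor in log1p expression space of
the fitted genes (log1p variance-stabilizes the displacement; the
choice is stated because nothing upstream fixes it). Embedded arrows
use transition weights softmax(c_ij/σ), σ = 0.1, minus the uniform
distribution, applied to embedding displacements, so a cell with a flat
cosine profile gets a zero arrow. The model recovers *directions*
(which branch a population feeds) — its γ values are attenuated a few
percent by noise in s, which is why tests check direction recovery and
ratio consistency, not exact per-cell numbers.

## Signature matching

A signature profile is per-group mean expression of an ordered gene
set, z-scored per gene across groups with the population (n)
denominator (exactly reproducible in tests). Cross-species alignment
uses the bundled explicit human↔mouse symbol table; unmapped genes
raise rather than silently dropping. Matching is plain Pearson
correlation between profile columns; genes constant in either profile
are excluded, and fewer than three usable genes is an error.

## Staging

ANOVA is one-way per gene on log1p expression across stages; degenerate
(flat) genes get p = 1 with a flag. BH q-values use the standard
step-up with clipping. The hypergeometric upper tail is summed in log
space (gammaln binomials + log-sum-exp), exact to 1e-12 against direct
enumeration on small universes. Stage separation is operationalized as
the mean silhouette of stage labels in the first two PCs of the
z-scored gene subset — a scalar stand-in for "clusters better". The
overlap-test universe is an explicit parameter (all genes surviving
expression filtering) because published universes are often ambiguous.

## What the generators emulate

* **Cohort** (82 genes × 75 samples): NB counts (var = μ + φμ²,
  φ = 0.1) around log-normal baselines; reference genes share only the
  library factor; HF adds 1 log2 unit on 39 fibrosis genes; a 45%
  subset of HF patients (subcluster sizes are not published; this is a
  free parameter) adds 1.5 log2 units on the 12 signature genes with
  ACE2 reversed; clinical flags use the published 84%/46% ischemia
  rates; a few genes drift 0.02 log2/year with age.
* **Culture** (8000 cells × 250 genes): populations EC 0.89%,
  macrophages 24.9%, fibroblasts 74.2% with FB1..FB6 at
  13/15/25.7/12/22.3/12% of fibroblasts (largest-remainder rounding,
  ties by name). Cells sit on a branched pseudotime (FB2 root; FB3/FB4
  parallel; FB5; FB6; FB1 a resting side branch that winds the program
  back down). An 88-gene activation program (named ECM genes plus
  unnamed block — activation remodels a broad program, and direction
  recovery genuinely needs that breadth) rises along the trajectory
  with logistic onsets; spliced levels follow unspliced with a
  pseudotime lag of 0.35, which is what makes induction visible to the
  steady-state model. Steady genes satisfy mean u / mean s =
  degradation/splicing ratio (0.25 on average). Identity markers are
  near-zero outside their population, and endothelial markers are
  exclusive — with a z > 1 typing rule, a sparse marker with nonzero
  background would flag every background cell holding a single count,
  so a 0.89% population can only be typed cleanly if its marker is
  truly specific. Fibroblast states are bimodal with a 4 log2-unit
  Col1a1/Acta2 separation; the 12 signature genes (mouse symbols) jump
  late on the FB5→FB6 segment with Ace2 falling, so only FB6's profile
  matches the patient cluster-2 signature. FB4 carries the G2M and
  proliferation boosts; FB1/FB3 are de-enriched (FB1 keeps its
  Ccnd1/Ccnd2 peak); FB5/FB6 get +1 log2 on the proliferation set,
  sized to survive the depth-normalization deflation that their high
  program load causes. Doublets (1%) overwrite cells with random pair
  sums. Three batches with 0.05-sd log-normal gene effects.
* **Bulk** (1750 genes × 20 samples): each stage's expectation is a
  convex mixture of the culture population signatures (FB4 weight peaks
  at 3d; FB5/FB6 at 7d; near-uninjured by 2w) plus constant background
  genes; 4 replicates per stage with φ = 0.01 and 4% library sd —
  bulk replicate noise, far tighter than single-cell. "Planted" DE
  truth = expected stage range > 2-fold.
* **Reference**: category patterns (0.80/0.05/0.15 etc.) chosen so the
  default rule round-trips exactly at zero noise; optional log-normal
  noise.

What passing these tests shows: the pipeline's operators recover the
structure they are designed for at realistic effect sizes and depths,
with calibrated error rates. What it does not show: robustness to
platform artifacts (lane effects, spike-ins, ambient RNA, sequencing
error), to continuous (non-blocky) population structure, to strong
batch confounding, or to homotypic doublets — none of which the
generators emulate.

## Problem sizes and determinism

Defaults throughout are the sizes above; tests and the acceptance
script run the full 8000-cell chain in seconds on one CPU. Every
stochastic step takes an explicit seed; identical config + seed is
bit-identical. Degenerate inputs (zero-variance genes, empty clusters,
all-zero references, isolated cells) raise or flag rather than
propagate NaNs, as documented per operation.
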