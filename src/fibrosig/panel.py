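"""Patient gene-panel analysis.

Reference-gene (housekeeping) normalization of nCounter-style counts,
linear age correction, variance filtering, Ward subclustering of heart
failure patients on the fibrosis signature, clinical-feature enrichment
ratios, and Welch two-group differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .genes import REFERENCE_GENES, SIGNATURE_GENES_HUMAN
from .staging import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class PanelCohort:
    """Gene-panel counts (genes x samples) with per-sample metadata.

    Metadata columns: ``group`` in {donor, HF}, ``age`` (years), boolean
    clinical flags (ischemic, diabetes, high_bmi, female) and, for
    synthetic cohorts, the ground-truth ``true_subcluster``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not self.counts.columns.equals(self.metadata.index):
            self.metadata = self.metadata.loc[self.counts.columns]
        if (self.metadata["age"] <= 0).any():
            raise ValueError("ages must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class NormalizedPanel:
    """log2-scale normalized panel values with provenance flags."""

    values: pd.DataFrame
    factors: pd.Series
    ref_genes: list[str] = field(default_factory=list)
    age_corrected: bool = False

    @property
    def nonreference_genes(self) -> list[str]:
        return [g for g in self.values.index if g not in self.ref_genes]


def normalize_reference_genes(
    cohort: PanelCohort, ref_genes: list[str] | None = None
) -> NormalizedPanel:
    """Scale each sample by its reference-gene geometric mean, then log2.

    The per-sample scale is the geometric mean of the five housekeeping
    counts; counts are multiplied by (cohort median scale / sample scale),
    anchoring values on the original count scale, then log2(x + 1).
    """
    ref_genes = list(ref_genes or REFERENCE_GENES)
    missing = [g for g in ref_genes if g not in cohort.counts.index]
    if missing:
        raise ValueError(f"reference genes absent from panel: {missing}")
    refs = cohort.counts.loc[ref_genes].astype(float)
    dead = refs.columns[(refs <= 0).all(axis=0)]
    if len(dead):
        raise ValueError(f"all-zero reference counts in samples: {list(dead)}")
    scale = np.exp(np.log(refs.where(refs > 0)).mean(axis=0))
    factors = scale.median() / scale
    values = np.log2(cohort.counts.astype(float).mul(factors, axis=1) + 1.0)
    return NormalizedPanel(values=values, factors=factors, ref_genes=ref_genes)


def correct_age(panel: NormalizedPanel, ages: pd.Series) -> NormalizedPanel:
    """Remove the per-gene linear age trend by OLS.

    Output = residual + fitted value at the cohort mean age, so corrected
    values stay on the normalized log2 scale.
    """
    ages = ages.loc[panel.values.columns].astype(float)
    if len(ages) < 3 or ages.nunique() < 2:
        raise ValueError("age correction needs >= 3 samples with varying age")
    x = ages.to_numpy()
    xc = x - x.mean()
    y = panel.values.to_numpy()
    slope = (y * xc).sum(axis=1) / (xc**2).sum()
    corrected = y - np.outer(slope, xc)
    return replace(
        panel,
        values=pd.DataFrame(
            corrected, index=panel.values.index, columns=panel.values.columns
        ),
        age_corrected=True,
    )


def variance_filter(values: pd.DataFrame, threshold: float) -> list[str]:
    """Keep the most variable genes: the top (1 - threshold) count-quantile.

    ``threshold`` is a variance-quantile level in [0, 1): 0 keeps every
    gene and levels near 1 keep only the single most variable gene. The
    kept count is round((1 - threshold) * n_genes), at least 1; ties are
    broken deterministically by gene id order.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    if values.empty:
        raise ValueError("empty panel")
    variances = values.var(axis=1, ddof=1)
    n = len(variances)
    k = max(1, int(np.floor((1 - threshold) * n + 0.5)))
    order = sorted(values.index, key=lambda g: (-variances[g], g))
    return order[:k]


def cluster_patients(
    panel: NormalizedPanel,
    genes: list[str],
    metadata: pd.DataFrame,
    k: int = 2,
    signature_genes: list[str] | None = None,
    embedding: str = "pca",
    seed: int = 0,
) -> dict:
    """Ward-cluster HF patients on z-scored signature genes.

    Donors keep the label ``donor``; HF samples get cluster ids 1..k,
    ordered so that cluster 2 has the higher mean over the non-ACE2
    signature genes (the severe-fibrosis subcluster). A 2-D embedding of
    all samples is returned for visualization.
    """
    missing = [g for g in genes if g not in panel.values.index]
    if missing:
        raise ValueError(f"genes absent from panel: {missing}")
    sub = panel.values.loc[genes]
    z = sub.sub(sub.mean(axis=1), axis=0).div(
        sub.std(axis=1).replace(0, 1.0), axis=0
    )
    hf = metadata.index[metadata["group"] == "HF"]
    if k > len(hf):
        raise ValueError("k exceeds number of HF samples")
    hf = [s for s in panel.values.columns if s in set(hf)]  # deterministic order
    zhf = z[hf].T.to_numpy()
    linkage = hierarchy.ward(zhf)
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")

    up_genes = [
        g for g in (signature_genes or SIGNATURE_GENES_HUMAN)
        if g in z.index and g != "ACE2"
    ]
    means = {
        c: z.loc[up_genes, [s for s, r in zip(hf, raw) if r == c]].values.mean()
        for c in np.unique(raw)
    }
    order = sorted(means, key=lambda c: means[c])  # ascending: last = cluster k
    relabel = {c: i + 1 for i, c in enumerate(order)}

    labels = pd.Series("donor", index=panel.values.columns, dtype=object)
    labels.loc[hf] = [relabel[c] for c in raw]

    if embedding == "pca":
        coords = PCA(n_components=2, svd_solver="full").fit_transform(z.T)
    else:  # pragma: no cover - pluggable visual embedding
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2, random_state=seed, perplexity=min(30, z.shape[1] - 1)
        ).fit_transform(z.T.to_numpy())
    emb = pd.DataFrame(coords, index=panel.values.columns, columns=["dim1", "dim2"])
    cluster_means = pd.DataFrame(
        {c: z.loc[:, labels == c].mean(axis=1) for c in relabel.values()}
    )
    return {"labels": labels, "embedding": emb, "cluster_means": cluster_means}


def enrichment_ratio(labels: pd.Series, flags: pd.DataFrame) -> pd.DataFrame:
    """Clinical-feature percentages per HF cluster and cluster-2/1 ratios.

    ``ratio`` = pct_cluster2 / pct_cluster1; flagged undefined (NaN ratio)
    when no cluster-1 patient carries the feature.
    """
    in1, in2 = labels == 1, labels == 2
    if in1.sum() == 0 or in2.sum() == 0:
        raise ValueError("both clusters must be non-empty")
    rows = []
    for feature in flags.columns:
        f = flags[feature].astype(bool)
        pct1 = 100.0 * f[in1].mean()
        pct2 = 100.0 * f[in2].mean()
        undefined = pct1 == 0
        rows.append(
            {
                "feature": feature,
                "pct_cluster1": pct1,
                "pct_cluster2": pct2,
                "ratio": np.nan if undefined else pct2 / pct1,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def two_group_de(
    panel: NormalizedPanel,
    metadata: pd.DataFrame,
    group_a,
    group_b,
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per gene between two sample groups, BH-adjusted.

    ``group_a``/``group_b`` are values of ``metadata[group_col]`` (or
    boolean masks). Genes flat in both groups are skipped with a notice.
    """
    if isinstance(group_a, str) or np.isscalar(group_a):
        mask_a = (metadata[group_col] == group_a).to_numpy()
        mask_b = (metadata[group_col] == group_b).to_numpy()
    else:
        mask_a, mask_b = np.asarray(group_a), np.asarray(group_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    genes = panel.nonreference_genes
    a = panel.values.loc[genes].to_numpy()[:, mask_a]
    b = panel.values.loc[genes].to_numpy()[:, mask_b]
    flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if flat.any():
        log.info("%d genes with zero variance in both groups skipped", flat.sum())
    t, p = stats.ttest_ind(a[~flat], b[~flat], axis=1, equal_var=False)
    out = pd.DataFrame(
        {"t": t, "p": p, "q": bh_adjust(p)},
        index=pd.Index(np.asarray(genes)[~flat], name="gene"),
    )
    out["significant"] = out["q"] < alpha
    return out
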