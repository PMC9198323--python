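"""Staging of bulk infarct time courses with fibroblast-subpopulation markers.

Hosts the shared multiple-testing (Benjamini-Hochberg) and hypergeometric
overlap primitives, one-way ANOVA differential expression across disease
stages, marker-set PCA with a stage-separation (silhouette) score, and
stage x marker-set mean z-score heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BulkTimecourse:
    """Bulk expression (genes x samples) with ordered stage labels."""

    expression: pd.DataFrame
    stages: pd.Series  # per sample, ordered categorical
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stage_order:
            self.stage_order = list(pd.unique(self.stages))
        if len(self.stage_order) < 2:
            raise ValueError("a time course needs at least 2 stages")
        missing = set(self.stages.index) ^ set(self.expression.columns)
        if missing:
            raise ValueError(f"stage labels and samples disagree: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.expression.index


@dataclass
class OverlapTest:
    """Hypergeometric overlap between a marker set and a DE set."""

    universe_size: int
    de_size: int
    set_size: int
    overlap: int
    expected: float
    p_value: float


# ---------------------------------------------------------------------------
# Shared primitives
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _log_binom(n: float, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_overlap(marker_set, de_set, universe) -> OverlapTest:
    """Upper-tail hypergeometric test P(X >= k) for a marker/DE overlap.

    The tail sum is evaluated with log-binomial coefficients (gammaln) and a
    log-sum-exp reduction so that tiny p-values on large universes do not
    underflow intermediate terms.
    """
    universe = set(universe)
    marker_set = set(marker_set) & universe
    de_set = set(de_set) & universe
    big_n, big_k, n = len(universe), len(de_set), len(marker_set)
    if n > big_n:
        raise ValueError("marker set larger than universe")
    k = len(marker_set & de_set)
    expected = n * big_k / big_n if big_n else 0.0
    kmax = min(n, big_k)
    if k == 0:
        p = 1.0
    else:
        ks = np.arange(k, kmax + 1)
        logs = (
            _log_binom(big_k, ks)
            + _log_binom(big_n - big_k, n - ks)
            - _log_binom(big_n, n)
        )
        top = logs.max()
        p = float(min(1.0, np.exp(top) * np.exp(logs - top).sum()))
    return OverlapTest(big_n, big_k, n, k, expected, p)


# ---------------------------------------------------------------------------
# Stage-wise differential expression
# ---------------------------------------------------------------------------

def anova_de(bulk: BulkTimecourse, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across stages, per gene, on log1p expression.

    Returns a per-gene table with F, p and BH q; ``de`` marks q < alpha.
    Genes with zero variance everywhere get the p = 1 convention and a flag.
    """
    values = np.log1p(bulk.expression.to_numpy(dtype=float))
    groups = [
        values[:, (bulk.stages == s).to_numpy()] for s in bulk.stage_order
    ]
    if any(g.shape[1] < 2 for g in groups):
        raise ValueError("every stage needs >= 2 replicates for ANOVA")
    f, p = stats.f_oneway(*groups, axis=1)
    degenerate = ~np.isfinite(f)
    if degenerate.any():
        log.info("%d genes with no variance: p set to 1", int(degenerate.sum()))
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"F": f, "p": p, "q": q, "de": q < alpha, "degenerate": degenerate},
        index=bulk.genes,
    )


# ---------------------------------------------------------------------------
# Marker-set staging
# ---------------------------------------------------------------------------

def pca_stage_separation(
    bulk: BulkTimecourse, gene_set, n_pc: int = 2
) -> dict:
    """PCA of a z-scored gene subset with a stage-label silhouette score.

    Returns PC coordinates (samples x n_pc), the silhouette of the stage
    labels in that space, and per-PC explained-variance percentages.
    """
    genes = [g for g in gene_set if g in bulk.expression.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 genes present in the bulk data")
    if len(bulk.stage_order) < 2:
        raise ValueError("need at least two stages")
    values = np.log1p(bulk.expression.loc[genes].to_numpy(dtype=float))
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = ((values - mu) / sd).T  # samples x genes
    n_pc = min(n_pc, min(z.shape) - 1, len(genes))
    pca = PCA(n_components=n_pc, svd_solver="full")
    coords = pca.fit_transform(z)
    sil = float(silhouette_score(coords, bulk.stages.to_numpy()))
    return {
        "coords": pd.DataFrame(
            coords,
            index=bulk.expression.columns,
            columns=[f"PC{i + 1}" for i in range(n_pc)],
        ),
        "silhouette": sil,
        "variance_pct": 100 * pca.explained_variance_ratio_,
    }


def stage_score_heatmap(
    bulk: BulkTimecourse, marker_sets: dict[str, list[str]]
) -> dict:
    """Stage x marker-set matrix of mean z-scores and per-set peak stages.

    Each gene is z-scored across samples (expression relative to its mean
    over the time course), averaged within the set, then within each stage.
    """
    values = np.log1p(bulk.expression.to_numpy(dtype=float))
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = pd.DataFrame(
        (values - mu) / sd, index=bulk.genes, columns=bulk.expression.columns
    )
    cols, peaks = {}, {}
    for name, genes in marker_sets.items():
        present = [g for g in genes if g in z.index]
        if not present:
            log.info("marker set %s has no genes in the bulk data; skipped", name)
            continue
        per_sample = z.loc[present].mean(axis=0)
        stage_means = per_sample.groupby(bulk.stages, observed=True).mean()
        stage_means = stage_means.reindex(bulk.stage_order)
        cols[name] = stage_means
        peaks[name] = stage_means.idxmax()
    matrix = pd.DataFrame(cols)
    matrix.index.name = "stage"
    return {"matrix": matrix, "peak_stage": peaks}
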