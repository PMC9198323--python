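"""Single-cell stage: QC, doublet scoring, normalization, clustering,
markers, cell typing, fibroblast states, cell cycle and proliferation.

All operations act on an AnnData with ``spliced``/``unspliced`` layers
(the container produced by the synthetic generator or read from MTX
triplets). Derived layers and graphs are written back in place following
the usual single-cell conventions (``X`` = normalized log expression,
``obsm["X_pca"]``, ``obsm["knn_indices"]``).
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import anndata as ad
import igraph
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .genes import (
    CONTRACTILE_GENES,
    G2M_GENES,
    MATRIX_STATE_GENES,
    PROLIFERATION_GENES,
    S_PHASE_GENES,
)
from .staging import bh_adjust

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC and doublets
# ---------------------------------------------------------------------------

def qc_filter_genes(adata: ad.AnnData, min_count: int = 20) -> ad.AnnData:
    """Keep genes with total spliced >= min_count AND total unspliced >= min_count."""
    s = np.asarray(adata.layers["spliced"]).sum(axis=0)
    u = np.asarray(adata.layers["unspliced"]).sum(axis=0)
    keep = (s >= min_count) & (u >= min_count)
    if not keep.any():
        raise ValueError("QC removed every gene")
    return adata[:, keep].copy()


def doublet_score(
    adata: ad.AnnData,
    k: int = 30,
    sim_ratio: float = 1.0,
    threshold_quantile: float = 0.99,
    n_pcs: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated-doublet kNN score per cell, plus a removal mask.

    ceil(sim_ratio * n) synthetic doublets are formed as sums of random
    observed cell pairs; observed cells and synthetics are co-embedded by
    PCA of log-normalized counts, and each observed cell is scored by the
    fraction of synthetics among its k nearest co-embedded neighbors,
    rescaled by the synthetic proportion so 1.0 means "at chance". Cells
    above the score's threshold quantile are flagged for removal.
    """
    n = adata.n_obs
    if n < 2 * k:
        raise ValueError("need at least 2k cells for doublet scoring")
    rng = np.random.default_rng(seed)
    counts = np.asarray(adata.layers["spliced"], dtype=float)
    m = int(np.ceil(sim_ratio * n))
    p1 = rng.integers(0, n, m)
    p2 = rng.integers(0, n, m)
    synth = counts[p1] + counts[p2]
    combined = np.vstack([counts, synth])
    totals = combined.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    logn = np.log1p(combined / totals * np.median(combined.sum(axis=1)))
    n_pcs = min(n_pcs, logn.shape[1] - 1)
    coords = PCA(n_components=n_pcs, random_state=seed).fit_transform(logn)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords[:n])
    idx = idx[:, 1:]  # drop self
    frac_synth = (idx >= n).mean(axis=1)
    chance = m / (m + n)
    score = frac_synth / chance
    cut = np.quantile(score, threshold_quantile)
    return pd.DataFrame(
        {"score": score, "remove": score > cut}, index=adata.obs_names
    )


# ---------------------------------------------------------------------------
# Preprocessing and clustering
# ---------------------------------------------------------------------------

def preprocess(
    adata: ad.AnnData,
    n_top_genes: int = 2000,
    n_pcs: int = 30,
    k: int = 30,
    batch_center: bool = False,
    seed: int = 0,
) -> ad.AnnData:
    """Total-count scale spliced counts to the median, log1p, PCA, kNN graph.

    Cells with zero total counts are removed with a notice. With
    ``batch_center`` the PCs are mean-centered per batch (a light-weight
    stand-in for full batch integration).
    """
    counts = np.asarray(adata.layers["spliced"], dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        log.info("removing %d cells with zero counts", int((totals == 0).sum()))
        adata = adata[totals > 0].copy()
        counts = np.asarray(adata.layers["spliced"], dtype=float)
        totals = counts.sum(axis=1)
    scaled = counts / totals[:, None] * np.median(totals)
    logn = np.log1p(scaled)
    adata.X = logn.astype(np.float32)
    variances = logn.var(axis=0)
    top = np.sort(np.argsort(variances)[::-1][: min(n_top_genes, logn.shape[1])])
    adata.var["highly_variable"] = np.isin(np.arange(adata.n_vars), top)
    n_pcs = min(n_pcs, len(top) - 1, adata.n_obs - 1)
    pca = PCA(n_components=n_pcs, random_state=seed)
    coords = pca.fit_transform(logn[:, top])
    if batch_center and "batch" in adata.obs:
        for b in adata.obs["batch"].unique():
            mask = (adata.obs["batch"] == b).to_numpy()
            coords[mask] -= coords[mask].mean(axis=0)
    adata.obsm["X_pca"] = coords
    adata.uns["pca_variance_ratio"] = pca.explained_variance_ratio_
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    adata.obsm["knn_indices"] = idx[:, 1:]
    adata.obsm["X_embed"] = coords[:, :2]  # default 2-D embedding
    return adata


def _knn_graph(adata: ad.AnnData) -> igraph.Graph:
    idx = adata.obsm["knn_indices"]
    n, k = idx.shape
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i]}
    return igraph.Graph(n=n, edges=list(edges), directed=False)


def cluster_cells(
    adata: ad.AnnData, resolution: float = 1.0, seed: int = 0
) -> pd.Series:
    """Louvain community detection on the kNN graph."""
    if "knn_indices" not in adata.obsm:
        raise ValueError("run preprocess first: kNN graph missing")
    graph = _knn_graph(adata)
    if graph.ecount() == 0:
        raise ValueError("empty kNN graph")
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)  # igraph's multilevel uses Python's RNG
        communities = graph.community_multilevel(resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    labels = pd.Series(
        pd.Categorical(np.asarray(communities.membership).astype(str)),
        index=adata.obs_names,
        name="cluster",
    )
    return labels


def scan_resolutions(
    adata: ad.AnnData,
    truth: pd.Series,
    resolutions=(0.4, 0.6, 0.8, 1.0, 1.2, 1.5),
    seed: int = 0,
) -> dict:
    """Cluster at several resolutions and keep the labels maximizing ARI
    against a ground-truth annotation."""
    best = None
    for r in resolutions:
        labels = cluster_cells(adata, resolution=r, seed=seed)
        ari = adjusted_rand_score(truth.to_numpy(), labels.to_numpy())
        if best is None or ari > best["ari"]:
            best = {"resolution": r, "ari": ari, "labels": labels}
    return best


def map_clusters_to_truth(labels: pd.Series, truth: pd.Series) -> pd.Series:
    """Majority-vote mapping of each cluster to a ground-truth population."""
    mapping = {}
    for c in labels.unique():
        mapping[c] = truth[labels == c].value_counts().idxmax()
    return labels.map(mapping).rename("mapped")


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def cluster_markers_ttest(
    adata: ad.AnnData, labels: pd.Series, top_n: int = 10
) -> pd.DataFrame:
    """Welch t-test of each gene, cluster vs all other cells; top_n by t.

    q-values are BH-adjusted across genes within each cluster. Genes flat
    in both groups are skipped.
    """
    x = np.asarray(adata.X, dtype=float)
    out = []
    for c in labels.unique():
        mask = (labels == c).to_numpy()
        if mask.sum() < 3:
            raise ValueError(f"cluster {c} has fewer than 3 cells")
        a, b = x[mask], x[~mask]
        flat = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
        t, p = stats.ttest_ind(a[:, ~flat], b[:, ~flat], axis=0, equal_var=False)
        q = bh_adjust(p)
        table = pd.DataFrame(
            {
                "cluster": c,
                "gene": np.asarray(adata.var_names)[~flat],
                "t": t,
                "p": p,
                "q": q,
            }
        ).sort_values("t", ascending=False, kind="mergesort")
        table["rank"] = np.arange(1, len(table) + 1)
        out.append(table.head(top_n))
    return pd.concat(out, ignore_index=True)


def marker_sets(markers: pd.DataFrame) -> dict[str, list[str]]:
    """Per-cluster marker gene lists from a cluster_markers_ttest table."""
    return {
        str(c): list(sub.sort_values("rank")["gene"])
        for c, sub in markers.groupby("cluster", observed=True)
    }


# ---------------------------------------------------------------------------
# Cell typing and states
# ---------------------------------------------------------------------------

def _gene_z(adata: ad.AnnData, gene: str, cells: np.ndarray | None = None):
    if gene not in adata.var_names:
        raise ValueError(f"marker gene {gene} missing from the data")
    x = np.asarray(adata[:, gene].X, dtype=float).ravel()
    if cells is not None:
        x = x[cells]
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


@dataclass
class CellTypeRules:
    """Marker-score thresholds for the rule-based cell typer."""

    endothelial_gene: str = "Emcn"
    macrophage_gene: str = "Lyz2"
    fibroblast_genes: tuple[str, str] = ("Acta2", "Col1a1")
    high_z: float = 1.0
    #: softer threshold for double-positive flags: a Lyz2+ fibroblast is a
    #: cell that stayed below the macrophage cutoff but is clearly above
    #: the fibroblast background (and symmetrically for Acta2+ macrophages)
    flag_z: float = 0.5


def classify_celltypes(
    adata: ad.AnnData, rules: CellTypeRules | None = None
) -> pd.DataFrame:
    """Rule-based typing: Emcn-high -> endothelial; else Lyz2-high ->
    macrophage; else fibroblast. Double positives are flags, not labels."""
    rules = rules or CellTypeRules()
    z_ec = _gene_z(adata, rules.endothelial_gene)
    z_mp = _gene_z(adata, rules.macrophage_gene)
    z_fb = np.mean([_gene_z(adata, g) for g in rules.fibroblast_genes], axis=0)
    label = np.where(
        z_ec > rules.high_z,
        "endothelial",
        np.where(z_mp > rules.high_z, "macrophage", "fibroblast"),
    )
    z_acta2 = _gene_z(adata, rules.fibroblast_genes[0])
    return pd.DataFrame(
        {
            "celltype": label,
            "acta2_positive": (label == "macrophage") & (z_acta2 > rules.flag_z),
            "lyz2_positive": (label == "fibroblast") & (z_mp > rules.flag_z),
            "score_endothelial": z_ec,
            "score_macrophage": z_mp,
            "score_fibroblast": z_fb,
        },
        index=adata.obs_names,
    )


def classify_fb_state(
    adata: ad.AnnData,
    fb_mask,
    matrix_genes: list[str] | None = None,
    contractile_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Matrix-producing vs contractile fibroblast states.

    Scores are mean z-scored expression (within fibroblasts) of the
    Col1a1 set vs the Acta2/Tpm2 set; the larger wins, ties break to
    contractile.
    """
    fb_mask = np.asarray(fb_mask, dtype=bool)
    if fb_mask.sum() == 0:
        raise ValueError("no fibroblasts to classify")
    matrix_genes = matrix_genes or list(MATRIX_STATE_GENES)
    contractile_genes = contractile_genes or ["Acta2", "Tpm2"]
    z_mat = np.mean([_gene_z(adata, g, fb_mask) for g in matrix_genes], axis=0)
    z_con = np.mean([_gene_z(adata, g, fb_mask) for g in contractile_genes], axis=0)
    state = np.where(z_mat > z_con, "matrix_producing", "contractile")
    out = pd.DataFrame(
        {"state": state, "score_matrix": z_mat, "score_contractile": z_con},
        index=adata.obs_names[fb_mask],
    )
    out.attrs["fractions"] = (
        out["state"].value_counts(normalize=True)
        .reindex(["matrix_producing", "contractile"], fill_value=0.0)
        .to_dict()
    )
    return out


def cellcycle_phase(
    adata: ad.AnnData,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell phase: argmax of mean z-scored S and G2M set scores if
    positive, else G1."""
    s_genes = [g for g in (s_genes or S_PHASE_GENES) if g in adata.var_names]
    g2m_genes = [g for g in (g2m_genes or G2M_GENES) if g in adata.var_names]
    if not s_genes or not g2m_genes:
        raise ValueError("cell-cycle gene sets must be nonempty and present")
    s_score = np.mean([_gene_z(adata, g) for g in s_genes], axis=0)
    g2m_score = np.mean([_gene_z(adata, g) for g in g2m_genes], axis=0)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(g2m_score > s_score, "G2M", "S"),
    )
    return pd.DataFrame(
        {"phase": phase, "S_score": s_score, "G2M_score": g2m_score},
        index=adata.obs_names,
    )


def proliferation_score(
    adata: ad.AnnData,
    labels: pd.Series | None = None,
    genes: list[str] | None = None,
) -> dict:
    """Equal-weight proliferation score over the 17-gene default set.

    The score is the unweighted mean of per-gene z-scored expression; a
    cell is "proliferating" when its score exceeds 0. When cluster labels
    are given, the per-cluster proliferating fraction is reported too.
    """
    genes = list(genes or PROLIFERATION_GENES)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"proliferation genes missing: {missing}")
    score = np.mean([_gene_z(adata, g) for g in genes], axis=0)
    per_cell = pd.Series(score, index=adata.obs_names, name="proliferation")
    result = {"score": per_cell, "proliferating": per_cell > 0}
    if labels is not None:
        result["cluster_fraction"] = (
            (per_cell > 0).groupby(labels, observed=True).mean().sort_index()
        )
    return result


def population_fractions(labels: pd.Series) -> pd.Series:
    """Label fractions, reported at 0.1% precision, summing to exactly 1."""
    if len(labels) == 0:
        raise ValueError("no labels")
    frac = labels.value_counts(normalize=True).sort_index()
    rounded = (frac * 1000).round() / 1000
    # push any rounding remainder onto the largest class
    gap = 1.0 - rounded.sum()
    if abs(gap) > 1e-12:
        rounded[rounded.idxmax()] += gap
    return rounded
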