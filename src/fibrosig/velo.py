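"""Steady-state RNA velocity.

The deterministic first-moment model: after kNN smoothing of the
normalized spliced (s) and unspliced (u) layers, each gene's
degradation/splicing ratio gamma is fit by regression through the origin
on the cells in the extreme quantiles of s, and the per-cell velocity is
v = u - gamma * s. Genes being induced have unspliced counts above the
steady-state line (v > 0). A velocity graph of cosine similarities
between velocities and neighbor displacements is projected onto the 2-D
embedding as per-cell arrows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd


@dataclass
class VelocityModel:
    """Per-gene steady-state ratio estimates."""

    gamma: pd.Series  # per fitted gene
    fitted: pd.Series  # bool per gene
    quantile: float
    residual_sd: pd.Series = field(default_factory=pd.Series)


@dataclass
class VelocityField:
    """Per-cell velocity vectors and their graph/embedding projections."""

    velocity: pd.DataFrame  # cells x fitted genes
    genes: list[str]
    cosines: np.ndarray | None = None  # cells x k, aligned with knn_indices
    arrows: pd.DataFrame | None = None  # cells x 2


def _normalized_layers(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    """Scale both layers by the spliced-count cell totals (preserving the
    per-gene u/s ratio)."""
    s = np.asarray(adata.layers["spliced"], dtype=float)
    u = np.asarray(adata.layers["unspliced"], dtype=float)
    totals = s.sum(axis=1)
    totals[totals == 0] = 1.0
    factor = np.median(s.sum(axis=1)) / totals
    return s * factor[:, None], u * factor[:, None]


def smooth_layers(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    """First-order kNN averaging (including self) of normalized u and s."""
    if "knn_indices" not in adata.obsm:
        raise ValueError("run scpop.preprocess first: kNN graph missing")
    s, u = _normalized_layers(adata)
    idx = adata.obsm["knn_indices"]
    n = adata.n_obs
    rows = np.repeat(np.arange(n), idx.shape[1] + 1)
    cols = np.concatenate([np.arange(n)[:, None], idx], axis=1).ravel()
    ms = np.zeros_like(s)
    mu = np.zeros_like(u)
    np.add.at(ms, rows, s[cols])
    np.add.at(mu, rows, u[cols])
    ms /= idx.shape[1] + 1
    mu /= idx.shape[1] + 1
    adata.layers["Ms"] = ms
    adata.layers["Mu"] = mu
    return ms, mu


def fit_gamma(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    gene_names,
    q: float = 0.05,
    min_extreme: int = 4,
) -> VelocityModel:
    """Per-gene gamma = sum(u*s) / sum(s^2) over the extreme-s cells.

    The extreme set is the union of cells in the bottom and top q-quantiles
    of s (ties included, so a constant positive gene uses every cell and
    gamma reduces to mean(u)/s). Genes with all-zero s are flagged unfitted.
    """
    s = np.asarray(spliced, dtype=float)
    u = np.asarray(unspliced, dtype=float)
    n_genes = s.shape[1]
    gamma = np.full(n_genes, np.nan)
    fitted = np.zeros(n_genes, dtype=bool)
    resid = np.full(n_genes, np.nan)
    lo = np.quantile(s, q, axis=0)
    hi = np.quantile(s, 1 - q, axis=0)
    for j in range(n_genes):
        if not s[:, j].any():
            continue
        extreme = (s[:, j] <= lo[j]) | (s[:, j] >= hi[j])
        if extreme.sum() < min_extreme:
            extreme = np.ones(s.shape[0], dtype=bool)
        ss = s[extreme, j]
        denom = (ss**2).sum()
        if denom == 0:
            continue
        gamma[j] = (u[extreme, j] * ss).sum() / denom
        fitted[j] = True
        resid[j] = (u[:, j] - gamma[j] * s[:, j]).std()
    names = pd.Index(gene_names)
    return VelocityModel(
        gamma=pd.Series(gamma, index=names),
        fitted=pd.Series(fitted, index=names),
        quantile=q,
        residual_sd=pd.Series(resid, index=names),
    )


def compute_velocity(
    model: VelocityModel,
    spliced: np.ndarray,
    unspliced: np.ndarray,
    cell_names=None,
) -> VelocityField:
    """v = u - gamma * s elementwise over fitted genes."""
    keep = model.fitted.to_numpy()
    if not keep.any():
        raise ValueError("no fitted genes")
    s = np.asarray(spliced, dtype=float)[:, keep]
    u = np.asarray(unspliced, dtype=float)[:, keep]
    genes = list(model.gamma.index[keep])
    v = u - model.gamma.to_numpy()[keep][None, :] * s
    index = cell_names if cell_names is not None else pd.RangeIndex(len(v))
    return VelocityField(
        velocity=pd.DataFrame(v, index=index, columns=genes), genes=genes
    )


def velocity_graph(
    field: VelocityField, expression: np.ndarray, knn_indices: np.ndarray
) -> np.ndarray:
    """Cosine similarity between v_i and the log1p-expression displacement
    toward each kNN neighbor; zero-velocity cells get 0."""
    x = np.log1p(np.asarray(expression, dtype=float))
    v = field.velocity.to_numpy()
    n, k = knn_indices.shape
    cos = np.zeros((n, k))
    vnorm = np.linalg.norm(v, axis=1)
    for i in range(n):
        if vnorm[i] == 0:
            continue
        delta = x[knn_indices[i]] - x[i]
        dnorm = np.linalg.norm(delta, axis=1)
        ok = dnorm > 0
        cos[i, ok] = delta[ok] @ v[i] / (dnorm[ok] * vnorm[i])
    field.cosines = cos
    return cos


def embed_velocity(
    field: VelocityField,
    embedding: np.ndarray,
    knn_indices: np.ndarray,
    kernel_sigma: float = 0.1,
    cell_names=None,
) -> pd.DataFrame:
    """Project the velocity graph onto a 2-D embedding as arrows.

    Transition weights pi_ij = softmax over neighbors of c_ij / sigma;
    arrow_i = sum_j (pi_ij - 1/|N_i|) * (e_j - e_i), so a uniform cosine
    profile yields a zero arrow. Isolated cells (or cells with zero
    velocity) get a zero arrow with a flag.
    """
    if field.cosines is None:
        raise ValueError("run velocity_graph first")
    emb = np.asarray(embedding, dtype=float)
    n, k = knn_indices.shape
    arrows = np.zeros((n, 2))
    flagged = np.zeros(n, dtype=bool)
    vnorm = np.linalg.norm(field.velocity.to_numpy(), axis=1)
    for i in range(n):
        if vnorm[i] == 0 or k == 0:
            flagged[i] = True
            continue
        c = field.cosines[i]
        w = np.exp((c - c.max()) / kernel_sigma)
        w /= w.sum()
        delta = emb[knn_indices[i]] - emb[i]
        arrows[i] = (w - 1.0 / k) @ delta
    index = cell_names if cell_names is not None else pd.RangeIndex(n)
    out = pd.DataFrame(arrows, index=index, columns=["dx", "dy"])
    out["isolated"] = flagged
    field.arrows = out
    return out


def run_velocity_pipeline(
    adata: ad.AnnData, q: float = 0.05, kernel_sigma: float = 0.1
) -> tuple[VelocityModel, VelocityField]:
    """Smooth, fit gamma, compute velocities, graph and embedded arrows."""
    ms, mu = smooth_layers(adata)
    model = fit_gamma(ms, mu, adata.var_names, q=q)
    field = compute_velocity(model, ms, mu, cell_names=adata.obs_names)
    keep = model.fitted.to_numpy()
    velocity_graph(field, ms[:, keep], adata.obsm["knn_indices"])
    embed_velocity(
        field,
        adata.obsm["X_embed"],
        adata.obsm["knn_indices"],
        kernel_sigma=kernel_sigma,
        cell_names=adata.obs_names,
    )
    return model, field
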