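"""Projection-score selection of an informative gene subset.

The projection score of a gene subset quantifies how much "non-random"
structure its leading principal components capture: the variance fraction
retained by the top d components of the standardized subset, minus the
expectation of the same quantity over random subsets of equal size. A
variance-filter threshold scan then keeps the subset whose score is
maximal, replacing an eyeballed choice of variance cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import variance_filter

log = logging.getLogger(__name__)


@dataclass
class ProjectionScoreConfig:
    d: int = 2
    B: int = 100
    thresholds: list[float] = field(
        default_factory=lambda: [round(0.50 + 0.05 * i, 2) for i in range(10)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.B < 10:
            raise ValueError("B must be >= 10 for a stable null estimate")


@dataclass
class ProjectionScoreResult:
    trace: pd.DataFrame  # per threshold: size, alpha, alpha_random, tau, null_sd
    best_threshold: float
    best_subset: list[str]
    informative: bool  # False when the best tau is within Monte-Carlo noise


def _standardize(matrix: np.ndarray) -> np.ndarray:
    mu = matrix.mean(axis=0, keepdims=True)
    sd = matrix.std(axis=0, ddof=1, keepdims=True)
    return (matrix - mu) / sd


def alpha_score(matrix: pd.DataFrame, subset: list[str], d: int = 2) -> float:
    """Variance fraction (square-rooted) captured by the top d PCs.

    ``matrix`` is samples x genes. The subset columns are z-scored, and
    alpha = sqrt(sum of the top min(d, |S|) eigenvalues / total) of the
    resulting covariance. alpha = 1 when d >= |S| or the subset is rank-d.
    """
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    sub = matrix.loc[:, list(subset)].to_numpy(dtype=float)
    sd = sub.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(subset, sd) if s == 0]
        raise ValueError(f"zero-variance genes in subset: {bad}")
    z = _standardize(sub)
    sv = np.linalg.svd(z, compute_uv=False)
    lam = sv**2
    top = min(d, len(subset))
    return float(np.sqrt(lam[:top].sum() / lam.sum()))


def projection_score(
    matrix: pd.DataFrame,
    subset: list[str],
    d: int = 2,
    B: int = 100,
    seed: int = 0,
    return_se: bool = False,
):
    """tau = alpha(subset) - mean alpha over B random equal-size subsets.

    Random subsets are drawn uniformly from the full gene universe of the
    matrix (with the observed subset size), matching the null of the
    projection-score method.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)
    genes = list(matrix.columns)
    size = len(subset)
    obs = alpha_score(matrix, subset, d)
    if size >= len(genes):
        null = np.full(B, obs)  # every size-|S| subset is the full set
    else:
        null = np.empty(B)
        for b in range(B):
            draw = rng.choice(len(genes), size=size, replace=False)
            null[b] = alpha_score(matrix, [genes[i] for i in draw], d)
    tau = obs - null.mean()
    if return_se:
        # the noise scale of tau is the null spread itself (alpha of one
        # subset is a single draw from the null), not the s.e. of its mean
        return tau, obs, float(null.mean()), float(null.std(ddof=1))
    return tau


def select_optimal_subset(
    matrix: pd.DataFrame, config: ProjectionScoreConfig
) -> ProjectionScoreResult:
    """Scan variance-filter thresholds and keep the max-tau subset.

    Ties prefer the larger subset, then the lower threshold. The result is
    flagged uninformative when the best tau is below twice its Monte-Carlo
    standard error.
    """
    if not config.thresholds:
        raise ValueError("thresholds must be nonempty")
    rows, subsets = [], {}
    for i, t in enumerate(config.thresholds):
        subset = variance_filter(matrix.T, t)
        if not subset:  # pragma: no cover - defensive; filter returns >= 1
            log.info("threshold %.2f yields an empty subset; skipped", t)
            continue
        tau, obs, null_mean, null_sd = projection_score(
            matrix, subset, config.d, config.B, seed=config.seed + i, return_se=True
        )
        subsets[t] = subset
        rows.append(
            {
                "threshold": t,
                "size": len(subset),
                "alpha": obs,
                "alpha_random": null_mean,
                "tau": tau,
                "null_sd": null_sd,
            }
        )
    if not rows:
        raise ValueError("all thresholds yielded empty subsets")
    trace = pd.DataFrame(rows)
    best = trace.sort_values(
        ["tau", "size", "threshold"],
        ascending=[False, False, True],
        kind="mergesort",
    ).iloc[0]
    best_t = float(best["threshold"])
    trace = trace.set_index("threshold")
    informative = bool(best["tau"] >= 2 * best["null_sd"])
    if not informative:
        log.info("no informative subset: best tau %.4f within MC noise", best["tau"])
    return ProjectionScoreResult(
        trace=trace,
        best_threshold=best_t,
        best_subset=subsets[best_t],
        informative=informative,
    )
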