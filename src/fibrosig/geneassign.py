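"""Assign panel genes to cell-type categories from a reference matrix.

The reference is a mean-expression table (genes x reference cell types)
derived from a cardiac single-nucleus atlas; reference cell types are
pooled into three groups (cardiomyocyte; fibroblast + pericyte; everything
else) and each gene is categorized by which groups dominate its
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ["cardiomyocyte", "fibroblast_pericyte", "both", "other"]

#: Default pooling of reference cell types into assignment groups.
DEFAULT_GROUP_MAP: dict[str, str] = {
    "cardiomyocyte": "cardiomyocyte",
    "fibroblast": "fibroblast_pericyte",
    "pericyte": "fibroblast_pericyte",
    "endothelial": "other",
    "macrophage": "other",
    "lymphocyte": "other",
}


@dataclass
class CellTypeReference:
    """Mean expression per reference cell type, plus the pooling map."""

    means: pd.DataFrame  # genes x cell types, nonnegative
    group_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))

    def __post_init__(self) -> None:
        if (self.means.to_numpy() < 0).any():
            raise ValueError("reference means must be nonnegative")
        unknown = set(self.means.columns) - set(self.group_map)
        if unknown:
            raise ValueError(f"cell types without a group assignment: {sorted(unknown)}")

    def group_means(self) -> pd.DataFrame:
        """genes x {CM, FB+pericyte, other} pooled means."""
        groups = pd.Series(
            [self.group_map[c] for c in self.means.columns], index=self.means.columns
        )
        pooled = self.means.T.groupby(groups).mean().T
        for g in ("cardiomyocyte", "fibroblast_pericyte", "other"):
            if g not in pooled.columns:
                pooled[g] = 0.0
        return pooled[["cardiomyocyte", "fibroblast_pericyte", "other"]]


@dataclass
class GeneAssignment:
    category: pd.Series  # gene -> category
    fractions: pd.DataFrame  # per-gene specificity fractions (rows sum to 1)
    flagged_zero: list[str] = field(default_factory=list)


def assign_gene_categories(
    ref: CellTypeReference,
    genes: list[str] | None = None,
    theta_dom: float = 0.5,
    theta_both: float = 0.3,
) -> GeneAssignment:
    """Categorize genes by their pooled-group specificity fractions.

    s_c = group mean / sum of group means. A gene is cardiomyocyte if
    s_CM >= theta_dom and s_FB < theta_both (symmetric for fibroblast/
    pericyte), "both" if both fractions reach theta_both, else "other".
    All-zero genes fall to "other" with a flag.
    """
    if theta_both > theta_dom:
        raise ValueError("theta_both must not exceed theta_dom")
    pooled = ref.group_means()
    if genes is not None:
        missing = [g for g in genes if g not in pooled.index]
        if missing:
            raise ValueError(f"genes missing from the reference: {missing}")
        pooled = pooled.loc[list(genes)]
    total = pooled.sum(axis=1)
    zero = total == 0
    fractions = pooled.div(total.replace(0, 1.0), axis=0)
    s_cm = fractions["cardiomyocyte"].to_numpy()
    s_fb = fractions["fibroblast_pericyte"].to_numpy()
    category = np.select(
        [
            (s_cm >= theta_dom) & (s_fb < theta_both),
            (s_fb >= theta_dom) & (s_cm < theta_both),
            (s_cm >= theta_both) & (s_fb >= theta_both),
        ],
        ["cardiomyocyte", "fibroblast_pericyte", "both"],
        default="other",
    )
    category = pd.Series(category, index=pooled.index, name="category")
    category[zero] = "other"
    return GeneAssignment(
        category=category,
        fractions=fractions,
        flagged_zero=list(pooled.index[zero]),
    )


def category_counts(assign: GeneAssignment) -> pd.Series:
    """Number of genes per category (all four categories always present)."""
    counts = assign.category.value_counts()
    return counts.reindex(CATEGORIES, fill_value=0).astype(int)
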