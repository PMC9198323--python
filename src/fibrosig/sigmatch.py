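"""Cross-dataset signature matching by Pearson correlation.

A signature profile is the per-group mean expression of an ordered gene
set, z-scored per gene across groups (expression relative to the gene's
mean over groups). The heart-failure patient profile is matched against
fibroblast-subpopulation profiles from the cultured cells; gene symbols
are translated between species with the bundled map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genes import map_symbols


@dataclass
class SignatureProfile:
    """Per-group z-scored mean expression over an ordered gene set."""

    zmatrix: pd.DataFrame  # genes x groups
    species: str = "human"
    constant_genes: tuple[str, ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(self.zmatrix.index)

    @property
    def groups(self) -> list[str]:
        return list(self.zmatrix.columns)


def group_profile(
    expression: pd.DataFrame,
    gene_set: list[str],
    group_labels: pd.Series,
    species: str = "human",
) -> SignatureProfile:
    """Build a signature profile from expression (genes x samples).

    Per gene: group means, then a z-score across groups with the
    population (n) denominator. Genes constant across groups are kept in
    the matrix (as zeros) but flagged so correlations can exclude them.
    """
    missing = [g for g in gene_set if g not in expression.index]
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing}")
    groups = list(pd.unique(group_labels))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to z-score a profile")
    sub = expression.loc[list(gene_set)]
    means = sub.T.groupby(group_labels, observed=True).mean().T[groups]
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    constant = tuple(means.index[sd == 0])
    z = means.sub(mu, axis=0).div(sd.replace(0, 1.0), axis=0)
    return SignatureProfile(zmatrix=z, species=species, constant_genes=constant)


def match_signature(
    profile_a: SignatureProfile,
    profiles_b: SignatureProfile,
    target_group,
) -> pd.DataFrame:
    """Pearson r between one group of profile_a and every group of profiles_b.

    Gene sets are aligned after translating profile_a's symbols into
    profiles_b's species. Genes constant in either profile are dropped;
    fewer than 3 usable genes is an error. Returns a per-subpopulation
    table with r, p, a positivity flag and the argmax marker.
    """
    genes_a = profile_a.genes
    if profile_a.species != profiles_b.species:
        mapped = map_symbols(genes_a, to=profiles_b.species)
    else:
        mapped = list(genes_a)
    missing = [m for m in mapped if m not in profiles_b.zmatrix.index]
    if missing:
        raise ValueError(f"genes absent from the compared profile: {missing}")
    drop = set(profile_a.constant_genes) | {
        a for a, m in zip(genes_a, mapped) if m in profiles_b.constant_genes
    }
    keep_a = [g for g in genes_a if g not in drop]
    keep_b = [m for a, m in zip(genes_a, mapped) if a not in drop]
    if len(keep_a) < 3:
        raise ValueError("fewer than 3 non-constant shared genes")
    x = profile_a.zmatrix.loc[keep_a, target_group].to_numpy(dtype=float)
    rows = []
    for group in profiles_b.groups:
        y = profiles_b.zmatrix.loc[keep_b, group].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        rows.append({"subpopulation": group, "r": r, "p": p, "positive": r > 0})
    out = pd.DataFrame(rows).set_index("subpopulation")
    out["best_match"] = out.index == out["r"].idxmax()
    return out
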