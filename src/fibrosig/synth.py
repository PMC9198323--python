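"""Synthetic data generators with ground truth.

Four generators emulate the statistical structure of the study's inputs:

* a Nanostring-like patient cohort (10 donors, 65 heart-failure patients,
  82 panel genes, 5 invariant reference genes, two HF subclusters driven
  by a 12-gene block with ACE2 moving opposite to the rest);
* a cultured cardiac-cell scRNA-seq experiment (~8000 cells; endothelial
  cells, two macrophage subsets and six fibroblast subpopulations along a
  branched activation trajectory, with spliced/unspliced two-state
  kinetics so that unspliced counts lead spliced counts during induction);
* a cell-type reference table whose mean-expression patterns round-trip
  exactly through the default gene-assignment rule at zero noise;
* a bulk infarct time course built as stage-dependent convex mixtures of
  the subpopulation expression signatures plus stage-constant background.

Counts are negative binomial around log-normal baselines; a single RNG
stream per generator call is seeded from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from . import genes as G

# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer allocation of n items; ties broken by name order."""
    names = list(fractions)
    raw = {k: n * fractions[k] for k in names}
    counts = {k: int(np.floor(raw[k])) for k in names}
    short = n - sum(counts.values())
    order = sorted(names, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for the synthetic heart-failure panel cohort."""

    n_donors: int = 10
    n_patients: int = 65
    n_panel_genes: int = 82
    ref_gene_names: list[str] = field(default_factory=lambda: list(G.REFERENCE_GENES))
    informative_gene_names: list[str] = field(
        default_factory=lambda: list(G.SIGNATURE_GENES_HUMAN)
    )
    hf_log2fc: float = 1.0
    cluster2_log2fc: float = 1.5
    cluster2_fraction: float = 0.45
    n_effect_filler: int = 28  # extra fibrosis-effect genes beyond the signature
    age_range: tuple[float, float] = (18.0, 85.0)
    dispersion: float = 0.1
    seed: int = 0

    def panel_genes(self) -> list[str]:
        n_filler = self.n_panel_genes - len(self.informative_gene_names) - len(
            self.ref_gene_names
        )
        if n_filler < 0:
            raise ValueError("n_panel_genes too small for signature + reference genes")
        filler = [f"FIBG{i:02d}" for i in range(1, n_filler + 1)]
        return list(self.informative_gene_names) + list(self.ref_gene_names) + filler

    def effect_genes(self) -> list[str]:
        """Fibrosis genes elevated in HF (signature minus ACE2, plus filler)."""
        sig = [g for g in self.informative_gene_names if g != "ACE2"]
        return sig + [f"FIBG{i:02d}" for i in range(1, self.n_effect_filler + 1)]

    def validate(self) -> None:
        if self.n_donors <= 0 or self.n_patients <= 0:
            raise ValueError("sample counts must be positive")
        if not 0 < self.cluster2_fraction < 1:
            raise ValueError("cluster2_fraction must lie in (0, 1)")
        panel = set(self.panel_genes())
        if not set(self.informative_gene_names) <= panel:
            raise ValueError("informative genes must be part of the panel")
        if set(self.ref_gene_names) & set(self.effect_genes()):
            raise ValueError("reference genes must carry no group effect")


def generate_patient_cohort(config: CohortConfig):
    """Simulate panel counts and clinical metadata; see :class:`CohortConfig`.

    Reference genes carry no group effect; HF samples carry ``hf_log2fc``
    on the fibrosis-effect genes; a ``cluster2_fraction`` subset of HF
    samples additionally carries ``cluster2_log2fc`` on the informative
    genes, with the ACE2 direction reversed.
    """
    from .panel import PanelCohort

    config.validate()
    rng = np.random.default_rng(config.seed)
    panel_genes = config.panel_genes()
    effect = set(config.effect_genes())
    informative = list(config.informative_gene_names)

    samples = [f"D{i + 1:02d}" for i in range(config.n_donors)] + [
        f"HF{i + 1:02d}" for i in range(config.n_patients)
    ]
    group = np.array(["donor"] * config.n_donors + ["HF"] * config.n_patients)

    # Two HF subclusters; cluster 2 is the severe-fibrosis subcluster.
    n_c2 = int(round(config.cluster2_fraction * config.n_patients))
    subcluster = np.zeros(len(samples), dtype=int)
    hf_idx = np.where(group == "HF")[0]
    c2 = rng.choice(hf_idx, size=n_c2, replace=False)
    subcluster[hf_idx] = 1
    subcluster[c2] = 2

    lo, hi = config.age_range
    age = np.where(
        group == "donor", rng.normal(43.0, 13.0, len(samples)),
        rng.normal(52.0, 14.0, len(samples)),
    ).clip(max(lo, 18.0), hi)

    def _flag(p_donor, p_c1, p_c2):
        p = np.where(subcluster == 2, p_c2, np.where(subcluster == 1, p_c1, p_donor))
        return rng.random(len(samples)) < p

    metadata = pd.DataFrame(
        {
            "group": group,
            "age": np.round(age, 1),
            "ischemic": _flag(0.0, 0.46, 0.84),
            "diabetes": _flag(0.10, 0.30, 0.50),
            "high_bmi": _flag(0.30, 0.35, 0.55),
            "female": _flag(0.60, 0.30, 0.45),
            "true_subcluster": subcluster,
        },
        index=pd.Index(samples, name="sample"),
    )

    base = pd.Series(
        rng.lognormal(np.log(300.0), 0.8, len(panel_genes)), index=panel_genes
    )
    base[config.ref_gene_names] = rng.lognormal(
        np.log(1500.0), 0.3, len(config.ref_gene_names)
    )
    # A few filler genes drift linearly with age (log2 per year).
    age_slope = pd.Series(0.0, index=panel_genes)
    aged = [g for g in panel_genes if g.startswith("FIBG")][-10:]
    age_slope[aged] = np.where(np.arange(len(aged)) % 2 == 0, 0.02, -0.02)

    log2fc = np.zeros((len(panel_genes), len(samples)))
    gene_pos = {g: i for i, g in enumerate(panel_genes)}
    is_hf = group == "HF"
    for g in effect:
        log2fc[gene_pos[g], is_hf] += config.hf_log2fc
    in_c2 = subcluster == 2
    for g in informative:
        sign = -1.0 if g == "ACE2" else 1.0
        log2fc[gene_pos[g], in_c2] += sign * config.cluster2_log2fc

    lib = rng.lognormal(0.0, 0.10, len(samples))
    mean_age = age.mean()
    mu = (
        base.to_numpy()[:, None]
        * 2.0 ** (log2fc + np.outer(age_slope.to_numpy(), age - mean_age))
        * lib[None, :]
    )
    counts = _nb_counts(rng, mu, config.dispersion)
    counts = pd.DataFrame(counts, index=pd.Index(panel_genes, name="gene"),
                          columns=samples)
    return PanelCohort(counts=counts, metadata=metadata)


# ---------------------------------------------------------------------------
# Cell-type reference
# ---------------------------------------------------------------------------


@dataclass
class ReferenceConfig:
    celltypes: list[str] = field(
        default_factory=lambda: [
            "cardiomyocyte", "fibroblast", "pericyte",
            "endothelial", "macrophage", "lymphocyte",
        ]
    )
    noise_sd: float = 0.0  # log-normal sd on each entry
    seed: int = 0


#: Group-mean patterns guaranteeing exact recovery by the default rule
#: (theta_dom = 0.5, theta_both = 0.3) in the noiseless case.
_CATEGORY_PATTERNS = {
    "cardiomyocyte": {"cardiomyocyte": 0.80, "fibroblast_pericyte": 0.05, "other": 0.15},
    "fibroblast_pericyte": {"cardiomyocyte": 0.05, "fibroblast_pericyte": 0.80, "other": 0.15},
    "both": {"cardiomyocyte": 0.42, "fibroblast_pericyte": 0.42, "other": 0.16},
    "other": {"cardiomyocyte": 0.10, "fibroblast_pericyte": 0.10, "other": 0.80},
}


def default_panel_partition(panel_genes: list[str] | None = None) -> dict[str, str]:
    """The study's category sizes (24 CM / 20 FB+pericyte / 15 both / 23 other)
    over the 82-gene panel, with the 12 signature genes fibroblast-specific."""
    genes = panel_genes or CohortConfig().panel_genes()
    signature = [g for g in genes if g in set(G.SIGNATURE_GENES_HUMAN)]
    refs = [g for g in genes if g in set(G.REFERENCE_GENES)]
    filler = [g for g in genes if g not in set(signature) | set(refs)]
    partition: dict[str, str] = {}
    for g in signature + filler[:8]:  # 20 fibroblast/pericyte genes
        partition[g] = "fibroblast_pericyte"
    for g in filler[8:32]:  # 24 cardiomyocyte genes
        partition[g] = "cardiomyocyte"
    for g in filler[32:47]:  # 15 genes in both groups
        partition[g] = "both"
    for g in refs + filler[47:]:  # 23 remaining genes
        partition[g] = "other"
    return partition


def generate_celltype_reference(
    partition: dict[str, str], config: ReferenceConfig | None = None
):
    """Construct a mean-expression reference realizing a category partition.

    At ``noise_sd = 0`` the default assignment rule recovers the partition
    exactly; positive noise multiplies each entry by a log-normal factor.
    """
    from .geneassign import DEFAULT_GROUP_MAP, CellTypeReference

    config = config or ReferenceConfig()
    bad = set(partition.values()) - set(_CATEGORY_PATTERNS)
    if bad:
        raise ValueError(f"unknown category labels: {sorted(bad)}")
    rng = np.random.default_rng(config.seed)
    group_map = {c: DEFAULT_GROUP_MAP.get(c, "other") for c in config.celltypes}
    rows = []
    for gene in partition:
        pattern = _CATEGORY_PATTERNS[partition[gene]]
        rows.append([pattern[group_map[c]] for c in config.celltypes])
    means = pd.DataFrame(
        rows, index=pd.Index(list(partition), name="gene"), columns=config.celltypes
    )
    if config.noise_sd > 0:
        means = means * rng.lognormal(0.0, config.noise_sd, means.shape)
    return CellTypeReference(means=means, group_map=group_map)


# ---------------------------------------------------------------------------
# Cultured-cell scRNA-seq
# ---------------------------------------------------------------------------

POPULATIONS = ["EC", "MP1", "MP2", "FB1", "FB2", "FB3", "FB4", "FB5", "FB6"]

#: Fibroblast shares within the fibroblast compartment (FB3 and FB5 largest).
_FB_SHARES = {"FB1": 0.13, "FB2": 0.15, "FB3": 0.257,
              "FB4": 0.12, "FB5": 0.223, "FB6": 0.12}

#: Pseudotime interval of each population on the branched lineage
#: FB2 -> {FB1, FB3, FB4}, FB3/FB4 -> FB5, FB5 -> FB6.
_PSEUDOTIME = {"FB2": (0.0, 1.0), "FB1": (1.0, 2.0), "FB3": (1.0, 2.0),
               "FB4": (1.0, 2.0), "FB5": (2.0, 3.0), "FB6": (3.0, 4.0)}

BRANCH_TOPOLOGY = [("FB2", "FB3"), ("FB2", "FB4"), ("FB3", "FB5"),
                   ("FB4", "FB5"), ("FB5", "FB6"), ("FB2", "FB1")]


def _default_fractions() -> dict[str, float]:
    fb_total = 1.0 - 0.0089 - 0.150 - 0.099
    fr = {"EC": 0.0089, "MP1": 0.150, "MP2": 0.099}
    fr.update({p: fb_total * s for p, s in _FB_SHARES.items()})
    return fr


@dataclass
class CultureConfig:
    """Study conditions for the cultured cardiac-cell experiment."""

    n_cells: int = 8000
    population_fractions: dict[str, float] = field(default_factory=_default_fractions)
    n_genes: int = 250
    marker_log2fc: float = 3.0
    doublet_rate: float = 0.01
    contractile_propensity: dict[str, float] = field(
        default_factory=lambda: {"FB1": 0.7, "FB2": 1.0}
    )
    state_log2fc: float = 4.0
    lag: float = 0.35  # pseudotime lag of spliced behind unspliced
    us_ratio: float = 0.25  # mean steady-state unspliced/spliced ratio (gamma/beta)
    lyz2_fb_rate: float = 0.02  # Lyz2+ fibroblasts
    acta2_mp_rate: float = 0.04  # Acta2+ macrophages
    n_batches: int = 3
    batch_sd: float = 0.05
    library_sd: float = 0.25
    dispersion: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.population_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"population fractions sum to {total}, not 1")
        if set(self.population_fractions) != set(POPULATIONS):
            raise ValueError("population_fractions must cover exactly "
                             f"{POPULATIONS}")


def _culture_gene_table(config: CultureConfig, rng: np.random.Generator):
    """Ordered gene list with baselines, kinetics and program parameters."""
    named: list[str] = []
    for block in (
        G.EC_MARKERS, G.MP_SHARED_MARKERS, G.MP1_MARKERS, G.MP2_MARKERS,
        G.CONTRACTILE_GENES, G.MATRIX_STATE_GENES, G.ECM_PROGRAM_GENES,
        G.RESTING_MARKERS, *G.FB_UNIQUE_MARKERS.values(),
        G.S_PHASE_GENES, G.G2M_GENES, G.PROLIFERATION_GENES,
        G.TGFB_GENES, G.OTHER_NAMED_GENES, G.SIGNATURE_GENES_MOUSE,
    ):
        for g in block:
            if g not in named:
                named.append(g)
    if config.n_genes < len(named):
        raise ValueError(f"n_genes must be >= {len(named)} to hold all markers")
    filler = [f"Gene{i:04d}" for i in range(1, config.n_genes - len(named) + 1)]
    genes = named + filler

    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["base"] = rng.lognormal(np.log(5.0), 0.8, len(genes))
    # Identity markers sit near zero outside their population so that the
    # z-threshold rules separate cleanly; endothelial markers are exclusive
    # (endomucin is not expressed by fibroblasts or macrophages at all).
    var.loc[G.EC_MARKERS, "base"] = 25.0
    var.loc[G.MP1_MARKERS + G.MP2_MARKERS, "base"] = 1.0
    var.loc[["Csf1r", "Adgre1", "Cd68"], "base"] = 1.0
    var.loc["Lyz2", "base"] = 1.5
    for markers in G.FB_UNIQUE_MARKERS.values():
        var.loc[markers, "base"] = 1.5
    var["us_ratio"] = config.us_ratio * rng.lognormal(0.0, 0.2, len(genes))
    var["program_onset"] = np.nan
    var["program_amp"] = 0.0
    var["program_width"] = np.nan

    # ECM activation program: induction onsets spread along the trajectory.
    # Activation remodels a broad transcriptional program, so a block of
    # unnamed genes is induced alongside the named ECM genes.
    program = list(G.ECM_PROGRAM_GENES) + [g for g in filler[:60]]
    onsets = rng.uniform(0.1, 3.4, len(program))
    amps = rng.uniform(1.5, 2.5, len(program))
    for g, o, a in zip(program, onsets, amps):
        var.loc[g, ["program_onset", "program_amp", "program_width"]] = (o, a, 0.3)
    # The 12-gene signature jumps late, along the FB5 -> FB6 segment;
    # Ace2 falls where the rest rise.
    for g in G.SIGNATURE_GENES_MOUSE:
        amp = -2.0 if g == "Ace2" else 2.0
        if g in ("Col1a1", "Col1a2"):
            amp = 1.2  # on top of the matrix-state boost
        var.loc[g, ["program_onset", "program_amp", "program_width"]] = (3.3, amp, 0.2)
    var.loc[G.SIGNATURE_GENES_MOUSE, "base"] = rng.lognormal(
        np.log(12.0), 0.3, len(G.SIGNATURE_GENES_MOUSE)
    )
    return var


def _population_boosts(config: CultureConfig) -> dict[str, dict[str, float]]:
    """Steady per-population log2 boosts (identical in both layers)."""
    m = config.marker_log2fc
    boosts: dict[str, dict[str, float]] = {p: {} for p in POPULATIONS}

    fb_like = (G.CONTRACTILE_GENES + G.MATRIX_STATE_GENES + G.ECM_PROGRAM_GENES
               + ["Vim", "S100a4", "Tgfb2", "Tgfb3"])
    for p in ("EC", "MP1", "MP2"):
        for g in fb_like:
            boosts[p][g] = -2.0
    for g in G.EC_MARKERS:
        for p in POPULATIONS:
            if p != "EC":
                boosts[p][g] = -30.0  # exclusive: zero outside endothelium
    for p in ("MP1", "MP2"):
        boosts[p]["Lyz2"] = 4.8
        for g in ("Csf1r", "Adgre1", "Cd68"):
            boosts[p][g] = 2.5
        boosts[p]["Tgfb1"] = 2.0
    for g in G.MP1_MARKERS:
        boosts["MP1"][g] = 3.0
    for g in G.MP2_MARKERS:
        boosts["MP2"][g] = 3.0

    for p, markers in G.FB_UNIQUE_MARKERS.items():
        for g in markers:
            boosts[p][g] = m
    for p in ("FB1", "FB2", "FB3", "FB4", "FB5", "FB6"):
        boosts[p]["Tgfb2"] = boosts[p].get("Tgfb2", 0.0) + 1.5
        boosts[p]["Tgfb3"] = boosts[p].get("Tgfb3", 0.0) + 1.5
    # FB4: proliferative, G2/M-dominated, inflammation-high.
    for g in G.G2M_GENES:
        boosts["FB4"][g] = max(boosts["FB4"].get(g, 0.0), 2.0)
    for g in ("Mki67", "Pcna", "Cdk4", "Cdk6", "Ccne1"):
        boosts["FB4"][g] = 1.5
    for g in G.S_PHASE_GENES:
        boosts["FB4"][g] = 0.5
    for g in ("Cd44", "Ccl2", "Efhd2"):
        boosts["FB4"][g] = 1.5
    # FB1 and FB3 are the least proliferative (FB1 keeps its Ccnd1/Ccnd2 peak).
    for p in ("FB1", "FB3"):
        for g in G.PROLIFERATION_GENES:
            if p == "FB1" and g in ("Ccnd1", "Ccnd2"):
                continue
            boosts[p][g] = boosts[p].get(g, 0.0) - 0.8
    # FB5/FB6 keep proliferating; the boost also has to survive the higher
    # library size of the strongly induced late populations
    for p in ("FB5", "FB6"):
        for g in G.PROLIFERATION_GENES:
            boosts[p][g] = boosts[p].get(g, 0.0) + 1.0
    # Late-activation / resolution markers high from FB4 on.
    for p in ("FB4", "FB5", "FB6"):
        for g in G.RESTING_MARKERS:
            boosts[p][g] = 1.5
    boosts["FB6"]["Acta2"] = -1.5  # contractile program shut down at the end point
    return boosts


def _activation_coordinate(pop: str, t: np.ndarray, lag: float):
    """Unspliced and spliced program coordinates for cells of one population."""
    if pop not in _PSEUDOTIME:
        zero = np.zeros_like(t)
        return zero, zero
    if pop == "FB1":  # resting side branch: the ECM program winds back down
        a_u = 1.0 - 0.6 * (t - 1.0)
        a_s = 1.0 - 0.6 * (t - lag - 1.0)
        return a_u, a_s
    return t, np.maximum(t - lag, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_culture_scdata(config: CultureConfig | None = None) -> ad.AnnData:
    """Simulate the cultured-cell experiment; returns an AnnData with
    ``spliced``/``unspliced`` layers and ground-truth ``obs`` columns.

    Spliced abundance follows the unspliced program with a pseudotime lag,
    so genes being induced along a branch have unspliced counts above their
    steady-state line (positive velocity); steady genes satisfy
    mean(u)/mean(s) = us_ratio (degradation/splicing rate ratio).
    """
    config = config or CultureConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    var = _culture_gene_table(config, rng)
    genes = list(var.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    boosts = _population_boosts(config)

    counts_per_pop = largest_remainder(config.n_cells, config.population_fractions)
    population = np.concatenate(
        [np.full(counts_per_pop[p], p) for p in POPULATIONS]
    )
    n = len(population)
    perm = rng.permutation(n)
    population = population[perm]

    t = np.zeros(n)
    for p, (lo, hi) in _PSEUDOTIME.items():
        mask = population == p
        t[mask] = rng.uniform(lo, hi, mask.sum())

    # Per-cell states and double-positive flags.
    u = rng.random(n)
    propensity = np.array(
        [config.contractile_propensity.get(p, 0.0) for p in population]
    )
    is_fb = np.char.startswith(population.astype(str), "FB")
    is_mp = np.isin(population, ["MP1", "MP2"])
    fb_state = np.where(is_fb, np.where(u < propensity, "contractile",
                                        "matrix_producing"), "")
    lyz2_pos = is_fb & (rng.random(n) < config.lyz2_fb_rate)
    acta2_pos = is_mp & (rng.random(n) < config.acta2_mp_rate)

    log2 = np.zeros((n, len(genes)))
    for p in POPULATIONS:
        mask = population == p
        for g, b in boosts[p].items():
            log2[mask, gene_pos[g]] += b
    for g, b in (("Acta2", config.state_log2fc), ("Tpm2", config.state_log2fc),
                 ("Tagln", 1.0), ("Myl9", 1.0)):
        log2[fb_state == "contractile", gene_pos[g]] += b
    for g in G.MATRIX_STATE_GENES:
        log2[fb_state == "matrix_producing", gene_pos[g]] += config.state_log2fc
    log2[lyz2_pos, gene_pos["Lyz2"]] += 2.5
    for g in ("Csf1r", "Cd68"):
        log2[lyz2_pos, gene_pos[g]] += 0.8
    log2[acta2_pos, gene_pos["Acta2"]] += 4.0  # from the -2 floor up to FB level

    # Activation program factors (unspliced at a_u, spliced lagging at a_s).
    prog = var["program_amp"].to_numpy() != 0
    onset = var["program_onset"].to_numpy()[prog]
    amp = var["program_amp"].to_numpy()[prog]
    width = var["program_width"].to_numpy()[prog]
    factor_u = np.zeros((n, prog.sum()))
    factor_s = np.zeros((n, prog.sum()))
    for p in POPULATIONS:
        mask = population == p
        a_u, a_s = _activation_coordinate(p, t[mask], config.lag)
        factor_u[mask] = amp * _sigmoid((a_u[:, None] - onset) / width)
        factor_s[mask] = amp * _sigmoid((a_s[:, None] - onset) / width)
    off = np.isin(population, ["EC", "MP1", "MP2"])
    factor_u[off] = factor_s[off] = 0.0

    batch = rng.integers(0, config.n_batches, n)
    batch_fx = rng.lognormal(0.0, config.batch_sd, (config.n_batches, len(genes)))
    lib = rng.lognormal(0.0, config.library_sd, n)

    base = var["base"].to_numpy()
    ratio = var["us_ratio"].to_numpy()
    common = base[None, :] * 2.0**log2 * batch_fx[batch] * lib[:, None]
    mu_s = common.copy()
    mu_u = common * ratio[None, :]
    mu_s[:, prog] *= 2.0**factor_s
    mu_u[:, prog] *= 2.0**factor_u

    spliced = _nb_counts(rng, mu_s, config.dispersion)
    unspliced = _nb_counts(rng, mu_u, config.dispersion)

    # Doublets: overwrite a random subset with sums of two random cells.
    n_doub = int(np.floor(config.doublet_rate * n))
    is_doublet = np.zeros(n, dtype=bool)
    parents = np.full(n, "", dtype=object)
    if n_doub:
        targets = rng.choice(n, size=n_doub, replace=False)
        is_doublet[targets] = True
        singles = np.where(~is_doublet)[0]
        p1 = rng.choice(singles, size=n_doub)
        p2 = rng.choice(singles, size=n_doub)
        spliced[targets] = spliced[p1] + spliced[p2]
        unspliced[targets] = unspliced[p1] + unspliced[p2]
        parents[targets] = [f"{population[a]}+{population[b]}"
                            for a, b in zip(p1, p2)]

    obs = pd.DataFrame(
        {
            "population": pd.Categorical(population, categories=POPULATIONS),
            "batch": pd.Categorical([f"batch{b + 1}" for b in batch]),
            "pseudotime": t,
            "fb_state": fb_state,
            "is_doublet": is_doublet,
            "doublet_parents": parents,
            "true_lyz2_pos": lyz2_pos,
            "true_acta2_pos": acta2_pos,
        },
        index=pd.Index([f"cell{i + 1:05d}" for i in range(n)], name="cell"),
    )
    adata = ad.AnnData(
        X=spliced.astype(np.float32),
        obs=obs,
        var=var,
        layers={
            "spliced": spliced.astype(np.float32),
            "unspliced": unspliced.astype(np.float32),
        },
    )
    adata.uns["branch_topology"] = BRANCH_TOPOLOGY
    adata.uns["populations"] = POPULATIONS
    return adata


def population_signatures(adata: ad.AnnData, layer: str = "spliced") -> pd.DataFrame:
    """Mean depth-normalized expression per ground-truth population
    (genes x populations), the input for the bulk time-course mixer."""
    counts = np.asarray(adata.layers[layer])
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    scaled = counts / totals * np.median(counts.sum(axis=1))
    pops = adata.obs["population"].astype(str)
    keep = ~adata.obs["is_doublet"].to_numpy()
    cols = {}
    for p in POPULATIONS:
        mask = keep & (pops == p).to_numpy()
        cols[p] = scaled[mask].mean(axis=0)
    return pd.DataFrame(cols, index=adata.var_names)


# ---------------------------------------------------------------------------
# Bulk infarct time course
# ---------------------------------------------------------------------------

_DEFAULT_STAGES = ["uninjured", "3d", "7d", "2w", "later"]

#: Stage-dependent fibroblast-subpopulation weights: FB4 peaks at 3d and
#: collapses by 7d; FB5 and FB6 peak at 7d; near-uninjured again by 2w.
_DEFAULT_WEIGHTS = pd.DataFrame(
    [
        [0.35, 0.45, 0.15, 0.01, 0.03, 0.01],
        [0.05, 0.10, 0.15, 0.45, 0.15, 0.10],
        [0.05, 0.05, 0.10, 0.10, 0.35, 0.35],
        [0.25, 0.35, 0.20, 0.05, 0.10, 0.05],
        [0.30, 0.40, 0.17, 0.03, 0.06, 0.04],
    ],
    index=_DEFAULT_STAGES,
    columns=["FB1", "FB2", "FB3", "FB4", "FB5", "FB6"],
)


@dataclass
class TimecourseConfig:
    stages: list[str] = field(default_factory=lambda: list(_DEFAULT_STAGES))
    replicates_per_stage: int = 4
    mixing_weights: pd.DataFrame = field(
        default_factory=lambda: _DEFAULT_WEIGHTS.copy()
    )
    n_background_genes: int = 1500
    depth: float = 30.0  # sequencing-depth multiplier on signature units
    dispersion: float = 0.01  # bulk replicates are far tighter than single cells
    seed: int = 0

    def validate(self) -> None:
        if (self.mixing_weights.to_numpy() < 0).any():
            raise ValueError("mixing weights must be nonnegative")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if set(self.stages) != set(self.mixing_weights.index):
            raise ValueError("stages and mixing-weight rows disagree")


def generate_bulk_timecourse(
    config: TimecourseConfig, signatures: pd.DataFrame
):
    """Mix population signatures into a staged bulk data set.

    Each sample's expectation is its stage's convex mixture (weights
    normalized to sum 1) of the population signatures, plus stage-constant
    background genes; counts are negative binomial. Returns the
    BulkTimecourse plus a truth table of expected stage means and a
    ``varying`` flag (expected max/min ratio > 1.5).
    """
    from .staging import BulkTimecourse

    config.validate()
    missing = set(config.mixing_weights.columns) - set(signatures.columns)
    if missing:
        raise ValueError(f"signatures missing populations: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)

    w = config.mixing_weights.loc[config.stages]
    w = w.div(w.sum(axis=1), axis=0)
    sig = signatures[w.columns]
    expected_sig = config.depth * sig.to_numpy() @ w.to_numpy().T  # genes x stages

    bg_genes = [f"Bg{i:04d}" for i in range(1, config.n_background_genes + 1)]
    bg_mu = rng.lognormal(np.log(80.0), 1.0, len(bg_genes))
    expected = np.vstack(
        [expected_sig, np.tile(bg_mu[:, None], (1, len(config.stages)))]
    )
    all_genes = list(sig.index) + bg_genes

    samples, stage_of = [], []
    for s in config.stages:
        for r in range(config.replicates_per_stage):
            samples.append(f"{s}_r{r + 1}")
            stage_of.append(s)
    reps = expected[:, [config.stages.index(s) for s in stage_of]]
    lib = rng.lognormal(0.0, 0.04, len(samples))
    counts = _nb_counts(rng, reps * lib[None, :], config.dispersion)

    expression = pd.DataFrame(
        counts, index=pd.Index(all_genes, name="gene"), columns=samples
    )
    stages = pd.Series(stage_of, index=expression.columns, name="stage")
    bulk = BulkTimecourse(expression=expression, stages=stages,
                          stage_order=list(config.stages))
    exp_df = pd.DataFrame(expected, index=all_genes, columns=config.stages)
    lo = exp_df.min(axis=1).replace(0, np.nan)
    # planted stage effects: genes whose expected range spans > 2-fold
    truth = pd.DataFrame(
        {"varying": (exp_df.max(axis=1) / lo > 2.0).fillna(False)}
    )
    truth = pd.concat([truth, exp_df.add_prefix("expected_")], axis=1)
    return bulk, truth
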