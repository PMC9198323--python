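"""Single-cell QC, doublets, preprocessing, clustering, markers, typing."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibrosig import scpop


def _adata(spliced, unspliced=None, genes=None, X=None):
    spliced = np.asarray(spliced, dtype=float)
    unspliced = spliced.copy() if unspliced is None else np.asarray(unspliced, float)
    genes = genes or [f"G{i}" for i in range(spliced.shape[1])]
    adata = ad.AnnData(
        X=spliced if X is None else np.asarray(X, dtype=float),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        layers={"spliced": spliced, "unspliced": unspliced},
    )
    adata.obs_names = [f"c{i}" for i in range(spliced.shape[0])]
    return adata


class TestQC:
    def test_total_count_rule(self):
        spliced = np.array([[25, 19, 25], [0, 0, 0]])
        unspliced = np.array([[25, 25, 19], [0, 0, 0]])
        out = scpop.qc_filter_genes(_adata(spliced, unspliced), min_count=20)
        assert list(out.var_names) == ["G0"]

    def test_min_count_zero_is_identity(self):
        spliced = np.array([[0, 1], [2, 0]])
        out = scpop.qc_filter_genes(_adata(spliced), min_count=0)
        assert out.n_vars == 2

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError):
            scpop.qc_filter_genes(_adata(np.zeros((3, 2))), min_count=1)


class TestDoublets:
    def test_constructed_midpoints_get_top_scores(self, rng):
        # two tight, well-separated clusters plus explicit cell-pair sums
        n = 150
        a = rng.poisson(50, (n, 10)) * np.r_[np.ones(5), np.zeros(5)]
        b = rng.poisson(50, (n, 10)) * np.r_[np.zeros(5), np.ones(5)]
        mids = a[:20] + b[:20]
        counts = np.vstack([a, b, mids])
        adata = _adata(counts)
        out = scpop.doublet_score(adata, k=15, seed=0)
        mid_scores = out["score"].iloc[2 * n :]
        single_scores = out["score"].iloc[: 2 * n]
        assert mid_scores.min() > single_scores.quantile(0.95)

    def test_injected_doublets_score_higher(self, culture_chain, culture_raw):
        doublets = culture_chain["doublets"]
        truth = culture_raw.obs["is_doublet"].to_numpy()
        assert (
            doublets["score"][truth].mean() > doublets["score"][~truth].mean()
        )

    def test_null_flagged_fraction_at_nominal_rate(self, rng):
        counts = rng.poisson(20, (400, 30))
        out = scpop.doublet_score(_adata(counts), k=10, threshold_quantile=0.95, seed=1)
        assert out["remove"].mean() <= 0.06

    def test_too_few_cells_error(self, rng):
        with pytest.raises(ValueError):
            scpop.doublet_score(_adata(rng.poisson(5, (20, 5))), k=30)


class TestPreprocess:
    def test_scaling_arithmetic(self):
        # cell 1 has double the median total -> its counts are halved
        spliced = np.array([[10, 10], [20, 20], [5, 15]], dtype=float)
        adata = scpop.preprocess(_adata(spliced), n_pcs=1, k=1)
        totals = spliced.sum(axis=1)
        expected = np.log1p(spliced / totals[:, None] * np.median(totals))
        assert np.allclose(np.asarray(adata.X), expected, atol=1e-6)
        assert np.asarray(adata.X)[1, 0] == pytest.approx(np.log1p(10.0), abs=1e-6)

    def test_log1p_of_zero_stays_zero(self):
        spliced = np.array([[0, 10], [0, 10], [0, 20]], dtype=float)
        adata = scpop.preprocess(_adata(spliced), n_pcs=1, k=1)
        assert np.asarray(adata.X)[:, 0] == pytest.approx(0.0)

    def test_identical_cells_collapse_in_pc_space(self):
        spliced = np.tile([5.0, 7.0, 2.0], (6, 1))
        adata = scpop.preprocess(_adata(spliced), n_pcs=1, k=2)
        d = adata.obsm["X_pca"]
        assert np.allclose(d - d[0], 0.0, atol=1e-9)

    def test_zero_total_cell_removed(self):
        spliced = np.array([[5, 5], [0, 0], [4, 6], [5, 5]], dtype=float)
        adata = scpop.preprocess(_adata(spliced), n_pcs=1, k=1)
        assert adata.n_obs == 3


class TestClustering:
    def _blobs(self, rng, n=120):
        # enough genes that the kNN graph is connected within each blob
        mean_a = np.r_[np.full(15, 40.0), np.full(15, 2.0)]
        mean_b = np.r_[np.full(15, 2.0), np.full(15, 40.0)]
        a = rng.poisson(mean_a, (n, 30))
        b = rng.poisson(mean_b, (n, 30))
        return _adata(np.vstack([a, b]).astype(float))

    def test_two_blobs_two_clusters(self, rng):
        adata = self._blobs(rng)
        adata = scpop.preprocess(adata, n_pcs=5, k=15)
        labels = scpop.cluster_cells(adata, resolution=0.02, seed=0)
        assert labels.nunique() == 2

    def test_resolution_to_zero_single_cluster(self, rng):
        adata = self._blobs(rng)
        adata = adata[:120].copy()  # one connected blob
        adata = scpop.preprocess(adata, n_pcs=5, k=15)
        labels = scpop.cluster_cells(adata, resolution=0.005, seed=0)
        assert labels.nunique() == 1

    def test_missing_graph_error(self, rng):
        adata = _adata(rng.poisson(5, (10, 4)))
        with pytest.raises(ValueError):
            scpop.cluster_cells(adata)

    def test_full_dataset_ari(self, culture_chain):
        """Louvain at a scanned resolution recovers the 9 ground-truth
        populations on the default synthetic culture."""
        adata = culture_chain["adata"]
        truth = adata.obs["population"].astype(str)
        best = scpop.scan_resolutions(adata, truth, resolutions=(0.4, 0.8, 1.2), seed=0)
        assert best["ari"] >= 0.8


class TestMarkers:
    def test_exclusive_gene_is_top_marker(self, rng):
        counts = rng.poisson(10, (60, 5)).astype(float)
        counts[:30, 0] = 0.0  # G0 expressed only in cluster B
        adata = _adata(counts, X=np.log1p(counts))
        labels = pd.Series(["A"] * 30 + ["B"] * 30, index=adata.obs_names)
        table = scpop.cluster_markers_ttest(adata, labels, top_n=3)
        top_b = table[table["cluster"] == "B"].iloc[0]
        assert top_b["gene"] == "G0"

    def test_welch_t_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 3.5, 4.5])
        x = np.r_[a, b][:, None]
        adata = _adata(np.ones_like(x), X=x)
        labels = pd.Series(["A"] * 4 + ["B"] * 3, index=adata.obs_names)
        table = scpop.cluster_markers_ttest(adata, labels, top_n=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(
            a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        )
        got = table[table["cluster"] == "A"]["t"].iloc[0]
        assert got == pytest.approx(t_hand)

    def test_label_permutation_equivariance(self, rng):
        counts = rng.poisson(8, (40, 6)).astype(float)
        adata = _adata(counts, X=np.log1p(counts))
        labels = pd.Series(rng.choice(["A", "B"], 40), index=adata.obs_names)
        swapped = labels.map({"A": "B", "B": "A"})
        t1 = scpop.cluster_markers_ttest(adata, labels, top_n=6)
        t2 = scpop.cluster_markers_ttest(adata, swapped, top_n=6)
        a1 = t1[t1["cluster"] == "A"].set_index("gene")["t"]
        b2 = t2[t2["cluster"] == "B"].set_index("gene")["t"]
        assert np.allclose(a1.sort_index(), b2.sort_index())

    def test_planted_unique_markers_recovered(self, fb_compartment):
        from fibrosig.genes import FB_UNIQUE_MARKERS

        adata = fb_compartment["adata"]
        truth = fb_compartment["truth"]
        table = scpop.cluster_markers_ttest(adata, truth, top_n=10)
        for pop, markers in FB_UNIQUE_MARKERS.items():
            found = set(table[table["cluster"] == pop]["gene"])
            assert found & set(markers), f"{pop} lost its unique markers"


class TestTyping:
    def _typed_toy(self):
        genes = ["Emcn", "Lyz2", "Acta2", "Col1a1", "Tpm2"]
        rows = []
        for _ in range(50):  # fibroblasts
            rows.append([0, 0, 5, 5, 4])
        for _ in range(20):  # macrophages
            rows.append([0, 8, 0, 0, 0])
        rows.append([9, 0, 0, 0, 0])  # endothelial
        rows.append([0, 8, 6, 0, 0])  # Lyz2+Acta2 double positive
        x = np.array(rows, dtype=float)
        return _adata(np.expm1(x), genes=genes, X=x)

    def test_rule_order_and_flags(self):
        adata = self._typed_toy()
        out = scpop.classify_celltypes(adata)
        assert out["celltype"].iloc[0] == "fibroblast"
        assert out["celltype"].iloc[50] == "macrophage"
        assert out["celltype"].iloc[70] == "endothelial"
        dp = out.iloc[71]
        assert dp["celltype"] == "macrophage" and dp["acta2_positive"]

    def test_missing_marker_gene_error(self, rng):
        adata = _adata(rng.poisson(5, (10, 2)), genes=["A", "B"])
        with pytest.raises(ValueError):
            scpop.classify_celltypes(adata)

    def test_composition_recovery(self, culture_chain):
        fr = culture_chain["types"]["celltype"].value_counts(normalize=True) * 100
        assert fr["fibroblast"] == pytest.approx(74.3, abs=2.0)
        assert fr["macrophage"] == pytest.approx(24.9, abs=2.0)
        assert fr["endothelial"] == pytest.approx(0.89, abs=0.5)


class TestFibroblastState:
    def test_clear_matrix_cell(self):
        genes = ["Col1a1", "Col1a2", "Acta2", "Tpm2"]
        x = np.array([[4, 4, 1, 1]] * 10 + [[1, 1, 4, 4]] * 10, dtype=float)
        adata = _adata(np.expm1(x), genes=genes, X=x)
        out = scpop.classify_fb_state(adata, np.ones(20, dtype=bool))
        assert (out["state"].iloc[:10] == "matrix_producing").all()
        assert (out["state"].iloc[10:] == "contractile").all()

    def test_tie_breaks_to_contractile(self):
        genes = ["Col1a1", "Col1a2", "Acta2", "Tpm2"]
        x = np.array([[2, 2, 2, 2], [3, 3, 3, 3]], dtype=float)
        adata = _adata(np.expm1(x), genes=genes, X=x)
        out = scpop.classify_fb_state(adata, np.ones(2, dtype=bool))
        assert (out["state"] == "contractile").all()

    def test_no_fibroblasts_error(self, rng):
        adata = _adata(rng.poisson(5, (5, 4)),
                       genes=["Col1a1", "Col1a2", "Acta2", "Tpm2"])
        with pytest.raises(ValueError):
            scpop.classify_fb_state(adata, np.zeros(5, dtype=bool))

    def test_planted_state_split_recovered(self, culture_chain):
        fr = culture_chain["states"].attrs["fractions"]
        assert fr["matrix_producing"] * 100 == pytest.approx(76.0, abs=2.0)


class TestCellCycleAndProliferation:
    def test_cell_at_means_is_g1_with_zero_scores(self):
        genes = [f"S{i}" for i in range(3)] + [f"M{i}" for i in range(3)]
        x = np.tile(np.array([5.0, 4.0, 3.0, 2.0, 1.0, 6.0]), (20, 1))
        adata = _adata(np.expm1(x), genes=genes, X=x)
        out = scpop.cellcycle_phase(adata, genes[:3], genes[3:])
        assert (out["phase"] == "G1").all()
        assert np.allclose(out["S_score"], 0.0)

    def test_g2m_high_cell(self, rng):
        genes = ["S0", "S1", "M0", "M1"]
        x = rng.normal(0, 1, (50, 4))
        x[0, 2:] += 5.0
        adata = _adata(np.abs(x), genes=genes, X=x)
        out = scpop.cellcycle_phase(adata, ["S0", "S1"], ["M0", "M1"])
        assert out["phase"].iloc[0] == "G2M"

    def test_fb4_is_g2m_dominated(self, culture_chain):
        adata = culture_chain["adata"]
        out = scpop.cellcycle_phase(adata)
        pop = adata.obs["population"].astype(str)
        fb4 = (pop == "FB4").to_numpy()
        assert (out.loc[fb4, "phase"] == "G2M").mean() > 0.5
        assert (out.loc[~fb4, "phase"] == "G2M").mean() < 0.5

    def test_equal_weighting_cancels(self):
        # two genes at z = +1 and -1, two at the mean: score is exactly 0
        genes = [f"P{i}" for i in range(4)]
        x = np.array([[1.0, -1.0, 0.0, 0.0],
                      [-1.0, 1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0, -1.0],
                      [0.0, 0.0, -1.0, 1.0]])
        adata = _adata(np.abs(x) + 1, genes=genes, X=x)
        out = scpop.proliferation_score(adata, genes=genes)
        assert np.allclose(out["score"], 0.0)

    def test_missing_gene_listed(self, rng):
        adata = _adata(rng.poisson(5, (10, 2)), genes=["Ccnd1", "Ccnd2"])
        with pytest.raises(ValueError, match="Mki67"):
            scpop.proliferation_score(adata)

    def test_fb4_most_proliferative_fb1_fb3_least(self, culture_chain):
        adata = culture_chain["adata"]
        pop = adata.obs["population"].astype(str)
        out = scpop.proliferation_score(adata, labels=pop)
        frac = out["cluster_fraction"]
        fb = frac[[p for p in frac.index if p.startswith("FB")]]
        assert fb.idxmax() == "FB4"
        assert set(fb.nsmallest(2).index) == {"FB1", "FB3"}


class TestFractions:
    def test_equal_labels(self):
        out = scpop.population_fractions(pd.Series(["a", "b", "c"] * 4))
        assert np.allclose(out, 1 / 3, atol=1e-3)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_label(self):
        assert scpop.population_fractions(pd.Series(["x"] * 5)).iloc[0] == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            scpop.population_fractions(pd.Series(dtype=object))

    def test_fibroblast_total_near_743(self, culture_raw):
        pop = culture_raw.obs["population"].astype(str)
        frac = scpop.population_fractions(
            pd.Series(np.where(pop.str.startswith("FB"), "FB", pop))
        )
        assert frac["FB"] * 100 == pytest.approx(74.3, abs=0.5)
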