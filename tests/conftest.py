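"""Shared fixtures: the synthetic study datasets, generated once per session."""

import numpy as np
import pytest

from fibrosig import panel, scpop, synth


@pytest.fixture(scope="session")
def culture_raw():
    """Default cultured-cell dataset (8000 cells, seed 0)."""
    return synth.generate_culture_scdata(synth.CultureConfig(seed=0))


@pytest.fixture(scope="session")
def culture_chain(culture_raw):
    """End-to-end chain: QC -> doublet removal -> preprocess -> typing -> states."""
    adata = scpop.qc_filter_genes(culture_raw.copy())
    doublets = scpop.doublet_score(adata, seed=0)
    adata = adata[~doublets["remove"].to_numpy()].copy()
    adata = scpop.preprocess(adata, seed=0)
    types = scpop.classify_celltypes(adata)
    fb_mask = (types["celltype"] == "fibroblast").to_numpy()
    states = scpop.classify_fb_state(adata, fb_mask)
    return {
        "adata": adata,
        "doublets": doublets,
        "types": types,
        "fb_mask": fb_mask,
        "states": states,
    }


@pytest.fixture(scope="session")
def fb_compartment(culture_raw):
    """Ground-truth fibroblast cells (doublets dropped), preprocessed, with a
    resolution-scanned Louvain clustering and the velocity pipeline run."""
    from fibrosig import velo

    pop = culture_raw.obs["population"].astype(str)
    keep = pop.str.startswith("FB").to_numpy() & ~culture_raw.obs[
        "is_doublet"
    ].to_numpy()
    fb = culture_raw[keep].copy()
    fb = scpop.preprocess(fb, seed=0)
    truth = fb.obs["population"].astype(str)
    best = scpop.scan_resolutions(fb, truth, seed=0)
    mapped = scpop.map_clusters_to_truth(best["labels"], truth)
    model, field = velo.run_velocity_pipeline(fb)
    return {"adata": fb, "truth": truth, "best": best, "mapped": mapped,
            "model": model, "field": field}


@pytest.fixture(scope="session")
def cohort_default():
    cfg = synth.CohortConfig(seed=0)
    cohort = synth.generate_patient_cohort(cfg)
    norm = panel.normalize_reference_genes(cohort)
    norm = panel.correct_age(norm, cohort.metadata["age"])
    return {"config": cfg, "cohort": cohort, "norm": norm}


@pytest.fixture(scope="session")
def bulk_default(culture_raw):
    signatures = synth.population_signatures(culture_raw)
    cfg = synth.TimecourseConfig(seed=0)
    bulk, truth = synth.generate_bulk_timecourse(cfg, signatures)
    return {"bulk": bulk, "truth": truth, "signatures": signatures, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
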