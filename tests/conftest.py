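import numpy as np
import pytest
from hypothesis import settings

import isousage as iu

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return iu.SimulationConfig(seed=1234)


@pytest.fixture(scope="session")
def small_sim():
    """Small full-featured cohort: models, expression, annotations, truth."""
    cfg = iu.SimulationConfig(n_genes=150, seed=42)
    models = iu.simulate_gene_models(cfg)
    matrix, annotations, truth = iu.simulate_cohort(models, cfg)
    return cfg, models, matrix, annotations, truth


@pytest.fixture(scope="session")
def null_pair_pvalues():
    """Interaction p-values for 5000 two-isoform genes with no planted effects."""
    cfg = iu.SimulationConfig(
        n_genes=5000,
        isoform_count_distribution={2: 1.0},
        switch_fraction=0.0,
        gene_de_fraction=0.0,
        seed=901,
    )
    models = iu.simulate_gene_models(cfg)
    matrix, annotations, _ = iu.simulate_cohort(models, cfg)
    pairs = iu.pairwise_interaction_tests(matrix, models, annotations)
    return np.array([r.p for r in pairs])


@pytest.fixture(scope="session")
def power_sim():
    """Two-isoform cohort with planted switches at the reference conditions
    (switch_effect=2, noise_sd=0.5, 11+14 samples)."""
    cfg = iu.SimulationConfig(
        n_genes=800,
        isoform_count_distribution={2: 1.0},
        switch_fraction=0.25,
        seed=902,
    )
    models = iu.simulate_gene_models(cfg)
    matrix, annotations, truth = iu.simulate_cohort(models, cfg)
    results = iu.pairwise_interaction_tests(matrix, models, annotations)
    return cfg, models, matrix, annotations, truth, results


@pytest.fixture(scope="session")
def theta_recovery_fit():
    """NB dispersion recovery under the normalization model's own assumptions:
    per-probe constant expression, assay/well factors only, ~10k observations."""
    cfg = iu.SimulationConfig(
        n_genes=52,
        isoform_count_distribution={2: 1.0},
        nb_dispersion=10.0,
        noise_sd=0.0,
        switch_fraction=0.0,
        gene_de_fraction=0.0,
        n_samples_ERpos=48,
        n_samples_TN=48,
        seed=903,
    )
    models = iu.simulate_gene_models(cfg)
    matrix, annotations, _ = iu.simulate_cohort(models, cfg)
    genes = iu.group_by_gene(models)
    pairs = [
        tuple(sorted(tx.transcript_id for tx in txs)) for txs in genes.values()
    ]
    data = iu.simulate_nanostring(
        matrix, pairs, cfg, assay_sd=0.1, well_sd=0.05, library_sd=0.0
    )
    model, residuals = iu.fit_nanostring_model(data)
    return cfg, data, model, residuals


@pytest.fixture(scope="session")
def replication_sim():
    """Cross-platform replication conditions: switched pairs passed through
    probe-panel selection, NanoString counts at dispersion 30."""
    cfg = iu.SimulationConfig(n_genes=2200, nb_dispersion=30.0, seed=905)
    models = iu.simulate_gene_models(cfg)
    matrix, annotations, truth = iu.simulate_cohort(models, cfg)
    candidates = sorted(truth.switch_pair.values())
    panel = iu.select_probe_panel(matrix, candidates)
    data = iu.simulate_nanostring(matrix, panel, cfg)
    ns_model, residuals = iu.fit_nanostring_model(data)
    return cfg, models, matrix, annotations, truth, panel, residuals
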