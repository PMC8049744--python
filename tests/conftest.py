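import numpy as np
import pytest

from regenomics.synthio import (
    DesignConfig,
    EffectModel,
    generate_experiment,
    make_effect_model,
    make_motif_library,
)


@pytest.fixture(scope="session")
def small_config():
    return DesignConfig(n_genes=300, n_peaks=800, seed=42)


@pytest.fixture(scope="session")
def gene_ids(small_config):
    return [f"g{i:04d}" for i in range(small_config.n_genes)]


@pytest.fixture(scope="session")
def effect_model(gene_ids):
    return make_effect_model(
        gene_ids, n_injury=40, n_head=25, n_foot=25, n_apoptosis=10, seed=42
    )


@pytest.fixture(scope="session")
def motif_library():
    return make_motif_library(n_decoys=3, seed=42)


@pytest.fixture(scope="session")
def experiment(small_config, effect_model, motif_library):
    """One shared planted experiment: (rna, atac, truth, extras)."""
    return generate_experiment(small_config, effect_model, motif_library)


@pytest.fixture(scope="session")
def null_experiment():
    """No planted effects: 800 genes, 800 peaks, full design."""
    cfg = DesignConfig(n_genes=800, n_peaks=800, seed=7)
    return generate_experiment(cfg, EffectModel())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
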