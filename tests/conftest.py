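import numpy as np
import pandas as pd
import pytest

import salivamics as sm


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic cohort at default settings (seed fixed)."""
    cfg = sm.SynthConfig(seed=11)
    metadata, layers, truth = sm.generate_study(cfg)
    return cfg, metadata, layers, truth


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort for fast unit tests."""
    return sm.SynthConfig(
        n_control=20, n_mci=10, n_ad=10,
        n_proteins=60, n_metabolites=40, n_species=30,
        microbiome_subset=24, n_modules_per_layer=2,
        module_size_range=(8, 12), n_planted_markers=4,
        n_ptau_correlates=4, seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    metadata, layers, truth = sm.generate_study(small_config)
    return metadata, layers, truth


@pytest.fixture(scope="session")
def imputed_protein(default_study):
    """Default protein layer taken through normalize + impute."""
    _, metadata, layers, _ = default_study
    normalized = sm.log_median_normalize(layers["protein"])
    return sm.impute_downshift(normalized, sm.ImputationParams(seed=11)), metadata


def make_imputed(values: np.ndarray, layer: str = "protein",
                 prefix: str = "F") -> sm.OmicsMatrix:
    """Wrap a plain array as an analysis-ready (imputed-state) matrix."""
    n_feat, n_samp = values.shape
    frame = pd.DataFrame(
        values,
        index=pd.Index([f"{prefix}{i:03d}" for i in range(n_feat)], name="feature_id"),
        columns=[f"S{j:03d}" for j in range(n_samp)],
    )
    return sm.OmicsMatrix(frame, state="imputed", layer=layer)
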