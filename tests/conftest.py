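"""Shared fixtures: small phantom atlases, cohorts, and pipeline runs.

Everything is generated programmatically at fixed seeds; the expensive
moderate-scale pipeline run is session-scoped so the whole suite pays for
it once.
"""

import numpy as np
import pytest

from covnet.config import PipelineConfig
from covnet.phantom import make_phantom_sources


@pytest.fixture(scope="session")
def atlas_small():
    """Desk-scale atlas on a 16×20×16 grid (fast unit-test geometry)."""
    return make_phantom_sources((16, 20, 16), k_true=6, seed=42)


@pytest.fixture(scope="session")
def atlas_default():
    """Atlas at the default study geometry (32×40×32 at 3 mm)."""
    return make_phantom_sources((32, 40, 32), k_true=6, seed=42)


@pytest.fixture(scope="session")
def small_cfg():
    return PipelineConfig(n_components=8, n_icasso_runs=4, seed=7, n_volumes=120)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """A moderate synthetic study: big enough for directional effects,
    small enough to run in seconds."""
    from covnet.pipeline import run_pipeline

    return run_pipeline(
        small_cfg, n_pd=40, n_hc=30, n_followup=15,
        grid_shape=(16, 20, 16), n_group_ica_subjects=12,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
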