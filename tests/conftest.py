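"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from phconn.features import assemble_features
from phconn.pipeline import _preprocess_runs, compute_dc_map
from phconn.synthetic import CohortConfig, generate_cohort


def make_dc_map(config: CohortConfig):
    """Generate, preprocess and window a cohort; return (dc_map, truth)."""
    cohort, truth = generate_cohort(config)
    runs = _preprocess_runs(cohort.runs, cohort.nuisance, 0.01, 0.1)
    return compute_dc_map(runs), truth


@pytest.fixture(scope="session")
def strong_cohort():
    """8 subjects x 30 nodes with an overwhelming planted effect (delta=2)."""
    cfg = CohortConfig(
        n_subjects=8,
        n_nodes=30,
        n_volumes=150,
        conditions=("saline", "ketamine"),
        effect_size=2.0,
        seed=17,
    )
    dc_map, truth = make_dc_map(cfg)
    return cfg, dc_map, truth


@pytest.fixture(scope="session")
def strong_features(strong_cohort):
    """Binary feature set for the strong-effect cohort (ketamine = +1)."""
    _, dc_map, truth = strong_cohort
    return assemble_features(dc_map, "ketamine", "saline", truth.node_labels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
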