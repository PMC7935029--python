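import numpy as np
import pytest

from cgcn.fc_graph import KnnGraph, RoiTimeSeries
from cgcn.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_graph():
    """Hand-checkable 5-node graph with k=2."""
    neighbors = np.array([[1, 2], [0, 3], [3, 0], [4, 1], [0, 2]])
    return KnnGraph(n_nodes=5, k=2, neighbors=neighbors)


@pytest.fixture
def random_record(rng):
    return RoiTimeSeries(
        subject_id="subA", session_id="ses0", class_label=0, site_label="s0",
        signals=rng.standard_normal((50, 20)),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-class, two-site cohort small enough for harness tests."""
    spec = CohortSpec(n_subjects=8, n_sessions_per_subject=2, n_rois=20,
                      n_frames=120, n_networks=2, fingerprint_strength=0.2,
                      group_effect=0.8, n_classes=2, n_sites=2, seed=77)
    records, truth = generate_cohort(spec)
    return spec, records, truth
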