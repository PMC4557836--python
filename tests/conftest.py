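import numpy as np
import pytest

from connrel import (
    ConnectivityMatrix,
    ROIRecord,
    ROITable,
    SessionStack,
    StudyConfig,
    build_matrix,
    generate_cohort,
    run_study,
)


@pytest.fixture
def tiny_roi_table() -> ROITable:
    """Three midline ROIs with simple geometry for closed-form checks."""
    recs = [
        ROIRecord("a", "none", (0.0, 0.0, 0.0), 10.0, 2.0),
        ROIRecord("b", "none", (10.0, 0.0, 0.0), 10.0, 2.0),
        ROIRecord("c", "none", (0.0, 10.0, 0.0), 20.0, 4.0),
    ]
    return ROITable(recs, atlas_name="tiny")


def random_symmetric(n: int, rng: np.random.Generator, density: float = 1.0) -> np.ndarray:
    w = rng.uniform(0.1, 2.0, size=(n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        w = w * mask
    w = np.triu(w, k=1)
    return w + w.T


@pytest.fixture
def matrix_factory(tiny_roi_table):
    def make(weights, **kw):
        return ConnectivityMatrix(tiny_roi_table, np.asarray(weights, dtype=float), **kw)
    return make


def stack_from_weights(roi_table, weights_by_cell, sessions):
    """Build a SessionStack directly from {(subject, session): array}."""
    matrices = {
        cell: ConnectivityMatrix(roi_table, w, subject_id=cell[0], session_id=cell[1])
        for cell, w in weights_by_cell.items()
    }
    subjects = sorted({s for s, _ in weights_by_cell})
    return SessionStack(subjects, sessions, matrices)


def cohort_stack(params, roi_table=None):
    """Generate a cohort and assemble its SessionStack."""
    fiber_sets, truth = generate_cohort(params, roi_table=roi_table)
    table = truth.roi_table
    matrices = {
        (fs.subject_id, fs.session_id): build_matrix(fs, table) for fs in fiber_sets
    }
    subjects = sorted({fs.subject_id for fs in fiber_sets})
    return SessionStack(subjects, params.sessions, matrices, method=params.method), truth


@pytest.fixture(scope="session")
def default_study():
    """The default simulated study (83 ROIs, 20 subjects, both regimes),
    shared across acceptance-style checks because it is the expensive
    fixture of the suite."""
    return run_study(StudyConfig(seed=1))
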