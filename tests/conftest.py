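import numpy as np
import pytest

import micropoint as mp


@pytest.fixture(scope="session")
def model():
    return mp.NormativeModel()


@pytest.fixture(scope="session")
def grid():
    return mp.build_study_grid()


@pytest.fixture(scope="session")
def criteria():
    return mp.default_criteria()


@pytest.fixture
def make_exam(grid):
    """Factory for quick exams on the 33-point grid."""

    def _make(
        thresholds,
        *,
        subject_id="S001",
        eye="right",
        exam_index=1,
        age=62.2,
        fp=0.05,
        cohort="healthy",
    ):
        thresholds = np.asarray(thresholds, dtype=float)
        if thresholds.ndim == 0:
            thresholds = np.full(len(grid), float(thresholds))
        return mp.Exam(
            subject_id=subject_id,
            eye=eye,
            exam_index=exam_index,
            age=age,
            grid=grid,
            thresholds=thresholds,
            false_positive_rate=fp,
            cohort=cohort,
        )

    return _make


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-cohort simulated dataset shared across tests."""
    config = mp.SimulationConfig(n_healthy=10, n_iamd=12, seed=42)
    return mp.simulate_cohort(config)
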