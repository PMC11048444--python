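"""Shared fixtures.

The three preset pipelines are expensive, so they are fitted once per
session at a reduced subject count and shared across the end-to-end tests.
The equal-block designs behave like the full 100-subject runs at M=25; the
Dirichlet design needs M=50 because the scanner-noise fraction surviving
compression scales as K/(C*M) and its largest blocks sit closest to the
redundancy-test boundary.
"""

from __future__ import annotations

import numpy as np
import pytest

from hpca.model import HierarchicalPCA
from hpca.simulate import HierarchySpec, simulate_experiment

#: Scaled-down study conditions shared by the end-to-end tests.
SCALED_SUBJECTS = {"5L2D": 25, "3L3D": 25, "3L3Ddirich": 50}
SESSION_SEED = 20


def _run_preset(name: str):
    specs = {
        "5L2D": HierarchySpec(5, 2, 1024, "equal", seed=SESSION_SEED),
        "3L3D": HierarchySpec(3, 3, 1024, "equal", seed=SESSION_SEED),
        "3L3Ddirich": HierarchySpec(
            3, 3, 1024, "dirichlet", (3.0, 3.0, 3.0), seed=SESSION_SEED
        ),
    }
    sources, subjects = simulate_experiment(
        specs[name], SCALED_SUBJECTS[name], n_timepoints=300, tr=2.0, seed=SESSION_SEED
    )
    res = HierarchicalPCA(subjects, subject_pcs=295, group_pcs=300).fit()
    return sources, subjects, res


@pytest.fixture(scope="session")
def run_5l2d():
    return _run_preset("5L2D")


@pytest.fixture(scope="session")
def run_3l3d():
    return _run_preset("3L3D")


@pytest.fixture(scope="session")
def run_3l3ddirich():
    return _run_preset("3L3Ddirich")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_block_subjects():
    """Noiseless two-block data: two independent sources, 10 voxels each."""
    rng = np.random.default_rng(7)
    subjects = []
    for _ in range(4):
        s = rng.standard_normal((2, 200))
        weights = np.zeros((20, 2))
        weights[:10, 0] = 1.0
        weights[10:, 1] = 1.0
        # small within-block weight jitter keeps voxels distinct but correlated
        weights += rng.normal(0, 0.05, weights.shape) * (weights > 0)
        subjects.append(weights @ s)
    return subjects
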