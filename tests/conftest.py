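import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from conncohort import CohortConfig, ConnectivityMatrix


def as_matrix(w, scan_id="test"):
    w = np.asarray(w, dtype=float)
    labels = [str(i + 1) for i in range(w.shape[0])]
    return ConnectivityMatrix(scan_id=scan_id, weights=w, node_labels=labels)


@pytest.fixture
def path3():
    """Path graph 1-2-3, unit weights."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return as_matrix(w)


@pytest.fixture
def weighted_triangle():
    """Triangle with w(A,B)=1, w(A,C)=0.5, w(B,C)=0.5."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[0, 2] = w[2, 0] = 0.5
    w[1, 2] = w[2, 1] = 0.5
    return as_matrix(w)


@pytest.fixture
def star_k13():
    """Star K1,3: node 0 is the hub."""
    w = np.zeros((4, 4))
    for leaf in (1, 2, 3):
        w[0, leaf] = w[leaf, 0] = 1.0
    return as_matrix(w)


@pytest.fixture
def complete4():
    w = np.ones((4, 4)) - np.eye(4)
    return as_matrix(w)


@pytest.fixture
def ring90():
    w = np.zeros((90, 90))
    for i in range(90):
        j = (i + 1) % 90
        w[i, j] = w[j, i] = 0.5
    return as_matrix(w)


@pytest.fixture(scope="session")
def quiet_cohort_config():
    """Small cohort with no site effects, effects or noise (pure template)."""
    return CohortConfig(
        n_tbi=4, n_oi=2, seed=11, noise_sd_edge=0.0, age_slope=0.0,
        site_effects={s: {"shift": 0.0, "scale": 1.0}
                      for s in ("S1", "S2", "S3", "S4", "S5")},
    )
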