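import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sevnet as sv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chain6() -> sv.GroundTruthNetwork:
    """p = 6 chain with couplings 1.5 and thresholds -0.75."""
    couplings = np.zeros((6, 6))
    for i in range(5):
        couplings[i, i + 1] = couplings[i + 1, i] = 1.5
    return sv.GroundTruthNetwork(couplings, np.full(6, -0.75))


@pytest.fixture(scope="session")
def chain6_edges() -> set[tuple[int, int]]:
    return {(i, i + 1) for i in range(5)}


@pytest.fixture(scope="session")
def default_gt() -> sv.GroundTruthNetwork:
    return sv.default_ground_truth()


@pytest.fixture(scope="session")
def two_triangles() -> np.ndarray:
    """Two disconnected unit-weight triangles on 6 nodes."""
    w = np.zeros((6, 6))
    for tri in ((0, 1, 2), (3, 4, 5)):
        for i in tri:
            for j in tri:
                if i != j:
                    w[i, j] = 1.0
    return w


@pytest.fixture(scope="session")
def bridged_cliques() -> np.ndarray:
    """Two 4-cliques (weight 1.0) joined by one bridge edge (weight 0.1)."""
    w = np.zeros((8, 8))
    for clique in (range(4), range(4, 8)):
        for i in clique:
            for j in clique:
                if i != j:
                    w[i, j] = 1.0
    w[3, 4] = w[4, 3] = 0.1
    return w


@pytest.fixture(scope="session")
def small_cohort() -> sv.SymptomCohort:
    """Down-scaled default cohort for fast structural tests."""
    spec = sv.CohortSpec(group_sizes=(150, 100, 120, 130), seed=3)
    return sv.generate_ordinal_cohort(spec)
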