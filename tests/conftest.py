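import numpy as np
import pytest

import roiselect as rs


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted-signal cohort: 12 ROIs, planted {1, 4, 7}, 12+12 subjects."""
    spec = rs.SyntheticSpec(
        n_per_class=(12, 12), n_rois=12, planted_set=(1, 4, 7),
        series_length=60, seed=42,
    )
    return spec, rs.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    _, ds = small_cohort
    two = rs.select_pair(ds, rs.GroupPair("healthy", "UWS"))
    return rs.split(two, rs.SplitSpec(seed=7))


@pytest.fixture(scope="session")
def three_group_cohort():
    """Cohort with all three groups; MCS/UWS share the planted alteration."""
    spec = rs.SyntheticSpec(
        n_per_class=(8, 8), n_rois=10, planted_set=(2, 5, 8),
        series_length=60, seed=11,
    )
    cov_healthy = rs.build_class_covariance(spec, 0)
    cov_patient = rs.build_class_covariance(spec, 1)
    rng = np.random.default_rng(11)
    mats, ids, groups = [], [], []
    for label, cov, n in (("healthy", cov_healthy, 8),
                          ("MCS", cov_patient, 6),
                          ("UWS", cov_patient, 6)):
        for k in range(n):
            mats.append(rs.simulate_subject(cov, spec.series_length, rng))
            ids.append(f"{label}_{k}")
            groups.append(label)
    return rs.ConnectivityDataset(
        matrices=np.stack(mats), subject_ids=ids, groups=groups,
    )


@pytest.fixture()
def random_labeled_dataset():
    """Unstructured labeled dataset (no planted signal), 3 groups."""
    rng = np.random.default_rng(0)
    n = {"healthy": 10, "MCS": 8, "UWS": 7}
    mats, ids, groups = [], [], []
    for g, k in n.items():
        for i in range(k):
            a = rng.normal(size=(5, 5))
            m = (a + a.T) / 2
            np.fill_diagonal(m, 0.0)
            mats.append(m)
            ids.append(f"{g}{i}")
            groups.append(g)
    return rs.ConnectivityDataset(
        matrices=np.stack(mats), subject_ids=ids, groups=groups,
    )
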