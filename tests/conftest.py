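import numpy as np
import pytest

from petconn.cloud import LabeledPointCloud
from petconn.connectome.build import Connectome, build_cohort_connectomes
from petconn.phantom import default_cohort_spec, generate_cohort
from petconn.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def make_roi_connectome(c_matrix, roi_names, subject_id=""):
    """ROI-level Connectome wrapper around an arbitrary symmetric C matrix."""
    c = np.asarray(c_matrix, dtype=float)
    n = len(roi_names)
    return Connectome(
        tuple(roi_names), np.zeros((n, n)), np.eye(n), 0.0, c, level="roi", subject_id=subject_id
    )


def single_organ_cloud(values, rng=None, label="liver", subject_id="s"):
    """One-organ cloud with random (but seeded) positions."""
    values = np.asarray(values, dtype=float)
    rng = rng or np.random.default_rng(0)
    pos = rng.uniform(0, 100, size=(len(values), 3))
    return LabeledPointCloud(pos, values, np.full(len(values), label, dtype=object), subject_id)


@pytest.fixture(scope="session")
def reference_cohort(schema):
    """Reference phantom cohort (20 controls / 10 patients) + ROI connectomes.

    Session-scoped because connectome construction dominates test runtime;
    every consumer treats the returned objects as read-only.
    """
    cohort = generate_cohort(default_cohort_spec(n_controls=20, n_patients=10, seed=11))
    conns = build_cohort_connectomes(
        [c for c, _ in cohort], schema, alpha=1.0, seed=211, level="roi"
    )
    groups = [g for _, g in cohort]
    return cohort, conns, groups
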