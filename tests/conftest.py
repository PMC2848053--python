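import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qemgdx import (
    MUPTRecord,
    MuscleStudy,
    StudyCollection,
    default_feature_set,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def feature_set():
    return default_feature_set()


def make_study(study_id, true_class, matrix):
    """Build a MuscleStudy from a (n, d) array of transformed features."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    records = [MUPTRecord(study_id, true_class, row) for row in matrix]
    return MuscleStudy(study_id, true_class, records)


@pytest.fixture
def toy_collection():
    """Two well-separated 15-feature classes, 4 studies of 5 MUPTs each."""
    rng = np.random.default_rng(7)
    studies = []
    for i in range(2):
        studies.append(
            make_study(f"N{i}", "Normative", rng.normal(0.0, 1.0, size=(5, 15)))
        )
        studies.append(
            make_study(f"P{i}", "NSAP", rng.normal(8.0, 1.0, size=(5, 15)))
        )
    return StudyCollection(studies)
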