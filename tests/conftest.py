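import numpy as np
import pytest

from mirwoi.data import AssayRole, CqProfileSet, SampleMetadata
from mirwoi.matrix import FeatureMatrix


@pytest.fixture
def toy_profiles() -> CqProfileSet:
    """3 targets + 1 endogenous + 1 spike-in, 4 profiles from 2 patients."""
    assay_ids = ["miR-a", "miR-b", "miR-c", "RNU6B", "spike-1"]
    roles = {
        "miR-a": AssayRole.TARGET,
        "miR-b": AssayRole.TARGET,
        "miR-c": AssayRole.TARGET,
        "RNU6B": AssayRole.ENDOGENOUS_CONTROL,
        "spike-1": AssayRole.SPIKE_IN,
    }
    profile_ids = ["P1-r1", "P1-r2", "P2-r1", "P2-r2"]
    patient_of_profile = {p: p.rsplit("-r", 1)[0] for p in profile_ids}
    cq = np.array([
        [24.0, 26.0, 30.0, 31.0],
        [24.0, np.nan, 22.0, 22.5],
        [np.nan, np.nan, 28.0, 29.0],
        [18.0, 18.1, 18.2, 17.9],
        [22.0, 22.1, 21.9, 22.0],
    ])
    return CqProfileSet(assay_ids=assay_ids, roles=roles, profile_ids=profile_ids,
                        patient_of_profile=patient_of_profile, cq=cq)


@pytest.fixture
def toy_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("P1", label=120, implantation_success=True, n_pif=0),
        SampleMetadata("P2", label=108, implantation_success=True, n_pif=2),
    ]


def make_matrix(values, stage="raw_mean", feature_ids=None, patient_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureMatrix(
        patient_ids=patient_ids or [f"P{i + 1}" for i in range(n)],
        feature_ids=feature_ids or [f"miR-{j + 1}" for j in range(p)],
        values=values,
        stage=stage,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
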