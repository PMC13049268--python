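import numpy as np
import pytest

from grapetx.constants import REF_SENS_HZ_PER_V
from grapetx.fields import CohortConfig, SubjectFieldMap, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort_config():
    # coarse 10 mm grid keeps Bloch tables small (~450 brain voxels/subject)
    return CohortConfig(n_subjects=3, shape=(12, 10, 10), spacing_mm=10.0,
                        master_seed=77)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return generate_cohort(tiny_cohort_config)


@pytest.fixture(scope="session")
def tiny_subject(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture(scope="session")
def homogeneous_subject():
    """Uniform-sensitivity, on-resonance phantom (8 channels)."""
    shape = (5, 5, 5)
    sens = np.full((8,) + shape, REF_SENS_HZ_PER_V / 8, dtype=complex)
    mask = np.zeros(shape, dtype=bool)
    mask[1:4, 1:4, 1:4] = True
    return SubjectFieldMap(
        sens=sens * mask,
        db0=np.zeros(shape),
        mask=mask,
        spacing_mm=5.0,
        origin_mm=np.array([-10.0, -10.0, -10.0]),
        subject_id="phantom",
    )


@pytest.fixture(scope="session")
def four_voxel_subject(tiny_subject):
    import dataclasses

    # carve a 4-voxel subject out of the synthetic head
    idx = np.transpose(np.nonzero(tiny_subject.mask))[:4]
    mask = np.zeros_like(tiny_subject.mask)
    mask[tuple(idx.T)] = True
    return dataclasses.replace(tiny_subject, mask=mask)


@pytest.fixture(scope="session")
def unit_sens_row():
    """One voxel whose combined CP-mode sensitivity is the reference value."""
    return np.full(8, REF_SENS_HZ_PER_V / 8, dtype=complex)
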