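import numpy as np
import pandas as pd
import pytest

from tmtvkit.pet_suv import AcquisitionMeta, SuvVolume
from tmtvkit.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def meta_one_halflife():
    """350 MBq injected, scanned exactly one half-life later, 70 kg."""
    return AcquisitionMeta(
        injected_dose_mbq=350.0,
        injection_time="2020-01-01T09:00:00",
        scan_time="2020-01-01T10:49:46.200000",
        body_weight_kg=70.0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the default study conditions (n=689)."""
    return generate_cohort(CohortSpec(n=689, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for distributional checks (n=10000)."""
    return generate_cohort(CohortSpec(n=10_000, seed=7))


@pytest.fixture()
def tiny_survival():
    """Six subjects, distinct times, one binary covariate; hand-checkable."""
    return pd.DataFrame({
        "pfs_months": [2.0, 4.0, 5.0, 7.0, 9.0, 12.0],
        "pfs_event": [1, 1, 0, 1, 1, 0],
        "group": [1, 0, 1, 1, 0, 0],
    })


def make_suv(voxels, spacing=(4.0, 4.0, 4.0)):
    return SuvVolume(np.asarray(voxels, dtype=float), spacing)
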