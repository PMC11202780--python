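import numpy as np
import pytest

from lungsurv.fixtures import (
    FixtureSpec,
    make_cohort,
    make_patients,
    to_ct_series,
    to_structure_set,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Four clean synthetic patients, in memory."""
    spec = FixtureSpec(n_patients=4, seed=11)
    patients, manifest = make_patients(spec)
    return patients, manifest


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Three synthetic patients written as DICOM files with clinical CSV."""
    root = tmp_path_factory.mktemp("cohort")
    spec = FixtureSpec(n_patients=3, seed=3)
    out, manifest = make_cohort(spec, root)
    return out, manifest


@pytest.fixture()
def patient_pipeline(small_cohort):
    """(series, structure set, manifest entry) of the first clean patient."""
    patients, manifest = small_cohort
    fx = patients[0]
    return to_ct_series(fx), to_structure_set(fx), manifest.patients[fx.patient_id]


def disk_mask(shape, center, radius):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


@pytest.fixture(scope="session")
def make_disk_mask():
    return disk_mask
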