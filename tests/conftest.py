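import numpy as np
import pandas as pd
import pytest

from voxelhub.io import BoldImage, CohortTable, MaskImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)


def make_affine(vox=3.0, origin=(0.0, 0.0, 0.0)):
    a = np.diag([vox, vox, vox, 1.0])
    a[:3, 3] = origin
    return a


@pytest.fixture
def affine3mm():
    return make_affine(3.0)


@pytest.fixture
def box_mask(affine3mm):
    """12^3 grid with an 8^3 interior box mask (512 voxels)."""
    data = np.zeros((12, 12, 12), dtype=bool)
    data[2:10, 2:10, 2:10] = True
    return MaskImage(data, affine3mm)


@pytest.fixture
def bold_factory(affine3mm):
    def make(shape=(12, 12, 12), t=60, tr=2.0, rng=None, scale=1.0):
        rng = rng or np.random.default_rng(0)
        return BoldImage(rng.standard_normal((*shape, t)) * scale, affine3mm, tr)

    return make


@pytest.fixture
def small_cohort_df():
    n_pat, n_con = 10, 10
    rng = np.random.default_rng(7)
    rows = []
    for i in range(n_pat + n_con):
        grp = "patient" if i < n_pat else "control"
        rows.append(
            {
                "subject_id": f"s{i:02d}",
                "group": grp,
                "age": float(rng.normal(62, 6)),
                "sex": "M" if rng.uniform() < 0.7 else "F",
                "education": float(rng.normal(6, 3)),
                "fev1_pct": float(rng.normal(46 if grp == "patient" else 97, 18)),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def small_cohort(small_cohort_df):
    return CohortTable(small_cohort_df)
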