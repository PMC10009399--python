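import numpy as np
import pandas as pd
import pytest

from roiconn.atlas import Atlas, GridSpec, RoiSpec, block_index, bundled_atlas
from roiconn.connectivity import METRIC_NAMES


@pytest.fixture(scope="session")
def atlas():
    return bundled_atlas()


@pytest.fixture(scope="session")
def toy_atlas():
    """Two well-separated 5-mm sphere ROIs per network (6 ROIs total)."""
    coords = {
        ("conA", "CON"): (0, 0, 0), ("conB", "CON"): (30, 0, 0),
        ("dmnA", "DMN"): (0, 30, 0), ("dmnB", "DMN"): (30, 30, 0),
        ("ostA", "OST"): (0, 0, 30), ("ostB", "OST"): (30, 0, 30),
    }
    rois = tuple(
        RoiSpec(label=l, network=n, center_mni=np.array(c, dtype=float))
        for (l, n), c in coords.items()
    )
    return Atlas(rois)


@pytest.fixture(scope="session")
def toy_pairs(toy_atlas):
    return block_index(toy_atlas)


@pytest.fixture
def grid2mm():
    """2-mm isotropic grid whose voxel centers include integer-even MNI points."""
    return GridSpec.isotropic((40, 40, 40), 2.0, (-20.0, -20.0, -20.0))


def make_cohort_frame(rng, n_per_group=(10, 10, 10), covariate_free=False):
    """Small random cohort table with the six metrics, for statistics tests."""
    rows = []
    for g, n in zip(("OCD", "AC", "HC"), n_per_group):
        for i in range(n):
            row = {
                "subject_id": f"{g}{i}",
                "group": g,
                "age": 0.0 if covariate_free else float(rng.uniform(8, 21)),
                "mean_fd": 0.0 if covariate_free else float(rng.lognormal(-1.9, 0.4)),
            }
            for m in METRIC_NAMES:
                row[m] = float(rng.normal(0.4, 0.1))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def cohort_frame():
    return make_cohort_frame(np.random.default_rng(7))
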