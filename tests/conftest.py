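import numpy as np
import pytest

from ldgraph.cohort import (CohortConfig, DeficitParams, LesionMask,
                            PatientRecord, SubstrateSpec, make_ground_truth,
                            sample_lesion_cohort, simulate_cohort_deficits)
from ldgraph.grid import make_grid


@pytest.fixture(scope="session")
def small_grid():
    return make_grid((10, 10, 10))


@pytest.fixture(scope="session")
def stroke_cohort(small_grid):
    """Stroke-only cohort on a small grid, four territories."""
    cfg = CohortConfig(n_patients=40, aetiology_mix=1.0, n_territories=4,
                       branch_size=(15, 35), seed=11)
    masks, records = sample_lesion_cohort(cfg, small_grid)
    return cfg, masks, records


@pytest.fixture(scope="session")
def scored_cohort(small_grid):
    """Mixed cohort with a planted substrate and simulated deficits."""
    cfg = CohortConfig(n_patients=30, aetiology_mix=0.6, n_territories=3,
                       substrate_spec=SubstrateSpec(1, (2.5,), territory=0),
                       deficit_params=DeficitParams(sigma=1.0),
                       branch_size=(20, 40), seed=5)
    masks, records = sample_lesion_cohort(cfg, small_grid)
    gt = make_ground_truth(cfg, small_grid, seed=6)
    records = simulate_cohort_deficits(masks, records, gt,
                                       cfg.deficit_params, seed=7)
    return cfg, masks, records, gt


def mask_from_voxels(grid, voxels, pid="p0"):
    data = np.zeros(grid.shape, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    return LesionMask(pid, data, grid)


def record(pid="p0", score=6.0, nart=100.0, age=50.0, aet="stroke"):
    return PatientRecord(pid, score, nart, age, aet)
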