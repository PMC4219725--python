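import numpy as np
import pytest

from petquant import (BinaryMask, PhantomSpec, RunConfig, Volume3D,
                      make_cohort, make_phantom_subject, run_voi_analysis,
                      subjects_from_cohort)


def make_volume(data, spacing=(1.0, 1.0, 1.0), units="suv"):
    """Volume on an axis-aligned grid with the world origin at index 0."""
    data = np.asarray(data, dtype=np.float64)
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    return Volume3D(data, A, units)


def make_mask(data, spacing=(1.0, 1.0, 1.0), name="roi"):
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    return BinaryMask(np.asarray(data, dtype=np.uint8), A, "mask",
                      region_name=name)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def coarse_cohort():
    """One 6-vs-6 phantom cohort on the reduced 32^3 grid."""
    return make_cohort(PhantomSpec.coarse(seed=11))


@pytest.fixture(scope="session")
def coarse_analyses(coarse_cohort):
    cfg = RunConfig(stats_n_perm=200, stats_seed=5)
    tidy, report, analyses = run_voi_analysis(
        subjects_from_cohort(coarse_cohort), cfg)
    return {"tidy": tidy, "report": report, "analyses": analyses, "config": cfg}


@pytest.fixture(scope="session")
def default_hv_subject():
    """One healthy-volunteer phantom at the default 2-mm resolution."""
    return make_phantom_subject(PhantomSpec(seed=4), 0, "HV")
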