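import numpy as np
import pytest

from persipet import PhantomSpec, build_atlas, generate_cohort, generate_subject
from persipet.phantom import build_geometry


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def geometry(spec):
    return build_geometry(spec)


@pytest.fixture(scope="session")
def atlas(spec, geometry):
    return build_atlas(spec, geometry)


@pytest.fixture(scope="session")
def ad_subject(spec, geometry):
    """One fixed AD phantom: (pet, gm, wm, csf, truth)."""
    return generate_subject(spec, "AD", seed=42, subject_id="AD_fix", geometry=geometry)


@pytest.fixture(scope="session")
def hc_subject(spec, geometry):
    """One fixed healthy-control phantom (no spill-in contamination)."""
    return generate_subject(spec, "HC", seed=11, subject_id="HC_fix", geometry=geometry)


@pytest.fixture(scope="session")
def toy_cohort_dir(tmp_path_factory, spec):
    """A small 3 HC / 3 AD cohort materialized on disk."""
    out = tmp_path_factory.mktemp("toy_cohort")
    manifest, atlas_, truths = generate_cohort(
        spec, {"HC": 3, "AD": 3}, master_seed=123, out_dir=out
    )
    return out, manifest, atlas_, truths


def uniform_volume(shape=(12, 12, 12), value=1.0, voxel=2.0):
    from persipet import Volume3D

    return Volume3D(np.full(shape, value, dtype=float), np.diag([voxel] * 3 + [1.0]))
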