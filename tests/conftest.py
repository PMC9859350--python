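import numpy as np
import pytest

from gonogo_bpi import ContrastMap, GroupSample, MaskVolume, mni_like_affine
from gonogo_bpi.synthetic import Region, SceneSpec, generate_event_schedule


@pytest.fixture(scope="session")
def small_schedule():
    """A compact schedule shared by timing/behaviour tests."""
    return generate_event_schedule(seed=7, n_per_type=8, n_null=4)


@pytest.fixture(scope="session")
def default_schedule():
    """The full study schedule: 100 trials per type + 100 null events."""
    return generate_event_schedule(seed=1)


@pytest.fixture
def tiny_scene():
    """A 6x6x6 all-brain scene for fast BOLD forward models."""
    return SceneSpec(
        grid_shape=(6, 6, 6), smooth_fwhm=0.0, brain_fraction=2.0,
        n_subjects_hc=2, n_subjects_ocd=2,
    )


def make_group_sample(arrays, affine=None, group_label="g", mask=None):
    """Wrap a (n, x, y, z) array as a GroupSample on a trivial grid."""
    arrays = np.asarray(arrays, dtype=float)
    if affine is None:
        affine = mni_like_affine(arrays.shape[1:])
    if mask is None:
        mask = MaskVolume(np.ones(arrays.shape[1:], bool), affine)
    maps = [
        ContrastMap(arrays[i], affine, subject_id=f"{group_label}{i:02d}")
        for i in range(arrays.shape[0])
    ]
    return GroupSample(maps=maps, mask=mask, group_label=group_label)


@pytest.fixture
def group_sample_factory():
    return make_group_sample


@pytest.fixture
def one_sphere_scene():
    """One positive-effect sphere, no smoothing, for recovery checks."""
    return SceneSpec(
        grid_shape=(14, 14, 14), smooth_fwhm=0.0, brain_fraction=2.0,
        between_subject_sd=1.0, n_subjects_hc=34, n_subjects_ocd=2,
        effect_regions=[Region(center=(7, 7, 7), radius=4, effect_size=1.5)],
    )
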