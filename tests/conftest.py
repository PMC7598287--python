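import dataclasses

import numpy as np
import pytest

from cystex import LesionVolume, PhantomSpec, generate_cohort, generate_lesion
from cystex.imaging_io import NEGATIVE, POSITIVE


def lesion_from_slices(images, masks=None, lesion_id="lesion", label=None):
    """Build a LesionVolume from a list of 2D intensity arrays."""
    vol = np.stack([np.asarray(a) for a in images], axis=0)
    if masks is None:
        mask = np.ones_like(vol, dtype=bool)
    else:
        mask = np.stack([np.asarray(m, dtype=bool) for m in masks], axis=0)
    return LesionVolume(
        intensities=vol, mask=mask, lesion_id=lesion_id, class_label=label
    )


#: small phantom geometry used throughout the tests to keep runtimes low
SMALL_SPEC = PhantomSpec(
    grid_shape=(10, 28, 28),
    lesion_radii=(3.2, 9.0, 9.0),
    n_dark_spots=2,
    spot_radius=1.5,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separated two-class cohort (8 heterogeneous vs 6 smooth)."""
    return generate_cohort((8, 6), template=SMALL_SPEC, seed=11)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from cystex import extract_all

    return extract_all(small_cohort)


def null_cohort(n_pos, n_neg, seed, spec=None):
    """Lesions drawn from ONE distribution with arbitrary class labels.

    Used for type-I-error experiments: labels carry no signal.
    """
    if spec is None:
        spec = dataclasses.replace(
            SMALL_SPEC,
            grid_shape=(8, 24, 24),
            lesion_radii=(2.5, 8.0, 8.0),
            contrast_sd=400.0,
            correlation_length=3.0,
            n_dark_spots=0,
            spot_depth=0.0,
            noise_sd=60.0,
        )
    children = np.random.SeedSequence(seed).spawn(n_pos + n_neg)
    lesions = []
    for i, child in enumerate(children):
        sp = dataclasses.replace(
            spec, seed=int(child.generate_state(1)[0] & 0x7FFFFFFF)
        )
        les = generate_lesion(sp, lesion_id=f"null-{i:03d}")
        les.class_label = POSITIVE if i < n_pos else NEGATIVE
        lesions.append(les)
    return lesions
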