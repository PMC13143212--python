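import numpy as np
import pytest

import spinemetrics as sm
from spinemetrics.images import BinaryMask


@pytest.fixture
def straight_tube_mask():
    """7-px-wide horizontal ribbon spanning 100 columns at 0.1 µm/px."""
    m = np.zeros((40, 100), dtype=bool)
    m[17:24, :] = True
    return BinaryMask(m, 0.1)


@pytest.fixture
def one_spine_spec():
    """Straight channel with a single mushroom spine, noiseless."""
    return sm.DendriteSpec(
        image_shape=(96, 128),
        centerline_control_points=((48.0, 5.0), (48.0, 122.0)),
        dendrite_diameter_um=0.7,
        spines=(sm.SpineSpec(anchor=(48.0, 64.0), side=-1,
                             neck_length_um=0.5, neck_width_um=0.3,
                             head_diameter_um=0.6),),
        psf_sigma_px=0.0, noise_sd=0.0,
    )


@pytest.fixture
def mushroom_island():
    """Hand-drawn mushroom spine island: 6-px head disk on a 2-px neck."""
    m = np.zeros((24, 16), dtype=bool)
    yy, xx = np.mgrid[0:24, 0:16]
    m |= (yy - 7) ** 2 + (xx - 8) ** 2 <= 3.0**2        # head
    m[10:18, 7:9] = True                                # neck, 2 px wide
    return BinaryMask(m, 0.1)


def segment_noiseless(spec, min_head_area=10):
    """Generate a noiseless image from ``spec`` and segment it."""
    image, truth = sm.generate_dendrite_image(spec)
    threshold = spec.background_level + spec.signal_level / 2
    from spinemetrics.benchmark import clean_mask
    mask = clean_mask(image, threshold, 50)
    seg = sm.extract_spines_by_peeling(mask, 2, min_head_area)
    return mask, seg, truth
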