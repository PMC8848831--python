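import numpy as np
import pytest

from fcmgwo import (
    FcmConfig,
    GwoConfig,
    PreprocessSettings,
    SegmentationConfig,
    SyntheticSpec,
    generate_cell_image,
)

NO_PREPROCESS = PreprocessSettings(resize_to=None, grayscale=True,
                                   median_size=None, closing_radius=None)


@pytest.fixture
def small_spec():
    """Down-scaled synthetic image: same intensity structure, fast to segment."""
    return SyntheticSpec(width=120, height=90, n_cells=4,
                         nucleus_radius_range=(4, 6), cytoplasm_radius_range=(9, 12),
                         seed=7)


@pytest.fixture
def small_image(small_spec):
    return generate_cell_image(small_spec)


def seg_config(method="fcmgwo", seed=0, preprocess=NO_PREPROCESS, **kw):
    return SegmentationConfig(
        fcm=FcmConfig(seed=seed, **kw.get("fcm", {})),
        gwo=GwoConfig(seed=seed, **kw.get("gwo", {})),
        preprocess=preprocess,
        method=method,
    )
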