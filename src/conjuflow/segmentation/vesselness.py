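"""Classical multiscale vesselness segmentation (no training required).

A Hessian-eigenvalue (Frangi) filter enhances dark curvilinear structures
over a range of scales matched to the expected vessel radii; Otsu
thresholding of the response plus small-object removal yields a binary
mask.  This is the pipeline's classical baseline: it lets every downstream
stage run without a trained network, at lower accuracy on hard images.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import frangi, threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = ["vesselness_segment"]


def vesselness_segment(
    image: np.ndarray,
    sigmas=(1.0, 2.0, 3.0, 4.0, 5.0),
    min_size: int = 64,
) -> np.ndarray:
    """Binary vessel mask from multiscale Hessian vesselness.

    ``sigmas`` should bracket the expected vessel radii in pixels of the
    (already preprocessed) image; dark vessels on a bright background are
    assumed.
    """
    img = np.asarray(image, dtype=np.float64)
    v = frangi(img, sigmas=sigmas, black_ridges=True)
    if v.max() <= 0:
        return np.zeros_like(img, dtype=bool)
    thr = threshold_otsu(v)
    mask = v > thr
    return remove_small_objects(mask, max_size=min_size - 1)
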