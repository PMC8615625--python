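"""DAPI nucleus segmentation helper.

A standard watershed pipeline (Gaussian smoothing, Otsu threshold, hole
filling, distance-transform peaks, watershed) for when no label mask is
supplied alongside the images.  Quantification accepts any label image, so
labs with their own segmentation can bypass this entirely.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, segmentation, feature

from .io import PlaneImage

__all__ = ["segment_nuclei"]


def segment_nuclei(dapi: PlaneImage, min_area_um2: float = 10.0,
                   smooth_sigma_px: float = 2.0,
                   min_peak_distance_um: float = 4.0) -> np.ndarray:
    """Segment nuclei from a DAPI plane into an int32 label image (0 = bg)."""
    img = ndimage.gaussian_filter(dapi.pixels.astype(float), smooth_sigma_px)
    thr = filters.threshold_otsu(img)
    fg = img > thr
    fg = ndimage.binary_fill_holes(fg)
    min_px = max(int(min_area_um2 / dapi.pixel_size ** 2), 1)
    fg = morphology.remove_small_objects(fg, max_size=min_px - 1)
    if not fg.any():
        return np.zeros(dapi.pixels.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    min_dist_px = max(int(min_peak_distance_um / dapi.pixel_size), 1)
    peaks = feature.peak_local_max(dist, min_distance=min_dist_px, labels=fg,
                                   exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        lab, _ = ndimage.label(fg)
        return lab.astype(np.int32)
    return segmentation.watershed(-dist, markers, mask=fg).astype(np.int32)
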