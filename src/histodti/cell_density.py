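"""Automated counting of dark-stained somata and cell density (CD) per ROI.

Classical threshold -> components -> watershed pipeline:

1. invert (stain is dark on a bright background),
2. background flattening (subtract a heavily smoothed copy),
3. global threshold — explicit 8-bit level or Otsu's method on the ROI,
4. binary opening to shed single-pixel noise,
5. connected components with an area filter in um^2,
6. optional distance-transform watershed split of touching somata.

CD is reported in cells/mm^2 of ROI area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk as disk_footprint
from skimage.segmentation import watershed

from .images import Micrograph

__all__ = ["CellCountParams", "CellCountResult", "count_cells"]


@dataclass(frozen=True)
class CellCountParams:
    threshold: int | None = None       # 8-bit level on the flattened inverted image; None = Otsu
    min_area_um2: float = 7.0          # below: sub-nucleus debris
    max_area_um2: float = 700.0        # above: not a single soma
    split_touching: bool = True
    flatten_sigma_um: float = 20.0     # background smoothing scale; 0 disables
    min_contrast: float = 8.0          # 8-bit levels; below: image treated as blank

    def __post_init__(self) -> None:
        if self.threshold is not None and not (0 <= self.threshold <= 255):
            raise ValueError("threshold must be in [0, 255]")
        if not (0 < self.min_area_um2 <= self.max_area_um2):
            raise ValueError("need 0 < min_area_um2 <= max_area_um2")


@dataclass
class CellCountResult:
    count: int
    roi_area_um2: float
    cd_per_mm2: float
    centers: np.ndarray  # (n, 2) row/col centroids, inside the ROI
    labels: np.ndarray   # labelled cell image (0 = background)


def count_cells(img: Micrograph, roi: np.ndarray,
                params: CellCountParams = CellCountParams()) -> CellCountResult:
    """Count dark somata within ``roi`` and convert to cells/mm^2."""
    roi = np.asarray(roi).astype(bool)
    if roi.shape != img.shape:
        raise ValueError("ROI shape must match the image")
    if not roi.any():
        raise ValueError("empty ROI")

    inverted = 255.0 - img.pixels.astype(float)
    if params.flatten_sigma_um > 0:
        sigma_px = params.flatten_sigma_um / img.pixel_size
        background = ndi.gaussian_filter(inverted, sigma_px, mode="reflect")
        flattened = np.clip(inverted - background, 0.0, None)
    else:
        flattened = inverted

    roi_vals = flattened[roi]
    if params.threshold is not None:
        level = float(params.threshold)
    else:
        if roi_vals.max() - roi_vals.min() < params.min_contrast:
            # featureless ROI: Otsu would split noise into phantom "cells"
            return _empty_result(img, roi)
        level = float(threshold_otsu(roi_vals))

    # segment over the full frame so cells straddling the ROI boundary keep
    # their shape; ROI membership is decided by the centroid below
    binary = flattened > level
    binary = ndi.binary_opening(binary, structure=disk_footprint(1))
    if not binary.any():
        return _empty_result(img, roi)

    min_area_px = params.min_area_um2 / img.pixel_area_um2()
    max_area_px = params.max_area_um2 / img.pixel_area_um2()

    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        min_radius_px = max(1, int(round(np.sqrt(min_area_px / np.pi))))
        peaks = peak_local_max(distance, min_distance=min_radius_px,
                               labels=binary, exclude_border=False)
        markers = np.zeros(binary.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndi.label(binary, structure=np.ones((3, 3)))

    # area filter and ROI-restricted centroids
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(areas >= min_area_px) & (areas <= max_area_px)]
    out_labels = np.where(np.isin(labels, keep), labels, 0)
    centers = []
    final_ids = []
    for i, (cy, cx) in zip(keep, ndi.center_of_mass(out_labels > 0, out_labels, keep)):
        if roi[int(round(cy)), int(round(cx))]:
            centers.append((cy, cx))
            final_ids.append(i)
    out_labels = np.where(np.isin(out_labels, final_ids), out_labels, 0)

    roi_area_um2 = float(roi.sum()) * img.pixel_area_um2()
    count = len(centers)
    return CellCountResult(
        count=count,
        roi_area_um2=roi_area_um2,
        cd_per_mm2=count / (roi_area_um2 / 1e6),
        centers=np.array(centers, dtype=float).reshape(-1, 2),
        labels=out_labels,
    )


def _empty_result(img: Micrograph, roi: np.ndarray) -> CellCountResult:
    roi_area_um2 = float(roi.sum()) * img.pixel_area_um2()
    return CellCountResult(count=0, roi_area_um2=roi_area_um2, cd_per_mm2=0.0,
                           centers=np.empty((0, 2)), labels=np.zeros(img.shape, dtype=int))
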