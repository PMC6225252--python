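"""Background removal and flower labeling.

The flower/background contrast is greatest near 1119 nm, so the scene
is binarized on the image plane at that band (reflectance strictly
above a threshold, default 0.122), small noise blobs are discarded with
a connected-component area filter (components with area strictly below
40 px removed; a 40-px component is kept), and the surviving components
are labeled one flower each, in raster-scan order of their first pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .hypercube import Hypercube, nearest_band

__all__ = [
    "SegmentationParams",
    "SampleRegion",
    "binarize",
    "remove_small_objects",
    "label_flowers",
    "segment",
    "regions_table",
]

_CONNECTIVITY = {4: 1, 8: 2}  # pixel connectivity -> skimage connectivity


@dataclass(frozen=True)
class SegmentationParams:
    band_nm: float = 1119.0
    reflectance_threshold: float = 0.122
    min_area_px: int = 40
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.reflectance_threshold < 1.0:
            raise ValueError("reflectance_threshold must lie in (0, 1)")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SampleRegion:
    """One labeled flower: pixel set and bookkeeping."""

    label: int
    coords: np.ndarray        # (n_pixels, 2) array of (row, col)
    area_px: int
    sample_id: int | None = None

    def mask(self, shape: tuple) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


def binarize(cube: Hypercube, params: SegmentationParams) -> np.ndarray:
    """Boolean foreground mask: reflectance at the segmentation band
    strictly above the threshold, on valid pixels only."""
    if cube.kind != "reflectance":
        raise ValueError("binarize expects a reflectance cube")
    plane = cube.band(nearest_band(cube.axis, params.band_nm))
    return (plane > params.reflectance_threshold) & cube.valid_mask


def remove_small_objects(mask: np.ndarray, min_area_px: int,
                         connectivity: int = 8) -> np.ndarray:
    """Drop connected components with area strictly below ``min_area_px``.

    A component of exactly ``min_area_px`` pixels is kept (the filter
    removes strictly smaller blobs only).
    """
    mask = np.asarray(mask, bool)
    if min_area_px <= 1 or not mask.any():
        return mask.copy()
    labels = measure.label(mask, connectivity=_CONNECTIVITY[connectivity])
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labels]


def label_flowers(mask: np.ndarray,
                  connectivity: int = 8) -> list[SampleRegion]:
    """One region per connected component, labeled 1..K in raster-scan
    order of each component's first pixel."""
    labels = measure.label(np.asarray(mask, bool),
                           connectivity=_CONNECTIVITY[connectivity])
    regions = []
    for rp in measure.regionprops(labels):
        regions.append(SampleRegion(0, rp.coords.copy(), int(rp.area)))
    # Re-label by raster order of the first (topmost-leftmost) pixel.
    regions.sort(key=lambda r: (int(r.coords[0, 0]), int(r.coords[0, 1])))
    for i, r in enumerate(regions, start=1):
        r.label = i
    return regions


def segment(cube: Hypercube,
            params: SegmentationParams | None = None) -> list[SampleRegion]:
    """Binarize, area-filter, and label in one call."""
    if params is None:
        params = SegmentationParams()
    mask = binarize(cube, params)
    mask = remove_small_objects(mask, params.min_area_px, params.connectivity)
    return label_flowers(mask, params.connectivity)


def regions_table(regions: list[SampleRegion]) -> pd.DataFrame:
    rows = [{
        "label": r.label,
        "area_px": r.area_px,
        "centroid_y": float(r.coords[:, 0].mean()),
        "centroid_x": float(r.coords[:, 1].mean()),
        "sample_id": r.sample_id,
    } for r in regions]
    return pd.DataFrame(rows)
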