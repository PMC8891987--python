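"""Focal-adhesion quantification from two-channel immunofluorescence images.

The processing chain mirrors the standard adhesion-scoring workflow:
rolling-ball background subtraction (50 px radius by default) on the
marker channel (phospho-paxillin or phospho-FAK), global auto-threshold,
particle labelling with a minimum adhesion size of 4.14 µm² to reject
background staining, and per-cell normalization — the cell footprint is
segmented from the actin channel and adhesion density is the adhesion
count divided by the cell area. An adhesion is assigned to the cell iff
its centroid lies inside the actin-derived mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, restoration

from .errors import DegenerateDataError, ThresholdError
from .images import BinaryMask, IntensityImage, LabeledMask
from .morphometry import _THRESHOLDS

__all__ = [
    "FAStats",
    "subtract_background",
    "segment_fas",
    "fa_statistics",
    "analyze_fa_image_set",
    "DEFAULT_MIN_FA_AREA_UM2",
    "DEFAULT_BACKGROUND_RADIUS_PX",
]

#: Minimum adhesion size (µm²) below which puncta are treated as background.
DEFAULT_MIN_FA_AREA_UM2 = 4.14
#: Rolling-ball radius (px) for background subtraction.
DEFAULT_BACKGROUND_RADIUS_PX = 50


@dataclass
class FAStats:
    """Per-cell focal-adhesion statistics."""

    fa_areas_um2: np.ndarray
    fa_count: int
    cell_area_um2: float
    density_per_um2: float

    def __post_init__(self) -> None:
        self.fa_areas_um2 = np.asarray(self.fa_areas_um2, dtype=float)
        if self.cell_area_um2 <= 0:
            raise ValueError("cell area must be positive")

    @property
    def mean_fa_area_um2(self) -> float:
        return float(self.fa_areas_um2.mean()) if self.fa_count else float("nan")

    def to_frame(self, cell_id: str = "cell") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": cell_id,
                    "fa_count": self.fa_count,
                    "mean_fa_area_um2": self.mean_fa_area_um2,
                    "cell_area_um2": self.cell_area_um2,
                    "density_per_um2": self.density_per_um2,
                }
            ]
        )


def subtract_background(
    image: IntensityImage,
    radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX,
    method: str = "rolling_ball",
) -> IntensityImage:
    """Remove smooth background by rolling-ball (default) or grayscale opening.

    Both estimate a background surface that cannot follow features smaller
    than the structuring radius, then subtract it; the result is clipped at
    zero. A uniform image maps to all zeros.
    """
    if radius_px < 1:
        raise ValueError("radius must be at least 1 px")
    ny, nx = image.shape
    if radius_px >= ny and radius_px >= nx:
        raise ValueError("radius exceeds both image dimensions")
    if method == "rolling_ball":
        bg = restoration.rolling_ball(image.data, radius=radius_px)
    elif method == "opening":
        footprint = morphology.disk(radius_px)
        bg = ndi.grey_erosion(image.data, footprint=footprint)
        bg = ndi.grey_dilation(bg, footprint=footprint)
    else:
        raise ValueError("method must be 'rolling_ball' or 'opening'")
    return IntensityImage(np.clip(image.data - bg, 0.0, None), image.pixel_size)


def segment_fas(
    marker: IntensityImage,
    min_fa_area_um2: float = DEFAULT_MIN_FA_AREA_UM2,
    threshold_method: str = "otsu",
) -> LabeledMask:
    """Auto-threshold the (background-subtracted) marker channel and label
    adhesions, discarding components smaller than the minimum size."""
    arr = marker.data
    if np.ptp(arr) == 0:
        raise ThresholdError("marker channel has no intensity range")
    try:
        thresh_fn = _THRESHOLDS[threshold_method]
    except KeyError:
        raise ValueError(f"unknown threshold method {threshold_method!r}") from None
    mask = arr > thresh_fn(arr)
    labels = measure.label(mask, connectivity=2)
    min_px = min_fa_area_um2 / marker.pixel_size**2
    if labels.max() > 0 and min_px > 1:
        counts = np.bincount(labels.ravel())
        too_small = np.nonzero(counts < min_px)[0]
        labels[np.isin(labels, too_small[too_small > 0])] = 0
    return LabeledMask(labels, marker.pixel_size)


def segment_cell(actin: IntensityImage, threshold_method: str = "otsu") -> BinaryMask:
    """Cell footprint from the actin channel: threshold, keep the largest
    component, fill holes."""
    arr = actin.data
    if np.ptp(arr) == 0:
        raise ThresholdError("actin channel has no intensity range")
    mask = arr > _THRESHOLDS[threshold_method](arr)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise DegenerateDataError("no cell region found in the actin channel")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    cell = labels == counts.argmax()
    return BinaryMask(ndi.binary_fill_holes(cell), actin.pixel_size)


def fa_statistics(
    fa_mask: LabeledMask,
    actin: IntensityImage,
    threshold_method: str = "otsu",
) -> FAStats:
    """Count adhesions inside the actin-derived cell mask and normalize.

    Density is count / cell area (µm⁻²). Adhesions whose centroid falls
    outside the cell footprint are excluded.
    """
    cell = segment_cell(actin, threshold_method)
    cell_area = cell.area_um2()
    if cell_area <= 0:
        raise DegenerateDataError("zero cell area")
    areas = []
    for rp in measure.regionprops(fa_mask.data):
        cy, cx = rp.centroid
        if cell.data[int(round(cy)), int(round(cx))]:
            areas.append(rp.area * fa_mask.pixel_size**2)
    count = len(areas)
    return FAStats(
        fa_areas_um2=np.asarray(areas),
        fa_count=count,
        cell_area_um2=cell_area,
        density_per_um2=count / cell_area,
    )


def analyze_fa_image_set(
    marker: IntensityImage,
    actin: IntensityImage,
    background_radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX,
    min_fa_area_um2: float = DEFAULT_MIN_FA_AREA_UM2,
    threshold_method: str = "otsu",
) -> FAStats:
    """Full chain: background subtraction → adhesion segmentation → per-cell stats."""
    if marker.shape != actin.shape:
        raise ValueError("marker and actin channels must share a shape")
    cleaned = subtract_background(marker, background_radius_px)
    fa_mask = segment_fas(cleaned, min_fa_area_um2, threshold_method)
    return fa_statistics(fa_mask, actin, threshold_method)


def write_fa_stats(stats: FAStats, path: str | Path, cell_id: str = "cell") -> None:
    stats.to_frame(cell_id).to_csv(path, index=False)
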