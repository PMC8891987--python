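"""Synthetic two-channel focal-adhesion image sets.

Emulates confocal images at the cell–substrate interface: a marker channel
(phospho-paxillin / phospho-FAK) with bright adhesion puncta inside the
cell footprint, and an actin channel that fills the footprint, from which
cell area is measured. Blob areas are drawn from a caller-supplied
distribution so that the minimum-adhesion-size filter can be exercised
against exact per-blob ground truth.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ..errors import PlacementError
from ..images import BinaryMask, IntensityImage

__all__ = ["generate_fa_image", "elliptical_cell_mask", "DEFAULT_MIN_FA_AREA_UM2"]

# Minimum adhesion size used in the quantification workflow (µm²).
DEFAULT_MIN_FA_AREA_UM2 = 4.14


def elliptical_cell_mask(
    shape: tuple[int, int],
    pixel_size: float,
    semi_axes_px: tuple[float, float] | None = None,
    center: tuple[float, float] | None = None,
) -> BinaryMask:
    """An elliptical cell footprint centred in the frame (default 80% fill)."""
    ny, nx = shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    if semi_axes_px is None:
        semi_axes_px = (0.4 * nx, 0.4 * ny)
    yy, xx = np.mgrid[0:ny, 0:nx]
    a, b = semi_axes_px
    inside = ((xx - center[0]) / a) ** 2 + ((yy - center[1]) / b) ** 2 <= 1.0
    return BinaryMask(inside, pixel_size)


def _resolve_areas(
    fa_area_dist: float | Sequence[float] | Callable,
    n_fas: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if callable(fa_area_dist):
        areas = np.asarray(fa_area_dist(rng, n_fas), dtype=float)
    elif np.isscalar(fa_area_dist):
        areas = np.full(n_fas, float(fa_area_dist))
    else:
        areas = np.asarray(fa_area_dist, dtype=float)
        if len(areas) != n_fas:
            raise ValueError("length of fa_area_dist must equal n_fas")
    if np.any(areas <= 0):
        raise ValueError("adhesion areas must be positive")
    return areas


def generate_fa_image(
    cell_mask: BinaryMask,
    n_fas: int,
    fa_area_dist: float | Sequence[float] | Callable = 6.0,
    pixel_size: float | None = None,
    seed: int | None = None,
    marker_intensity: float = 1000.0,
    actin_intensity: float = 600.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    gap_px: int = 2,
    max_tries: int = 5000,
) -> tuple[IntensityImage, IntensityImage, pd.DataFrame]:
    """Place ``n_fas`` disk-shaped adhesions inside the cell mask.

    ``fa_area_dist`` gives target blob areas in µm²: a scalar, a sequence of
    length ``n_fas``, or a callable ``(rng, n) -> areas``. Blobs are rendered
    by the pixel-center rule; the truth table records both the sampled target
    area and the realized rasterized area (pixel count × pixel area), and
    flags blobs whose realized area falls below the minimum-size cutoff.

    Raises :class:`PlacementError` if the mask cannot host the requested
    number of non-overlapping blobs.
    """
    if pixel_size is None:
        pixel_size = cell_mask.pixel_size
    if n_fas < 0:
        raise ValueError("n_fas must be non-negative")
    rng = np.random.default_rng(seed)
    areas = _resolve_areas(fa_area_dist, n_fas, rng)
    radii_px = np.sqrt(areas / np.pi) / pixel_size

    ny, nx = cell_mask.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    marker = np.full((ny, nx), background, dtype=float)
    occupied = ~cell_mask.data.copy()  # blobs must stay inside the mask
    rows = []
    # largest first: easier packing, deterministic given the seed
    order = np.argsort(radii_px)[::-1]
    for idx in order:
        r = radii_px[idx]
        placed = False
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, ny - r - 2)
            cx = rng.uniform(r + 1, nx - r - 2)
            # blob plus separation gap must avoid mask boundary and other blobs
            footprint = (xx - cx) ** 2 + (yy - cy) ** 2 <= (r + gap_px) ** 2
            if np.any(occupied & footprint):
                continue
            blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            if not blob.any():
                continue
            marker[blob] = marker_intensity
            occupied |= footprint
            realized = int(blob.sum())
            rows.append(
                {
                    "fa_id": int(idx),
                    "center_x_px": cx,
                    "center_y_px": cy,
                    "target_area_um2": areas[idx],
                    "pixel_count": realized,
                    "area_um2": realized * pixel_size**2,
                }
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {n_fas} adhesions of the requested sizes inside the mask"
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "fa_id", "center_x_px", "center_y_px",
            "target_area_um2", "pixel_count", "area_um2",
        ],
    ).sort_values("fa_id").reset_index(drop=True)
    truth["below_min_area"] = truth["area_um2"] < DEFAULT_MIN_FA_AREA_UM2

    actin = np.full((ny, nx), background, dtype=float)
    actin[cell_mask.data] = actin_intensity
    if noise_sd > 0:
        marker = marker + rng.normal(0.0, noise_sd, size=marker.shape)
        actin = actin + rng.normal(0.0, noise_sd, size=actin.shape)
    return (
        IntensityImage(marker, pixel_size),
        IntensityImage(actin, pixel_size),
        truth,
    )
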