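"""Calibrated 2D image containers and TIFF round-trip helpers.

All pixel grids carry a ``pixel_size`` in micrometres per pixel so that
downstream descriptors can report physical units. Images are written as
single-channel 16-bit TIFF with the calibration in a JSON sidecar, because
TIFF resolution tags are too often silently dropped by analysis tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["IntensityImage", "BinaryMask", "LabeledMask", "read_image", "write_image"]


@dataclass
class IntensityImage:
    """A single-channel grayscale image with physical pixel calibration.

    Parameters
    ----------
    data : ndarray
        2D array of intensities (any numeric dtype; stored as float64).
    pixel_size : float
        Edge length of one pixel in µm.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 2:
            raise ValueError("image must be 2D with at least 2x2 pixels")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_area_um2(self) -> float:
        return self.pixel_size**2


@dataclass
class BinaryMask:
    """A boolean foreground mask sharing the calibration of its source image."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def area_um2(self) -> float:
        return float(self.data.sum()) * self.pixel_size**2


@dataclass
class LabeledMask:
    """Connected-component labels: 0 is background, k labels particle k.

    Labels are contiguous 1..K (relabelled on construction if needed).
    """

    data: np.ndarray
    pixel_size: float
    _labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("labeled mask must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        labels = np.unique(arr)
        labels = labels[labels > 0]
        if len(labels) and not np.array_equal(labels, np.arange(1, len(labels) + 1)):
            remap = np.zeros(int(arr.max()) + 1, dtype=np.int32)
            remap[labels] = np.arange(1, len(labels) + 1, dtype=np.int32)
            arr = remap[arr]
        self.data = arr.astype(np.int32)
        self._labels = np.arange(1, len(labels) + 1, dtype=np.int32)

    @property
    def labels(self) -> np.ndarray:
        return self._labels

    @property
    def n_particles(self) -> int:
        return len(self._labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def write_image(path: str | Path, image: IntensityImage) -> None:
    """Write a 16-bit TIFF plus a ``<name>.json`` sidecar with the pixel size.

    Intensities are clipped to the uint16 range; synthetic images are
    generated within it.
    """
    path = Path(path)
    data = np.clip(np.round(image.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_um": image.pixel_size}))


def read_image(path: str | Path, pixel_size: float | None = None) -> IntensityImage:
    """Read a grayscale TIFF/PNG; pixel size from the sidecar unless given."""
    path = Path(path)
    data = tifffile.imread(path) if path.suffix.lower() in {".tif", ".tiff"} else None
    if data is None:
        import imageio.v3 as iio

        data = iio.imread(path)
    if data.ndim == 3:  # collapse trivial channel axes
        data = data.squeeze()
        if data.ndim != 2:
            raise ValueError(f"{path} is not single-channel")
    if pixel_size is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"no pixel size given and no sidecar at {sidecar}")
        pixel_size = float(json.loads(sidecar.read_text())["pixel_size_um"])
    return IntensityImage(np.asarray(data, dtype=float), pixel_size)
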