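"""Core image containers.

All images are 2D (single plane or max-intensity projection) and carry a
physical pixel size in micrometres per pixel. Coordinates are 0-based
(row, col) with the row axis increasing downward, the convention of both
numpy and the microscopy TIFF readers used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass(frozen=True)
class GrayscaleImage:
    """A 2D intensity array with a physical pixel size.

    Parameters
    ----------
    values : 2D float array of finite intensities.
    pixel_size : micrometres per pixel (> 0, isotropic).
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_tiff(cls, path, pixel_size: float) -> "GrayscaleImage":
        arr = tifffile.imread(path)
        if arr.ndim == 3:  # z-stack: collapse to max-intensity projection
            arr = arr.max(axis=0)
        return cls(arr.astype(float), pixel_size)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.values.astype(np.float32))


@dataclass(frozen=True)
class BinaryMask:
    """A boolean mask sharing shape and pixel size with its source image."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {v.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", v.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area_px(self) -> int:
        return int(self.values.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values & other.values, self.pixel_size)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values | other.values, self.pixel_size)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values & ~other.values, self.pixel_size)


@dataclass(frozen=True)
class LabelMap:
    """Integer island labels from connected-component analysis.

    ``labels`` holds 0 for background and consecutive positive integers
    1..n for the islands; ``island_sizes`` maps each label to its pixel
    count.
    """

    labels: np.ndarray
    island_sizes: dict[int, int] = field(default_factory=dict)
    pixel_size: float = 1.0

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label map must be 2D")
        object.__setattr__(self, "labels", lab.astype(np.int64))
        if not self.island_sizes:
            ids, counts = np.unique(lab[lab > 0], return_counts=True)
            object.__setattr__(
                self, "island_sizes", dict(zip(ids.tolist(), counts.tolist()))
            )

    @property
    def n_islands(self) -> int:
        return len(self.island_sizes)

    def mask_of(self, label: int) -> BinaryMask:
        return BinaryMask(self.labels == label, self.pixel_size)

    def foreground(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.pixel_size)
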