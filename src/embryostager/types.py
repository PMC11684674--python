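"""Calibrated in-memory containers shared by the pipelines.

Axis conventions follow the light-sheet recording geometry: ``x`` is the
illumination axis, ``y`` the (sample) rotation axis and ``z`` the detection
axis.  In a 2D frame (a z-maximum projection) rows run along ``y`` — the
anterior–posterior axis after alignment — and columns along ``x``.  3D
stacks are ordered ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass
class ImageFrame:
    """A single 2D intensity frame with physical calibration.

    Parameters
    ----------
    data:
        2D array of non-negative intensities, rows along ``y``.
    pixel_size:
        Lateral pixel size in micrometres per pixel, if known.
    time:
        Acquisition time in hours, if known.
    """

    data: np.ndarray
    pixel_size: float | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ConfigurationError("ImageFrame requires a 2D array")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ConfigurationError("intensities must be finite and non-negative")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class ImageStack:
    """A 3D intensity stack ordered ``(z, y, x)`` with voxel calibration."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None = None
    dataset_id: str | None = None
    timepoint_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError("ImageStack requires a 3D array")
        if self.voxel_size is not None and any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class SeedSet:
    """Seed coordinates with the blob-detection scale that produced them."""

    coords: np.ndarray  # (N, ndim) integer pixel/voxel coordinates
    scales: np.ndarray  # (N,) detection sigma in pixels

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        self.scales = np.atleast_1d(np.asarray(self.scales, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, max(1, self.coords.shape[-1] if self.coords.ndim == 2 else 1))

    def __len__(self) -> int:
        return 0 if self.coords.size == 0 else self.coords.shape[0]


@dataclass
class LabelMap:
    """Integer-labelled segmentation (0 = background) plus an object table.

    Labels are consecutive ``1..K``.  The object table is recomputed from
    the grid on demand so it can never drift out of sync.
    """

    labels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size and self.labels.min() < 0:
            raise ConfigurationError("labels must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ConfigurationError("labels must be consecutive 1..K")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def areas(self) -> np.ndarray:
        """Pixel (voxel) counts per object, index 0 -> label 1."""
        if self.n_objects == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]

    def table(self) -> pd.DataFrame:
        """Object table: label, pixel count, centroid, bbox, border flag."""
        rows = []
        lab = self.labels
        border = np.zeros(self.n_objects + 1, dtype=bool)
        for axis in range(lab.ndim):
            for sl in (0, -1):
                face = np.take(lab, sl, axis=axis)
                border[np.unique(face)] = True
        for k in range(1, self.n_objects + 1):
            coords = np.argwhere(lab == k)
            area = len(coords)
            row: dict = {
                "label": k,
                "area_px": area,
                "border": bool(border[k]),
            }
            if self.pixel_size is not None:
                row["area_um2"] = area * self.pixel_size ** 2
            for i, name in enumerate("zyx"[-lab.ndim:]):
                row[f"centroid_{name}"] = float(coords[:, i].mean())
                row[f"bbox_{name}_min"] = int(coords[:, i].min())
                row[f"bbox_{name}_max"] = int(coords[:, i].max())
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_array(cls, labels: np.ndarray, pixel_size: float | None = None) -> "LabelMap":
        return cls(labels=labels, pixel_size=pixel_size)


def as_array(img) -> np.ndarray:
    """Unwrap an ImageFrame/ImageStack to its raw array (pass arrays through)."""
    if isinstance(img, (ImageFrame, ImageStack)):
        return img.data
    return np.asarray(img)
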