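"""Core containers and exceptions shared across the package.

A radiograph is a 2-D grayscale intensity grid normalised to [0, 1]; a
segmentation mask is a binary grid of the same shape where 1 marks the
caries (lesion) foreground and 0 the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Radiograph",
    "SegmentationMask",
    "CariessegError",
    "AnnotationFormatError",
    "AnnotationError",
    "DatasetError",
    "ShapeMismatchError",
    "TrainingDivergedError",
    "PipelineError",
]


class CariessegError(Exception):
    """Base class for all package-specific errors."""


class AnnotationFormatError(CariessegError):
    """An annotation file is structurally invalid (missing/malformed keys)."""


class AnnotationError(CariessegError):
    """An individual annotation entry violates its contract."""


class DatasetError(CariessegError):
    """A dataset directory or item is inconsistent."""


class ShapeMismatchError(CariessegError):
    """Two grids that must be aligned have different shapes."""


class TrainingDivergedError(CariessegError):
    """Optimisation produced a non-finite loss."""


class PipelineError(CariessegError):
    """A pipeline stage cannot proceed (e.g. no usable pseudo labels)."""


def _require_2d(arr: np.ndarray, what: str) -> None:
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{what} must be a non-empty 2-D grid, got shape {arr.shape}")


@dataclass(eq=False)
class Radiograph:
    """A grayscale image with intensities in [0, 1] and an identifier."""

    id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        _require_2d(self.pixels, "Radiograph.pixels")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"Radiograph intensities must lie in [0, 1]; got range [{lo}, {hi}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(eq=False)
class SegmentationMask:
    """A binary mask aligned to a radiograph; 1 = lesion foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("SegmentationMask values must be 0 or 1")
        self.pixels = arr.astype(np.uint8)
        _require_2d(self.pixels, "SegmentationMask.pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def foreground_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def foreground_fraction(self) -> float:
        return self.foreground_pixels / self.pixels.size

    def is_empty(self) -> bool:
        return self.foreground_pixels == 0


def check_aligned(a, b, what: str = "grids") -> None:
    """Raise :class:`ShapeMismatchError` unless the two grids share a shape."""
    sa = a.shape if hasattr(a, "shape") else np.asarray(a).shape
    sb = b.shape if hasattr(b, "shape") else np.asarray(b).shape
    if tuple(sa) != tuple(sb):
        raise ShapeMismatchError(f"{what} have mismatched shapes {tuple(sa)} vs {tuple(sb)}")
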