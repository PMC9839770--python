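"""Image/mask file I/O and rasterisation of LabelMe-style polygon annotations.

Coordinate conventions
----------------------
Pixel grids are 0-based and row-major. Polygon vertices follow the LabelMe
JSON dialect: each point is ``(x, y)`` with ``x`` the column and ``y`` the
row, origin at the top-left, floating point. The centre of pixel ``(r, c)``
is the point ``(x=c, y=r)``.

Rasterisation marks a pixel as foreground iff its centre lies inside or on
the boundary of at least one polygon, using the even-odd fill rule;
overlapping polygons union.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .core import (
    AnnotationError,
    AnnotationFormatError,
    DatasetError,
    Radiograph,
    SegmentationMask,
)

__all__ = [
    "PolygonAnnotation",
    "read_labelme_polygons",
    "rasterize_polygons",
    "read_image",
    "read_mask_image",
    "write_mask_image",
    "write_image",
    "load_image_mask_dataset",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass(eq=False)
class PolygonAnnotation:
    """One labelled polygon in image coordinates ((x=col, y=row) vertices)."""

    label: str
    vertices: np.ndarray  # (n, 2) float array of (x, y)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise AnnotationError(
                f"polygon vertices must be an (n, 2) array, got {self.vertices.shape}"
            )
        if len(self.vertices) < 3:
            raise AnnotationError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )


def read_labelme_polygons(path) -> tuple[list[PolygonAnnotation], tuple[int, int]]:
    """Parse a LabelMe JSON file into polygon annotations plus the image shape.

    Returns ``(annotations, (height, width))`` with one annotation per entry
    of ``shapes``, in file order.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationFormatError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("imageHeight", "imageWidth", "shapes"):
        if key not in doc:
            raise AnnotationFormatError(f"{path}: missing required key {key!r}")
    height, width = int(doc["imageHeight"]), int(doc["imageWidth"])
    annotations: list[PolygonAnnotation] = []
    for idx, shape in enumerate(doc["shapes"]):
        for key in ("points", "label"):
            if key not in shape:
                raise AnnotationFormatError(
                    f"{path}: shape {idx} missing required key {key!r}"
                )
        points = np.asarray(shape["points"], dtype=np.float64)
        if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
            raise AnnotationError(
                f"{path}: shape {idx} has {0 if points.ndim != 2 else len(points)}"
                " usable points; polygons need >= 3"
            )
        # Clamp vertices into the image frame; LabelMe occasionally emits
        # coordinates a fraction of a pixel outside it.
        points[:, 0] = np.clip(points[:, 0], 0.0, float(width))
        points[:, 1] = np.clip(points[:, 1], 0.0, float(height))
        annotations.append(PolygonAnnotation(label=str(shape["label"]), vertices=points))
    return annotations, (height, width)


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd containment of points in a polygon, boundary inclusive.

    Uses the crossing-number rule for interior membership plus an explicit
    on-segment test so that points exactly on an edge or vertex count as
    inside regardless of edge orientation.
    """
    inside = np.zeros(xs.shape, dtype=bool)
    on_edge = np.zeros(xs.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        cross = dx * (ys - y1) - dy * (xs - x1)
        seg_len = max(np.hypot(dx, dy), 1e-300)
        in_box = (
            (xs >= min(x1, x2) - 1e-9)
            & (xs <= max(x1, x2) + 1e-9)
            & (ys >= min(y1, y2) - 1e-9)
            & (ys <= max(y1, y2) + 1e-9)
        )
        on_edge |= in_box & (np.abs(cross) <= 1e-9 * seg_len)
        crosses = (y1 > ys) != (y2 > ys)
        if crosses.any() and dy != 0.0:
            x_int = x1 + (ys - y1) * dx / dy
            inside ^= crosses & (xs < x_int)
    return inside | on_edge


def rasterize_polygons(
    annotations: Sequence[PolygonAnnotation], height: int, width: int
) -> SegmentationMask:
    """Rasterise polygons into a binary mask by pixel-centre containment.

    A pixel is foreground iff its centre ``(x=c, y=r)`` is inside or on the
    boundary of at least one polygon under the even-odd rule.
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"frame must be positive, got {height}x{width}")
    cols, rows = np.meshgrid(np.arange(width, dtype=np.float64),
                             np.arange(height, dtype=np.float64))
    mask = np.zeros((height, width), dtype=bool)
    for ann in annotations:
        mask |= _points_in_polygon(cols, rows, ann.vertices)
    return SegmentationMask(mask.astype(np.uint8))


def read_image(path, id: Optional[str] = None) -> Radiograph:
    """Read a PNG/TIFF/JPEG as a grayscale radiograph (RGB via luminance)."""
    path = Path(path)
    with Image.open(path) as img:
        arr = np.asarray(img.convert("F" if img.mode in ("F", "I") else "L"),
                         dtype=np.float64)
    if arr.size == 0:
        raise DatasetError(f"{path}: image has zero size")
    if arr.max() > 1.0:
        arr = arr / 255.0
    return Radiograph(id=id or path.stem, pixels=np.clip(arr, 0.0, 1.0))


def write_image(image: Radiograph, path) -> None:
    """Write a radiograph as an 8-bit grayscale PNG."""
    arr = np.clip(np.rint(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_mask_image(path) -> SegmentationMask:
    """Read a mask file; 8-bit intensities > 127 map to foreground."""
    path = Path(path)
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    if arr.size == 0:
        raise DatasetError(f"{path}: mask image has zero size")
    return SegmentationMask((arr > 127).astype(np.uint8))


def write_mask_image(mask: SegmentationMask, path) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L").save(Path(path))


def load_image_mask_dataset(
    image_dir, mask_dir=None, annotation_dir=None
) -> list[tuple[Radiograph, Optional[SegmentationMask]]]:
    """Load images with masks matched by filename stem.

    Masks come either from mask PNGs in ``mask_dir`` or from LabelMe JSON
    files in ``annotation_dir`` (rasterised on the fly). Images without a
    matching mask are returned with ``None`` (unlabelled). Order is
    lexicographic by stem, so repeated loads are deterministic.
    """
    image_dir = Path(image_dir)
    if not image_dir.is_dir():
        raise DatasetError(f"image directory {image_dir} does not exist")
    if (mask_dir is None) == (annotation_dir is None):
        raise ValueError("provide exactly one of mask_dir or annotation_dir")
    label_dir = Path(mask_dir) if mask_dir is not None else Path(annotation_dir)
    if not label_dir.is_dir():
        raise DatasetError(f"label directory {label_dir} does not exist")

    images = sorted(
        (p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
        key=lambda p: p.stem,
    )
    out: list[tuple[Radiograph, Optional[SegmentationMask]]] = []
    for img_path in images:
        image = read_image(img_path)
        mask: Optional[SegmentationMask] = None
        if mask_dir is not None:
            candidates = [label_dir / (img_path.stem + s) for s in _IMAGE_SUFFIXES]
            hit = next((c for c in candidates if c.exists()), None)
            if hit is not None:
                mask = read_mask_image(hit)
        else:
            cand = label_dir / (img_path.stem + ".json")
            if cand.exists():
                annotations, (h, w) = read_labelme_polygons(cand)
                mask = rasterize_polygons(annotations, h, w)
        if mask is not None and mask.shape != image.shape:
            raise DatasetError(
                f"{img_path.stem}: mask shape {mask.shape} does not match "
                f"image shape {image.shape}"
            )
        out.append((image, mask))
    return out
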