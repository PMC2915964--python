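"""Gridded binary shape images and lexicographic vectorization.

A shape is an ``L x L`` grid of {0, 1} pixels: 1 marks the object
(foreground, "white"), 0 the background ("black").  Pixel centers sit at
integer coordinates ``(x=column, y=row)`` with ``x, y = 1, ..., L``; the grid
is the image domain.  Vectorization stacks the columns of the grid into a
single length ``m = L**2`` row, which is the order the phenotype matrix uses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateShapeError, DimensionError

_TEXT_SUFFIXES = {".txt", ".dat", ".mat.txt", ".tsv"}


@dataclass(frozen=True)
class BinaryShapeImage:
    """An ``L x L`` binary image with at least one pixel of each class."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise DimensionError(f"image must be square 2-D, got shape {px.shape}")
        if px.shape[0] < 2:
            raise DimensionError("image side must be at least 2 pixels")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("binary image entries must be exactly 0 or 1")
        px = px.astype(np.uint8)
        s = int(px.sum())
        if s == 0:
            raise DegenerateShapeError("image has no foreground pixels")
        if s == px.size:
            raise DegenerateShapeError("image has no background pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def L(self) -> int:
        return self.pixels.shape[0]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class ShapeSet:
    """An ordered collection of same-sized binary shapes, one per progeny."""

    images: list[BinaryShapeImage]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("ShapeSet needs at least one image")
        sides = {im.L for im in self.images}
        if len(sides) != 1:
            raise DimensionError(f"all images must share one side length, got {sorted(sides)}")
        if not self.ids:
            self.ids = [f"progeny_{i + 1}" for i in range(len(self.images))]
        if len(self.ids) != len(self.images):
            raise ValueError("ids and images must have equal length")

    @property
    def n(self) -> int:
        return len(self.images)

    @property
    def L(self) -> int:
        return self.images[0].L

    def as_array(self) -> np.ndarray:
        """Stack into an (n, L, L) uint8 array."""
        return np.stack([im.pixels for im in self.images])


def _read_raster(path: str) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # RGB(A): use channel mean as luminance
        arr = arr[..., :3].mean(axis=2)
    return arr.astype(float)


def load_shape(path: str | os.PathLike, threshold: float = 0.5) -> BinaryShapeImage:
    """Read a PNG/PGM raster or whitespace-delimited text matrix as a binary shape.

    Grayscale intensities are scaled to [0, 1] by the dtype range (or by the
    observed maximum for float/text inputs) and set to foreground where the
    scaled value exceeds ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    path = os.fspath(path)
    suffix = os.path.splitext(path)[1].lower()
    if suffix in _TEXT_SUFFIXES or suffix == "":
        arr = np.loadtxt(path, ndmin=2, dtype=float)
    else:
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
        if raw.ndim == 3:
            raw = raw[..., :3].mean(axis=2)
        if np.issubdtype(raw.dtype, np.integer):
            arr = raw.astype(float) / float(np.iinfo(raw.dtype).max)
        else:
            arr = raw.astype(float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DimensionError(f"{path}: expected a square image, got shape {arr.shape}")
    amax = arr.max()
    if amax > 1.0:  # text matrices written as 0/255 etc.
        arr = arr / amax
    return BinaryShapeImage((arr > threshold).astype(np.uint8))


def save_shape(image: BinaryShapeImage, path: str | os.PathLike) -> None:
    """Write a binary shape as PNG/PGM (0/255) or text matrix (0/1) by suffix."""
    path = os.fspath(path)
    suffix = os.path.splitext(path)[1].lower()
    if suffix in _TEXT_SUFFIXES or suffix == "":
        np.savetxt(path, image.pixels, fmt="%d")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, (image.pixels * 255).astype(np.uint8))


def vectorize_lexicographic(matrix: np.ndarray) -> np.ndarray:
    """Stack the columns of a square matrix into one length ``L**2`` vector.

    Output index ``k = (c - 1) * L + r`` (1-based) holds the entry at row
    ``r``, column ``c`` — i.e. column-major (Fortran) order.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {m.shape}")
    return m.flatten(order="F")


def unvectorize(vector: np.ndarray, L: int) -> np.ndarray:
    """Inverse of :func:`vectorize_lexicographic`."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.size != L * L:
        raise DimensionError(f"vector length {v.size} is not {L}**2 = {L * L}")
    return v.reshape((L, L), order="F")


def load_shape_set(paths: Sequence[str | os.PathLike], threshold: float = 0.5,
                   ids: Sequence[str] | None = None) -> ShapeSet:
    """Load several shape files into one ShapeSet (ids default to stems)."""
    images = [load_shape(p, threshold) for p in paths]
    if ids is None:
        ids = [os.path.splitext(os.path.basename(os.fspath(p)))[0] for p in paths]
    return ShapeSet(images, list(ids))
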