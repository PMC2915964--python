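"""Signed distance embedding of aligned shapes and the phenotype matrix.

The contour of each aligned shape is represented implicitly as the zero level
set of a signed distance function (SDF): negative inside the shape, positive
outside.  Distances are exact Euclidean distances between pixel centers, so a
foreground pixel holds minus the distance to the nearest background pixel
(magnitude >= 1) and a background pixel holds the distance to the nearest
foreground pixel.  Vectorizing each SDF lexicographically gives one row of
the n x m phenotype matrix (m = L**2) that the mixture model is fitted to.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .alignment import AlignedShapeSet
from .errors import DegenerateShapeError, DimensionError
from .shape_image import BinaryShapeImage, unvectorize, vectorize_lexicographic

__all__ = [
    "SignedDistanceMap", "PhenotypeMatrix", "signed_distance",
    "build_phenotypes", "reconstruct_shape",
]


@dataclass(frozen=True)
class SignedDistanceMap:
    """Exact Euclidean SDF of a binary shape (negative inside)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError(f"SDF must be square, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def to_shape(self) -> BinaryShapeImage:
        """Threshold at the zero level set (values <= 0 are foreground)."""
        return BinaryShapeImage((self.values <= 0).astype(np.uint8))


def signed_distance(image) -> SignedDistanceMap:
    """Exact Euclidean signed distance of a binary image, pixel-center metric.

    Background pixels get the distance to the nearest foreground pixel;
    foreground pixels get minus the distance to the nearest background pixel.
    """
    if isinstance(image, BinaryShapeImage):
        fg = image.pixels.astype(bool)
    else:
        arr = np.asarray(image)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise DimensionError(f"expected a square image, got shape {arr.shape}")
        fg = arr > 0.5
    if fg.all():
        raise DegenerateShapeError("image is all foreground: no contour exists")
    if not fg.any():
        raise DegenerateShapeError("image is all background: no contour exists")
    outside = distance_transform_edt(~fg)   # distance to nearest foreground
    inside = distance_transform_edt(fg)     # distance to nearest background
    return SignedDistanceMap(outside - inside)


@dataclass
class PhenotypeMatrix:
    """n x m matrix of lexicographically vectorized SDF values."""

    values: np.ndarray
    ids: list[str]
    L: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DimensionError("phenotype matrix must be 2-D")
        if v.shape[1] != self.L * self.L:
            raise DimensionError(
                f"m = {v.shape[1]} does not equal L**2 = {self.L * self.L}")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match the number of rows")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                          columns=[str(k + 1) for k in range(self.m)])
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "PhenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        L = int(round(df.shape[1] ** 0.5))
        return cls(values=df.to_numpy(dtype=float),
                   ids=[str(i) for i in df.index], L=L)


def build_phenotypes(aligned: AlignedShapeSet,
                     binarize_threshold: float = 0.5) -> PhenotypeMatrix:
    """Binarize each aligned image, embed as an SDF, and vectorize into rows."""
    if not 0 < binarize_threshold < 1:
        raise ValueError("binarize_threshold must lie in (0, 1)")
    n, L = aligned.n, aligned.L
    ids = list(aligned.ids) if aligned.ids else [f"progeny_{i+1}" for i in range(n)]
    rows = np.empty((n, L * L))
    for i in range(n):
        binary = aligned.images[i] > binarize_threshold
        if binary.all() or not binary.any():
            raise DegenerateShapeError(
                f"aligned image for progeny '{ids[i]}' is degenerate after "
                f"thresholding at {binarize_threshold}")
        rows[i] = vectorize_lexicographic(signed_distance(binary).values)
    return PhenotypeMatrix(values=rows, ids=ids, L=L)


def reconstruct_shape(mean_vector: np.ndarray, L: int) -> BinaryShapeImage | None:
    """Render a mean SDF vector as the binary shape inside its zero level set.

    Foreground where the un-vectorized value is <= 0.  If the field has no
    sign change (empty or full shape) a degenerate-reconstruction warning is
    raised and None is returned.
    """
    field = unvectorize(mean_vector, L)
    fg = field <= 0
    if fg.all() or not fg.any():
        warnings.warn("mean field has no zero crossing: degenerate "
                      "reconstruction (empty or full shape)", RuntimeWarning)
        return None
    return BinaryShapeImage(fg.astype(np.uint8))
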