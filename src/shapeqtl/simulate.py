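"""Synthetic backcross populations with genotype-dependent leaf shapes.

The generator emulates the two study designs: a backcross of n = 200 progeny
on one linkage group of 11 equally spaced markers (10 cM apart), a shape QTL
in the third marker interval, and 75 x 75 silhouettes.  Each QTL genotype j
has a true mean field mu_j — the signed distance map of a parametric leaf
silhouette — and progeny phenotype fields are drawn from the additive model

    Y_i = xi_i * mu_1 + (1 - xi_i) * mu_2 + e_i,

where xi_i indicates QTL genotype QQ and e_i is iid N(0, sigma2) per pixel
(identity covariance scaled by sigma2; default sigma2 = 1).  Noise is added
in SDF space, where the multivariate-normal residual model is coherent; the
observable silhouette of a progeny is the field thresholded at its zero
level set.

Leaf silhouettes are polar-boundary rasterizations

    rho(phi) = base_radius * L * (1 - lobe_depth cos(n_lobes phi))
                               * (1 + serration cos(12 phi))

with the y-axis scaled by ``elongation``: lobed, serrated outlines for wild
types, rounder smoother ones for cultivars.  Named presets pin each scheme's
two genotype shapes so effect sizes are reproducible constants:

* ``big``          — deeply lobed wild type vs round cultivar (large effect)
* ``small-wild``   — two slightly different wild-type outlines
* ``small-cultivar`` — two slightly different cultivar outlines
* ``null``         — both genotypes share one outline (no QTL; calibration)
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import PoseParameters, apply_pose
from .errors import ParameterError
from .genetics import BackcrossGenotypes, LinkageMap, simulate_genotypes
from .sdf import signed_distance
from .shape_image import BinaryShapeImage, ShapeSet, save_shape

__all__ = [
    "LeafShapeParams", "SimulatedPopulation", "SCHEME_PRESETS",
    "default_map", "generate_leaf", "simulate_population", "perturb_poses",
    "write_fixture",
]


@dataclass(frozen=True)
class LeafShapeParams:
    """Parameters of the polar leaf-outline model (radii as fractions of L)."""

    n_lobes: int = 5
    lobe_depth: float = 0.3
    base_radius: float = 0.3
    elongation: float = 1.0
    serration: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lobes < 1:
            raise ParameterError("n_lobes must be >= 1")
        if not 0 <= self.lobe_depth < 1:
            raise ParameterError("lobe_depth must lie in [0, 1)")
        if not 0 < self.base_radius < 0.5:
            raise ParameterError("base_radius must lie in (0, 0.5)")
        if not self.elongation > 0:
            raise ParameterError("elongation must be positive")
        if self.serration < 0:
            raise ParameterError("serration must be nonnegative")


# Two genotype outlines per scheme: (QQ = wild-type side, Qq = cultivar side).
# The paired outlines have matched foreground areas: joint similarity
# alignment removes per-shape size (shape excludes scale by definition), so a
# genotype effect encoded as a size difference would be absorbed into the
# poses instead of the genotype means.  Effects therefore live in lobe depth,
# elongation and serration only.
_WILD = LeafShapeParams(n_lobes=5, lobe_depth=0.45, base_radius=0.28,
                        elongation=1.0, serration=0.06)
_CULTIVAR = LeafShapeParams(n_lobes=5, lobe_depth=0.08, base_radius=0.318,
                            elongation=0.85, serration=0.02)
SCHEME_PRESETS: dict[str, tuple[LeafShapeParams, LeafShapeParams]] = {
    "big": (_WILD, _CULTIVAR),
    "small-wild": (_WILD, replace(_WILD, lobe_depth=0.35, base_radius=0.285)),
    "small-cultivar": (_CULTIVAR, replace(_CULTIVAR, lobe_depth=0.03,
                                          elongation=0.92, base_radius=0.306)),
    "null": (_WILD, _WILD),
}


def default_map(n_markers: int = 11, spacing_cM: float = 10.0) -> LinkageMap:
    """One linkage group of equally spaced markers starting at 0 cM."""
    return LinkageMap(
        marker_names=[f"M{j + 1}" for j in range(n_markers)],
        positions_cM=np.arange(n_markers, dtype=float) * spacing_cM)


def generate_leaf(params: LeafShapeParams, L: int) -> BinaryShapeImage:
    """Rasterize the polar leaf outline, centered in an L x L grid."""
    rho_max = params.base_radius * (1 + params.lobe_depth) * (1 + params.serration)
    if rho_max * max(1.0, params.elongation) >= 0.5 - 1.0 / L:
        raise ParameterError("leaf boundary would leave the image grid; "
                             "reduce base_radius/lobe_depth/elongation")
    c = (L + 1) / 2.0
    xs, ys = np.meshgrid(np.arange(1, L + 1, dtype=float),
                         np.arange(1, L + 1, dtype=float), indexing="xy")
    dx = xs - c
    dy = (ys - c) / params.elongation
    r = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    rho = (params.base_radius * L
           * (1.0 - params.lobe_depth * np.cos(params.n_lobes * phi))
           * (1.0 + params.serration * np.cos(12.0 * phi)))
    return BinaryShapeImage((r <= rho).astype(np.uint8))


@dataclass
class SimulatedPopulation:
    """A simulated backcross with its ground truth."""

    shapes: ShapeSet
    fields: np.ndarray              # (n, L, L) noisy SDF phenotype fields
    genotypes: BackcrossGenotypes
    map: LinkageMap
    qtl_position_cM: float
    xi: np.ndarray                  # (n,) in {0, 1}; 1 = QQ
    mu1_img: np.ndarray             # true genotype mean SDF fields (L, L)
    mu2_img: np.ndarray
    sigma2_true: float
    scheme: str
    seed: int

    @property
    def n(self) -> int:
        return self.shapes.n

    @property
    def L(self) -> int:
        return self.shapes.L


def simulate_population(scheme: str = "big", n: int = 200, L: int = 75,
                        lmap: LinkageMap | None = None, qtl_interval: int = 3,
                        qtl_offset_cM: float | None = None,
                        sigma2: float = 1.0, seed: int = 0
                        ) -> SimulatedPopulation:
    """Simulate one backcross population under a named scheme.

    The QTL sits in marker interval ``qtl_interval`` (1-based; default the
    third), at its midpoint unless ``qtl_offset_cM`` gives the offset from
    the interval's left marker.  Marker genotypes and the QTL genotype are
    drawn jointly from one no-interference Markov chain so the indicator
    xi_i is exactly consistent with the flanking markers.
    """
    if scheme not in SCHEME_PRESETS:
        raise ParameterError(f"unknown scheme {scheme!r}; "
                             f"choose from {sorted(SCHEME_PRESETS)}")
    if n < 2:
        raise ParameterError("need at least two progeny")
    lmap = lmap or default_map()
    if not 1 <= qtl_interval <= lmap.M - 1:
        raise ParameterError(f"qtl_interval must lie in [1, {lmap.M - 1}]")
    left = lmap.positions_cM[qtl_interval - 1]
    right = lmap.positions_cM[qtl_interval]
    offset = (right - left) / 2.0 if qtl_offset_cM is None else float(qtl_offset_cM)
    if not 0 <= offset <= right - left:
        raise ParameterError("qtl_offset_cM outside the chosen interval")
    qtl_pos = float(left + offset)

    p1, p2 = SCHEME_PRESETS[scheme]
    mu1 = signed_distance(generate_leaf(p1, L)).values
    mu2 = signed_distance(generate_leaf(p2, L)).values

    rng = np.random.default_rng(seed)
    # augment the map with the QTL as a pseudo-locus, simulate jointly
    aug_pos = np.sort(np.append(lmap.positions_cM, qtl_pos))
    qtl_idx = int(np.searchsorted(aug_pos, qtl_pos))
    aug = LinkageMap(marker_names=[f"L{k}" for k in range(aug_pos.size)],
                     positions_cM=aug_pos)
    G_aug = simulate_genotypes(aug, n, rng).values
    marker_cols = [k for k in range(aug_pos.size) if k != qtl_idx]
    genotypes = BackcrossGenotypes(values=G_aug[:, marker_cols])
    xi = (G_aug[:, qtl_idx] == 1).astype(int)

    noise_sd = float(np.sqrt(sigma2))
    fields = np.where(xi[:, None, None] == 1, mu1, mu2).astype(float)
    if noise_sd > 0:
        fields = fields + noise_sd * rng.standard_normal((n, L, L))
    images = [BinaryShapeImage((f <= 0).astype(np.uint8)) for f in fields]
    shapes = ShapeSet(images, [f"progeny_{i + 1}" for i in range(n)])
    return SimulatedPopulation(
        shapes=shapes, fields=fields, genotypes=genotypes, map=lmap,
        qtl_position_cM=qtl_pos, xi=xi, mu1_img=mu1, mu2_img=mu2,
        sigma2_true=sigma2, scheme=scheme, seed=seed)


def perturb_poses(shapes: ShapeSet, max_shift: float = 0.0,
                  max_log_scale: float = 0.0, max_angle: float = 0.0,
                  seed: int = 0) -> tuple[ShapeSet, list[PoseParameters]]:
    """Apply an independent random pose (uniform within bounds) to each shape.

    Returns the perturbed set and the true poses, for alignment ground truth.
    The perturbed images are bilinear resamples rebinarized at 0.5.
    """
    if min(max_shift, max_log_scale, max_angle) < 0:
        raise ParameterError("perturbation bounds must be nonnegative")
    rng = np.random.default_rng(seed)
    out, poses = [], []
    for im in shapes.images:
        p = PoseParameters(
            a=rng.uniform(-max_shift, max_shift),
            b=rng.uniform(-max_shift, max_shift),
            h=float(np.exp(rng.uniform(-max_log_scale, max_log_scale))),
            theta=rng.uniform(-max_angle, max_angle))
        moved = apply_pose(im, p, order=1) > 0.5
        if not moved.any():
            raise ParameterError("a perturbation pushed a shape fully outside "
                                 "the grid; reduce the bounds")
        out.append(BinaryShapeImage(moved.astype(np.uint8)))
        poses.append(p)
    return ShapeSet(out, list(shapes.ids)), poses


def write_fixture(pop: SimulatedPopulation, outdir: str | os.PathLike,
                  image_format: str = "png") -> None:
    """Write the pipeline input contract: shape rasters + map/genotype CSVs
    + a truth sidecar JSON."""
    outdir = os.fspath(outdir)
    shape_dir = os.path.join(outdir, "shapes")
    os.makedirs(shape_dir, exist_ok=True)
    for pid, im in zip(pop.shapes.ids, pop.shapes.images):
        save_shape(im, os.path.join(shape_dir, f"{pid}.{image_format}"))
    pop.map.to_csv(os.path.join(outdir, "map.csv"))
    pop.genotypes.to_csv(os.path.join(outdir, "genotypes.csv"), pop.map)
    truth = {"scheme": pop.scheme, "seed": pop.seed, "n": pop.n, "L": pop.L,
             "qtl_position_cM": pop.qtl_position_cM,
             "sigma2": pop.sigma2_true, "xi": pop.xi.tolist()}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
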