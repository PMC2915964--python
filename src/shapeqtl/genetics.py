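"""Backcross linkage-map machinery.

A backcross progeny carries one of two genotypes at every locus, coded
1 (= QQ) and 2 (= Qq), segregating 1:1.  Map distance d (centiMorgans) maps
to a recombination fraction through the Haldane function (no interference)

    r(d) = (1 - exp(-2 d / 100)) / 2.

For a putative QTL between two flanking markers at recombination fractions
r1 (to the left marker) and r2 (to the right), with inter-marker fraction
r = r1 + r2 - 2 r1 r2, the conditional probability of QTL genotype QQ given
the flanking genotype pair is the standard no-interference table

    (1,1): (1-r1)(1-r2)/(1-r)      (1,2): (1-r1) r2 / r
    (2,1): r1 (1-r2) / r           (2,2): r1 r2 / (1-r)

These per-individual probabilities are the mixture weights of the shape
mixture model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MapDomainError

__all__ = [
    "LinkageMap", "BackcrossGenotypes", "MixtureWeights",
    "haldane_r", "simulate_genotypes", "qtl_weights",
]

_POSITION_TOL = 1e-9


@dataclass
class LinkageMap:
    """Ordered markers on one linkage group with cM positions."""

    marker_names: list[str]
    positions_cM: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cM, dtype=float)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("a linkage map needs at least two markers")
        if len(self.marker_names) != pos.size:
            raise ValueError("marker_names and positions_cM must match in length")
        if (np.diff(pos) < 0).any():
            raise ValueError("marker positions must be nondecreasing")
        self.positions_cM = pos

    @property
    def M(self) -> int:
        return self.positions_cM.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions_cM[0]), float(self.positions_cM[-1])

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame({"marker": self.marker_names,
                      "chrom": self.chrom,
                      "pos_cM": self.positions_cM}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "LinkageMap":
        df = pd.read_csv(path)
        chrom = str(df["chrom"].iloc[0]) if "chrom" in df.columns else "1"
        return cls(marker_names=[str(m) for m in df["marker"]],
                   positions_cM=df["pos_cM"].to_numpy(dtype=float), chrom=chrom)


@dataclass
class BackcrossGenotypes:
    """n x M genotype matrix with entries in {1 = QQ, 2 = Qq}."""

    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if not np.isin(v, (1, 2)).all():
            raise ValueError("backcross genotypes must be coded 1 (QQ) or 2 (Qq); "
                             "missing values are not supported")
        self.values = v.astype(np.int8)
        if not self.ids:
            self.ids = [f"progeny_{i + 1}" for i in range(v.shape[0])]
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match the number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | os.PathLike, lmap: LinkageMap | None = None) -> None:
        cols = lmap.marker_names if lmap is not None else \
            [f"m{j + 1}" for j in range(self.M)]
        pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                     columns=cols).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "BackcrossGenotypes":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=int), ids=[str(i) for i in df.index])


@dataclass
class MixtureWeights:
    """Per-individual prior probabilities of the two QTL genotypes."""

    omega: np.ndarray  # (n, 2), rows (w_QQ, w_Qq)
    test_position_cM: float

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        if w.ndim != 2 or w.shape[1] != 2:
            raise ValueError("omega must be an (n, 2) matrix")
        if (w < -1e-12).any() or np.abs(w.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("each omega row must be nonnegative and sum to 1")
        self.omega = w


def haldane_r(d_cM) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM."""
    d = np.asarray(d_cM, dtype=float)
    if (d < 0).any():
        raise MapDomainError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def simulate_genotypes(lmap: LinkageMap, n: int,
                       seed: int | np.random.Generator = 0) -> BackcrossGenotypes:
    """Simulate backcross marker genotypes as a Markov chain along the map.

    The first marker is 1 or 2 with probability 1/2 each; every subsequent
    marker switches state with the Haldane recombination fraction of its
    interval (no interference).
    """
    if n < 1:
        raise ValueError("need at least one progeny")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = haldane_r(np.diff(lmap.positions_cM))
    G = np.empty((n, lmap.M), dtype=np.int8)
    G[:, 0] = rng.integers(1, 3, size=n)
    for j in range(1, lmap.M):
        switch = rng.random(n) < r[j - 1]
        G[:, j] = np.where(switch, 3 - G[:, j - 1], G[:, j - 1])
    return BackcrossGenotypes(values=G)


def qtl_weights(genotypes: BackcrossGenotypes, lmap: LinkageMap,
                position_cM: float) -> MixtureWeights:
    """Conditional QTL-genotype probabilities given the flanking markers.

    At a marker position the weights collapse to that marker's genotype
    indicator; strictly inside an interval the no-interference flanking table
    applies.
    """
    pos = float(position_cM)
    lo, hi = lmap.span
    if pos < lo - _POSITION_TOL or pos > hi + _POSITION_TOL:
        raise MapDomainError(
            f"test position {pos} cM outside map span [{lo}, {hi}]")
    dist = np.abs(lmap.positions_cM - pos)
    j = int(np.argmin(dist))
    if dist[j] <= _POSITION_TOL:  # on a marker: weights are its indicator
        w1 = (genotypes.values[:, j] == 1).astype(float)
        omega = np.column_stack([w1, 1.0 - w1])
        return MixtureWeights(omega=omega, test_position_cM=pos)
    left = int(np.searchsorted(lmap.positions_cM, pos) - 1)
    right = left + 1
    r1 = haldane_r(pos - lmap.positions_cM[left])
    r2 = haldane_r(lmap.positions_cM[right] - pos)
    r = r1 + r2 - 2.0 * r1 * r2
    gl = genotypes.values[:, left]
    gr = genotypes.values[:, right]
    table = {
        (1, 1): (1 - r1) * (1 - r2) / (1 - r),
        (1, 2): (1 - r1) * r2 / r,
        (2, 1): r1 * (1 - r2) / r,
        (2, 2): r1 * r2 / (1 - r),
    }
    w1 = np.empty(genotypes.n)
    for (a, b), p in table.items():
        w1[(gl == a) & (gr == b)] = p
    omega = np.column_stack([w1, 1.0 - w1])
    return MixtureWeights(omega=omega, test_position_cM=pos)
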