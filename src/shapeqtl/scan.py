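"""Genome scan of the likelihood-ratio statistic and permutation thresholds.

At each test position the flanking-marker conditional probabilities give the
mixture weights, the two-component model is fitted by EM, and the statistic

    LR = 2 * (loglik_mixture - loglik_null)

is recorded (the null single-component fit does not depend on position, so it
is computed once).  Because the EM is additionally guaranteed to reach at
least the null log-likelihood (fallback start from mu1 = mu2 = mu0), the
profile is nonnegative everywhere.

Significance uses the standard permutation approach: phenotype rows are
shuffled against genotype rows, the full scan is repeated, and the empirical
(1 - alpha) quantile of the max-LR distribution is the genome-wide threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import BackcrossGenotypes, LinkageMap, qtl_weights
from .mixture import _as_matrix, fit_mixture_batch, fit_null

__all__ = ["ScanResult", "scan_grid", "scan", "permutation_threshold"]


@dataclass
class ScanResult:
    """LR profile over test positions, with optional permutation threshold."""

    positions_cM: np.ndarray
    lr: np.ndarray
    threshold: float | None = None
    alpha: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    @property
    def peak_position_cM(self) -> float:
        return float(self.positions_cM[int(np.argmax(self.lr))])

    @property
    def peak_lr(self) -> float:
        return float(self.lr.max())

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return self.peak_lr > self.threshold

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame({"position_cM": self.positions_cM, "LR": self.lr}).to_csv(
            path, index=False, float_format="%.10g")

    def summary(self) -> dict:
        out = {"peak_position_cM": self.peak_position_cM, "peak_lr": self.peak_lr}
        if self.threshold is not None:
            out.update(threshold=float(self.threshold), alpha=self.alpha,
                       n_permutations=self.n_permutations, seed=self.seed,
                       significant=bool(self.significant))
        return out

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def plot(self, path: str | os.PathLike) -> None:
        """Write the LR profile (with threshold line, if any) as an image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.2))
        ax.plot(self.positions_cM, self.lr, "-o", ms=3, color="tab:blue")
        if self.threshold is not None:
            ax.axhline(self.threshold, ls="--", color="tab:red",
                       label=f"{100 * (1 - self.alpha):g}% permutation threshold")
            ax.legend(frameon=False)
        ax.set_xlabel("map position (cM)")
        ax.set_ylabel("LR")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def scan_grid(lmap: LinkageMap, step_cM: float = 1.0) -> np.ndarray:
    """Test positions: every marker plus a regular grid at ``step_cM``."""
    lo, hi = lmap.span
    grid = np.arange(lo, hi + 1e-9, step_cM)
    return np.unique(np.concatenate([grid, lmap.positions_cM]))


def _weights_per_position(genotypes: BackcrossGenotypes, lmap: LinkageMap,
                          positions: np.ndarray) -> np.ndarray:
    """(P, n, 2) stack of mixture-weight matrices, one per test position."""
    return np.stack([qtl_weights(genotypes, lmap, p).omega for p in positions])


def scan(Y, genotypes: BackcrossGenotypes, lmap: LinkageMap,
         grid: np.ndarray | None = None, step_cM: float = 1.0,
         tol: float = 1e-6, max_iter: int = 200) -> ScanResult:
    """LR profile of the two-genotype mixture over the test-position grid."""
    Ymat = _as_matrix(Y)
    positions = np.asarray(grid, dtype=float) if grid is not None \
        else scan_grid(lmap, step_cM)
    null = fit_null(Ymat)
    omegas = _weights_per_position(genotypes, lmap, positions)
    ll = fit_mixture_batch(Ymat, omegas, null=null, tol=tol, max_iter=max_iter)
    lr = np.maximum(2.0 * (ll - null[2]), 0.0)
    return ScanResult(positions_cM=positions, lr=lr)


def permutation_threshold(Y, genotypes: BackcrossGenotypes, lmap: LinkageMap,
                          grid: np.ndarray | None = None, step_cM: float = 1.0,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, tol: float = 1e-6,
                          max_iter: int = 200,
                          return_draws: bool = False,
                          perms: np.ndarray | None = None):
    """Genome-wide LR threshold from the permutation max-LR distribution.

    Whole phenotype rows are shuffled against the genotype rows (the map and
    the within-shape correlation stay intact), the scan is rerun for every
    permutation, and the empirical (1 - alpha) quantile (type 7, linear
    interpolation) of the max LR is returned.  Reproducible for a fixed seed.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm * alpha < 1:
        import warnings

        warnings.warn(f"{n_perm} permutations cannot resolve alpha={alpha}",
                      RuntimeWarning)
    Ymat = _as_matrix(Y)
    n = Ymat.shape[0]
    positions = np.asarray(grid, dtype=float) if grid is not None \
        else scan_grid(lmap, step_cM)
    null = fit_null(Ymat)  # invariant under row permutation
    omegas = _weights_per_position(genotypes, lmap, positions)  # (P, n, 2)
    if perms is None:
        rng = np.random.default_rng(seed)
        # Shuffling Y rows against genotypes is the same (in distribution) as
        # permuting every weight matrix's rows, which avoids copying Y.
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    else:
        perms = np.asarray(perms)
        n_perm = perms.shape[0]
    max_lr = np.zeros(n_perm)
    for p_idx in range(positions.size):
        omega_b = omegas[p_idx][perms]  # (n_perm, n, 2)
        ll = fit_mixture_batch(Ymat, omega_b, null=null, tol=tol,
                               max_iter=max_iter)
        np.maximum(max_lr, 2.0 * (ll - null[2]), out=max_lr)
    threshold = float(np.quantile(max_lr, 1.0 - alpha))
    if return_draws:
        return threshold, max_lr
    return threshold
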