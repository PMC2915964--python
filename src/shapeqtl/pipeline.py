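"""End-to-end orchestration: align -> embed -> scan -> test -> report.

`run_mapping` is the library entry point; the CLI wraps it.  Stage outputs
are plain text (CSV/JSON/PNG) and the phenotype matrix is computed once and
reused by the scan and all permutations — alignment plus distance transforms
are the expensive stages, while permutations only reshuffle rows.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .alignment import AlignConfig, AlignedShapeSet, align_shapes
from .genetics import BackcrossGenotypes, LinkageMap, qtl_weights
from .mixture import fit_null, log_density, run_em
from .scan import ScanResult, permutation_threshold, scan, scan_grid
from .sdf import build_phenotypes, reconstruct_shape
from .shape_image import ShapeSet, load_shape_set, save_shape
from .simulate import simulate_population, write_fixture

__all__ = ["RunConfig", "run_mapping", "dice", "load_inputs"]

log = logging.getLogger("shapeqtl")


@dataclass
class RunConfig:
    """Serializable settings for one mapping run."""

    align: bool = True
    align_tol: float = 1e-6
    align_max_iter: int = 500
    align_step0: float = 0.1
    smoothing_sigma: float = 1.0
    energy_normalized: bool = True
    reference_index: int = 0
    binarize_threshold: float = 0.5
    scan_step_cM: float = 1.0
    em_tol: float = 1e-6
    em_max_iter: int = 200
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def align_config(self) -> AlignConfig:
        return AlignConfig(normalized=self.energy_normalized, tol=self.align_tol,
                           max_iter=self.align_max_iter, step0=self.align_step0,
                           smoothing_sigma=self.smoothing_sigma,
                           reference_index=self.reference_index)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def dice(a, b) -> float:
    """Dice coefficient 2|A&B| / (|A| + |B|) between two binary shapes."""
    A = np.asarray(getattr(a, "pixels", a)).astype(bool)
    B = np.asarray(getattr(b, "pixels", b)).astype(bool)
    denom = A.sum() + B.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (A & B).sum() / denom)


def load_inputs(shapes_dir: str, map_path: str, genotypes_path: str,
                threshold: float = 0.5):
    """Read the fixture layout: a directory of shape rasters + map/genotype CSVs."""
    names = sorted(f for f in os.listdir(shapes_dir)
                   if f.lower().endswith((".png", ".pgm", ".txt")))
    shapes = load_shape_set([os.path.join(shapes_dir, f) for f in names],
                            threshold=threshold)
    lmap = LinkageMap.from_csv(map_path)
    genotypes = BackcrossGenotypes.from_csv(genotypes_path)
    if genotypes.n != shapes.n:
        raise ValueError(f"{genotypes.n} genotype rows but {shapes.n} shapes")
    # pair shapes with genotype rows by progeny id when both carry ids
    order = {pid: k for k, pid in enumerate(shapes.ids)}
    if set(genotypes.ids) == set(shapes.ids):
        idx = [order[pid] for pid in genotypes.ids]
        shapes = ShapeSet([shapes.images[k] for k in idx], list(genotypes.ids))
    return shapes, lmap, genotypes


def _stage(name: str, t0: float, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, kv)


def run_mapping(shapes: ShapeSet, lmap: LinkageMap,
                genotypes: BackcrossGenotypes, config: RunConfig | None = None,
                outdir: str | os.PathLike | None = None) -> dict:
    """Full mapping analysis of one population; returns a results dict.

    Keys: ``aligned`` (AlignedShapeSet), ``phenotypes`` (PhenotypeMatrix),
    ``scan`` (ScanResult with threshold when n_perm > 0), ``model`` (peak
    QTLMixtureModel), ``shape_qq``/``shape_qq2`` reconstructions, and
    ``densities`` (per-progeny log densities under each fitted component).
    """
    cfg = config or RunConfig()
    t0 = time.perf_counter()
    if cfg.align and shapes.n >= 2:
        aligned = align_shapes(shapes, cfg.align_config())
        _stage("align", t0, n=shapes.n, L=shapes.L,
               final_energy=f"{aligned.energy_trace[-1]:.4g}",
               iters=len(aligned.energy_trace) - 1)
    else:
        aligned = AlignedShapeSet(
            images=shapes.as_array().astype(float), poses=[],
            energy_trace=np.zeros(1), converged=True, ids=list(shapes.ids))
        _stage("align", t0, skipped=True)

    t0 = time.perf_counter()
    phenotypes = build_phenotypes(aligned, cfg.binarize_threshold)
    _stage("phenotypes", t0, n=phenotypes.n, m=phenotypes.m)

    t0 = time.perf_counter()
    grid = scan_grid(lmap, cfg.scan_step_cM)
    result = scan(phenotypes, genotypes, lmap, grid=grid, tol=cfg.em_tol,
                  max_iter=cfg.em_max_iter)
    _stage("scan", t0, positions=grid.size,
           peak_lr=f"{result.peak_lr:.3f}", peak_cM=result.peak_position_cM)

    if cfg.n_perm > 0:
        t0 = time.perf_counter()
        thr = permutation_threshold(
            phenotypes, genotypes, lmap, grid=grid, n_perm=cfg.n_perm,
            alpha=cfg.alpha, seed=cfg.seed, tol=cfg.em_tol,
            max_iter=cfg.em_max_iter)
        result = ScanResult(positions_cM=result.positions_cM, lr=result.lr,
                            threshold=thr, alpha=cfg.alpha,
                            n_permutations=cfg.n_perm, seed=cfg.seed)
        _stage("threshold", t0, n_perm=cfg.n_perm, alpha=cfg.alpha,
               threshold=f"{thr:.3f}", significant=result.significant)

    # refit at the peak to expose the genotype mean shapes and densities
    t0 = time.perf_counter()
    w_peak = qtl_weights(genotypes, lmap, result.peak_position_cM)
    model, state = run_em(phenotypes, w_peak, tol=cfg.em_tol,
                          max_iter=cfg.em_max_iter)
    mu0, s0, ll0 = fit_null(phenotypes)
    if model.loglik < ll0:  # same LR>=0 guard as the scan
        from .mixture import QTLMixtureModel

        model, state = run_em(
            phenotypes, w_peak,
            init=QTLMixtureModel(mu1=mu0, mu2=mu0.copy(), sigma2=s0),
            tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    shape_qq = reconstruct_shape(model.mu1, phenotypes.L)
    shape_qq2 = reconstruct_shape(model.mu2, phenotypes.L)
    densities = pd.DataFrame({
        "id": phenotypes.ids,
        "logf_QQ": [log_density(y, model.mu1, model.sigma2)
                    for y in phenotypes.values],
        "logf_Qq": [log_density(y, model.mu2, model.sigma2)
                    for y in phenotypes.values],
        "post_QQ": state.posteriors[:, 0],
    })
    _stage("refit", t0, peak_cM=result.peak_position_cM,
           sigma2=f"{model.sigma2:.4g}")

    out = {"aligned": aligned, "phenotypes": phenotypes, "scan": result,
           "model": model, "shape_qq": shape_qq, "shape_qq2": shape_qq2,
           "densities": densities}
    if outdir is not None:
        _write_artifacts(out, cfg, os.fspath(outdir))
    return out


def _write_artifacts(res: dict, cfg: RunConfig, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    aligned: AlignedShapeSet = res["aligned"]
    if aligned.poses:
        pd.DataFrame(
            [{"id": pid, "a": p.a, "b": p.b, "h": p.h, "theta": p.theta}
             for pid, p in zip(aligned.ids, aligned.poses)]
        ).assign(final_energy=aligned.energy_trace[-1]).to_csv(
            os.path.join(outdir, "alignment_report.csv"), index=False,
            float_format="%.10g")
    res["phenotypes"].to_csv(os.path.join(outdir, "phenotypes.csv"))
    result: ScanResult = res["scan"]
    result.to_csv(os.path.join(outdir, "scan.csv"))
    result.to_json(os.path.join(outdir, "summary.json"))
    try:
        result.plot(os.path.join(outdir, "scan.png"))
    except ImportError:
        pass  # plotting is optional
    res["model"].save(os.path.join(outdir, "genotype_means.csv"),
                      os.path.join(outdir, "model.json"))
    for name, shp in (("shape_QQ.png", res["shape_qq"]),
                      ("shape_Qq.png", res["shape_qq2"])):
        if shp is not None:
            save_shape(shp, os.path.join(outdir, name))
    res["densities"].to_csv(os.path.join(outdir, "densities.csv"), index=False,
                            float_format="%.10g")
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))


def cmd_simulate(scheme: str, n: int, L: int, seed: int, outdir: str,
                 sigma2: float = 1.0) -> None:
    pop = simulate_population(scheme=scheme, n=n, L=L, sigma2=sigma2, seed=seed)
    write_fixture(pop, outdir)
    log.info("stage=simulate scheme=%s n=%d L=%d seed=%d outdir=%s",
             scheme, n, L, seed, outdir)


def cmd_map(shapes_dir: str, map_path: str, genotypes_path: str, outdir: str,
            config: RunConfig | None = None) -> dict:
    shapes, lmap, genotypes = load_inputs(shapes_dir, map_path, genotypes_path)
    return run_mapping(shapes, lmap, genotypes, config, outdir=outdir)
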