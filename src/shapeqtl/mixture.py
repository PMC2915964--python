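"""Two-component multivariate-normal mixture over shape phenotypes, fitted by EM.

Each progeny's phenotype row Y_i (the vectorized signed distance map, length
m = L**2) is modeled as coming from QTL genotype QQ with prior weight
w_{1|i} or Qq with weight w_{2|i} (the flanking-marker conditional
probabilities):

    Y_i ~ w_{1|i} N(mu_1, sigma2 I) + w_{2|i} N(mu_2, sigma2 I)

with unstructured genotype means mu_j and a residual covariance shared by
both genotypes and all pixels, Sigma = sigma2 * I (pixel independence).  The
E-step computes posterior genotype probabilities by Bayes' rule; the M-step
updates the means as posterior-weighted averages and sigma2 as the pooled
posterior-weighted mean squared deviation.  All density arithmetic is done in
log space: with m in the thousands the raw densities underflow.

A batched variant fits many weight matrices against one shared phenotype
matrix simultaneously (BLAS-level operations); the permutation scan uses it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyComponentError
from .sdf import PhenotypeMatrix

__all__ = [
    "QTLMixtureModel", "EMState", "log_density", "mixture_loglik",
    "e_step", "m_step", "run_em", "fit_null", "init_from_weights",
]

SIGMA_FLOOR = 1e-12
_EMPTY_MASS = 1e-8


def _as_matrix(Y) -> np.ndarray:
    if isinstance(Y, PhenotypeMatrix):
        return Y.values
    return np.asarray(Y, dtype=float)


def _as_omega(w) -> np.ndarray:
    omega = np.asarray(getattr(w, "omega", w), dtype=float)
    if omega.ndim != 2 or omega.shape[1] != 2:
        raise ValueError("weights must form an (n, 2) matrix")
    if np.abs(omega.sum(axis=1) - 1.0).max() > 1e-9 or (omega < -1e-12).any():
        raise ValueError("each weight row must be nonnegative and sum to 1")
    return omega


@dataclass
class QTLMixtureModel:
    """Fitted genotype mean fields and the common residual variance."""

    mu1: np.ndarray
    mu2: np.ndarray
    sigma2: float
    loglik: float = np.nan

    def __post_init__(self) -> None:
        self.mu1 = np.asarray(self.mu1, dtype=float).ravel()
        self.mu2 = np.asarray(self.mu2, dtype=float).ravel()
        if self.mu1.size != self.mu2.size:
            raise ValueError("mu1 and mu2 must have equal length")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")

    @property
    def m(self) -> int:
        return self.mu1.size

    def save(self, csv_path, json_path) -> None:
        import json

        import pandas as pd

        pd.DataFrame({"index": np.arange(1, self.m + 1),
                      "mu1": self.mu1, "mu2": self.mu2}).to_csv(
            csv_path, index=False, float_format="%.12g")
        with open(json_path, "w") as fh:
            json.dump({"sigma2": float(self.sigma2),
                       "loglik": float(self.loglik)}, fh, indent=2)


@dataclass
class EMState:
    """Posterior probabilities and convergence diagnostics of one EM run."""

    posteriors: np.ndarray  # (n, 2)
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int


def log_density(y, mu, sigma2: float) -> float:
    """Log N(y | mu, sigma2 * I) = -(m/2) ln(2 pi sigma2) - ||y-mu||^2/(2 sigma2)."""
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    if y.size != mu.size:
        raise ValueError("y and mu must have equal length")
    m = y.size
    return float(-(m / 2.0) * np.log(2.0 * np.pi * sigma2)
                 - ((y - mu) ** 2).sum() / (2.0 * sigma2))


def _component_logf(Y: np.ndarray, model: QTLMixtureModel) -> np.ndarray:
    """(n, 2) log component densities, computed via squared-norm expansion."""
    m = Y.shape[1]
    mu = np.vstack([model.mu1, model.mu2])  # (2, m)
    d2 = ((Y * Y).sum(axis=1)[:, None]
          - 2.0 * Y @ mu.T + (mu * mu).sum(axis=1)[None, :])
    np.maximum(d2, 0.0, out=d2)
    return -(m / 2.0) * np.log(2.0 * np.pi * model.sigma2) - d2 / (2.0 * model.sigma2)


def _log_joint(Y: np.ndarray, omega: np.ndarray, model: QTLMixtureModel):
    with np.errstate(divide="ignore"):
        a = np.log(omega) + _component_logf(Y, model)  # (n, 2)
    ll_i = np.logaddexp(a[:, 0], a[:, 1])
    return a, ll_i


def mixture_loglik(Y, w, model: QTLMixtureModel) -> float:
    """Observed-data log-likelihood sum_i ln[w1 f1(Y_i) + w2 f2(Y_i)]."""
    Y = _as_matrix(Y)
    omega = _as_omega(w)
    _, ll_i = _log_joint(Y, omega, model)
    return float(ll_i.sum())


def e_step(Y, w, model: QTLMixtureModel) -> np.ndarray:
    """Posterior genotype probabilities by Bayes' rule (log-space normalized)."""
    Y = _as_matrix(Y)
    omega = _as_omega(w)
    a, ll_i = _log_joint(Y, omega, model)
    bad = ~np.isfinite(ll_i)
    if bad.any():
        raise FloatingPointError(
            f"zero mixture density for progeny index(es) {np.nonzero(bad)[0].tolist()}")
    return np.exp(a - ll_i[:, None])


def m_step(Y, posteriors) -> QTLMixtureModel:
    """Weighted-mean / pooled-variance updates given posterior probabilities."""
    Y = _as_matrix(Y)
    post = np.asarray(posteriors, dtype=float)
    n, m = Y.shape
    mass = post.sum(axis=0)  # (2,)
    if (mass < _EMPTY_MASS).any():
        j = int(np.argmin(mass))
        raise EmptyComponentError(
            f"component {j + 1} has total posterior mass {mass[j]:.3g}")
    mu = (post.T @ Y) / mass[:, None]  # (2, m)
    d2 = ((Y * Y).sum(axis=1)[:, None]
          - 2.0 * Y @ mu.T + (mu * mu).sum(axis=1)[None, :])
    np.maximum(d2, 0.0, out=d2)
    sigma2 = float((post * d2).sum() / (n * m))
    return QTLMixtureModel(mu1=mu[0], mu2=mu[1], sigma2=max(sigma2, SIGMA_FLOOR))


def init_from_weights(Y, w) -> QTLMixtureModel:
    """Deterministic init: hard-assign each progeny to its likelier genotype.

    Ties go to component 1 (QQ).  A component left empty by the assignment is
    initialized at the grand mean.
    """
    Y = _as_matrix(Y)
    omega = _as_omega(w)
    hard = np.column_stack([(omega[:, 0] >= 0.5).astype(float),
                            (omega[:, 0] < 0.5).astype(float)])
    mass = hard.sum(axis=0)
    grand = Y.mean(axis=0)
    mu = np.vstack([hard[:, j] @ Y / mass[j] if mass[j] > 0 else grand
                    for j in range(2)])
    resid = Y - np.where(hard[:, 0:1] > 0, mu[0], mu[1])
    sigma2 = max(float((resid ** 2).mean()), SIGMA_FLOOR)
    return QTLMixtureModel(mu1=mu[0], mu2=mu[1], sigma2=sigma2)


def run_em(Y, w, init: QTLMixtureModel | None = None, tol: float = 1e-6,
           max_iter: int = 200, _restarted: bool = False
           ) -> tuple[QTLMixtureModel, EMState]:
    """Alternate E and M steps until the log-likelihood change falls below tol.

    The trace is non-decreasing (EM ascent).  If a component empties mid-run
    the fit restarts once from a slightly perturbed init, then the error
    propagates.
    """
    Y = _as_matrix(Y)
    omega = _as_omega(w)
    model = init if init is not None else init_from_weights(Y, omega)
    trace: list[float] = []
    converged = False
    post = e_step(Y, omega, model)
    try:
        for _ in range(max_iter):
            a, ll_i = _log_joint(Y, omega, model)
            ll = float(ll_i.sum())
            post = np.exp(a - ll_i[:, None])
            if trace and abs(ll - trace[-1]) < tol:
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            new = m_step(Y, post)
            model = QTLMixtureModel(mu1=new.mu1, mu2=new.mu2, sigma2=new.sigma2)
    except EmptyComponentError:
        if _restarted:
            raise
        rng = np.random.default_rng(0)
        base = init if init is not None else init_from_weights(Y, omega)
        s = np.sqrt(base.sigma2)
        perturbed = QTLMixtureModel(
            mu1=base.mu1 + 0.1 * s * rng.standard_normal(base.m),
            mu2=base.mu2 - 0.1 * s * rng.standard_normal(base.m),
            sigma2=base.sigma2)
        return run_em(Y, omega, init=perturbed, tol=tol, max_iter=max_iter,
                      _restarted=True)
    model.loglik = trace[-1]
    return model, EMState(posteriors=post, loglik_trace=np.asarray(trace),
                          converged=converged, n_iter=len(trace) - 1)


def fit_null(Y) -> tuple[np.ndarray, float, float]:
    """Closed-form single-component MLE (no QTL): grand mean and total variance."""
    Y = _as_matrix(Y)
    n, m = Y.shape
    if n < 2:
        raise ValueError("need at least two progeny")
    mu0 = Y.mean(axis=0)
    sigma2_0 = max(float(((Y - mu0) ** 2).mean()), SIGMA_FLOOR)
    loglik0 = float(-(n * m / 2.0) * np.log(2.0 * np.pi * sigma2_0)
                    - ((Y - mu0) ** 2).sum() / (2.0 * sigma2_0))
    return mu0, sigma2_0, loglik0


# ---------------------------------------------------------------------------
# Batched EM: many weight matrices against one shared phenotype matrix.
# ---------------------------------------------------------------------------

def _batch_hard_init(Y: np.ndarray, omega: np.ndarray):
    """Vectorized init_from_weights for a (B, n, 2) weight stack."""
    B, n, _ = omega.shape
    m = Y.shape[1]
    hard = np.empty((B, 2, n))
    hard[:, 0] = (omega[:, :, 0] >= 0.5).astype(float)
    hard[:, 1] = 1.0 - hard[:, 0]
    mass = hard.sum(axis=2)  # (B, 2)
    grand = Y.mean(axis=0)
    weights = hard / np.maximum(mass, 1.0)[:, :, None]
    mu = (weights.reshape(B * 2, n) @ Y).reshape(B, 2, m)
    mu[mass < 0.5] = grand
    # pooled variance under the hard assignment
    ynorm = (Y * Y).sum(axis=1)
    cross = (mu.reshape(B * 2, m) @ Y.T).reshape(B, 2, n)
    musq = (mu * mu).sum(axis=2)
    d2 = np.maximum(ynorm[None, None, :] - 2.0 * cross + musq[:, :, None], 0.0)
    sigma2 = np.maximum((hard * d2).sum(axis=(1, 2)) / (n * m), SIGMA_FLOOR)
    return mu, sigma2


def _em_batch_core(Y: np.ndarray, omega: np.ndarray, mu: np.ndarray,
                   sigma2: np.ndarray, tol: float, max_iter: int):
    """EM on B datasets sharing Y; returns (loglik, mu, sigma2, n_iter).

    A component whose posterior mass vanishes keeps its previous mean (it then
    contributes nothing to the likelihood), so degenerate scan positions where
    all progeny share one genotype reduce gracefully to the null fit.
    """
    B, n, _ = omega.shape
    m = Y.shape[1]
    ynorm = (Y * Y).sum(axis=1)
    with np.errstate(divide="ignore"):
        logw = np.log(omega.transpose(0, 2, 1))  # (B, 2, n)
    mu = mu.copy()
    sigma2 = sigma2.copy()
    ll = np.full(B, -np.inf)
    n_iter = np.zeros(B, dtype=int)
    active = np.arange(B)
    cross = (mu.reshape(B * 2, m) @ Y.T).reshape(B, 2, n)
    for it in range(max_iter):
        idx = active
        if idx.size == 0:
            break
        musq = (mu[idx] * mu[idx]).sum(axis=2)
        d2 = np.maximum(ynorm[None, None, :] - 2.0 * cross[idx]
                        + musq[:, :, None], 0.0)
        logf = (-(m / 2.0) * np.log(2.0 * np.pi * sigma2[idx]))[:, None, None] \
            - d2 / (2.0 * sigma2[idx])[:, None, None]
        a = logw[idx] + logf  # (b, 2, n)
        ll_i = np.logaddexp(a[:, 0], a[:, 1])  # (b, n)
        ll_new = ll_i.sum(axis=1)
        post = np.exp(a - ll_i[:, None, :])  # (b, 2, n)
        done = np.abs(ll_new - ll[idx]) < tol
        ll[idx] = ll_new
        n_iter[idx] = it
        if done.any():
            active = idx[~done]
            keep = ~done
            post, d2 = post[keep], d2[keep]
            idx = active
            if idx.size == 0:
                break
        # M-step
        b = idx.size
        mass = post.sum(axis=2)  # (b, 2)
        ok = mass >= _EMPTY_MASS
        weights = post / np.maximum(mass, _EMPTY_MASS)[:, :, None]
        mu_new = (weights.reshape(b * 2, n) @ Y).reshape(b, 2, m)
        mu_idx = mu[idx]
        mu_idx[ok] = mu_new[ok]
        mu[idx] = mu_idx
        cross_idx = (mu[idx].reshape(b * 2, m) @ Y.T).reshape(b, 2, n)
        cross[idx] = cross_idx
        musq = (mu[idx] * mu[idx]).sum(axis=2)
        d2_new = np.maximum(ynorm[None, None, :] - 2.0 * cross_idx
                            + musq[:, :, None], 0.0)
        sigma2[idx] = np.maximum((post * d2_new).sum(axis=(1, 2)) / (n * m),
                                 SIGMA_FLOOR)
    return ll, mu, sigma2, n_iter


def fit_mixture_batch(Y, omega_batch: np.ndarray, null: tuple | None = None,
                      tol: float = 1e-6, max_iter: int = 200) -> np.ndarray:
    """Maximized mixture log-likelihood for each weight matrix in a stack.

    ``omega_batch`` has shape (B, n, 2).  Each dataset is fitted from the
    deterministic hard-assignment init; any fit that lands below the
    single-component log-likelihood is refitted from the null solution
    (mu1 = mu2 = mu0), whose EM path can only ascend from loglik0 — so the
    returned log-likelihoods never fall below the null's.
    """
    Y = _as_matrix(Y)
    omega = np.asarray(omega_batch, dtype=float)
    if omega.ndim == 2:
        omega = omega[None]
    mu0, s0, ll0 = null if null is not None else fit_null(Y)
    mu_init, s_init = _batch_hard_init(Y, omega)
    ll, _, _, _ = _em_batch_core(Y, omega, mu_init, s_init, tol, max_iter)
    retry = np.nonzero(ll < ll0 - 1e-9)[0]
    if retry.size:
        B2 = retry.size
        mu_null = np.broadcast_to(mu0, (B2, 2, mu0.size)).copy()
        s_null = np.full(B2, s0)
        ll2, _, _, _ = _em_batch_core(Y, omega[retry], mu_null, s_null,
                                      tol, max_iter)
        ll[retry] = np.maximum(ll[retry], ll2)
    return np.maximum(ll, ll0)
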