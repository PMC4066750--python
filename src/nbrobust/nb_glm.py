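"""Negative binomial GLM fitting by Fisher scoring, with observation weights.

Counts follow ``Y_gi ~ NB(mu_gi, phi_g)`` with ``var = mu + phi mu^2`` and a
log link ``log mu_gi = x_i' beta_g + log N_i``.  Coefficients are estimated
by iteratively reweighted least squares (IRLS): with working weights
``Omega = diag(mu/(1+phi mu))`` and score residuals
``z = (y-mu)/(1+phi mu)``, the update is

    beta_new = beta_old + (X' [W Omega] X)^{-1} X' [W] z

where ``W`` is the diagonal matrix of per-observation weights in (0, 1].
Unit weights reproduce the classical fit; a zero weight removes an
observation from both the score and the Fisher information, which is exactly
observation deletion.

All fitting is vectorized across features: every feature shares the design
but carries its own dispersion, offset row and weight row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import CountMatrix, DesignMatrix

__all__ = ["GLMFit", "ObservationWeights", "nb_log_likelihood", "irls_fit", "fitted_log_fold_changes"]

_MIN_MU = 1e-8
_MAX_ETA = 60.0
_POISSON_PHI = 1e-12


@dataclass
class GLMFit:
    """Per-feature regression results from a (weighted) NB GLM fit."""

    coefficients: np.ndarray  # G x p
    fitted_means: np.ndarray  # G x n
    log_likelihood: np.ndarray  # G (weighted when weights supplied)
    working_weights: np.ndarray  # G x n, mu/(1+phi mu)
    score_residuals: np.ndarray  # G x n, (y-mu)/(1+phi mu)
    fisher_log_det: np.ndarray  # G, log |X'[W Omega]X|
    converged: np.ndarray  # G bool
    iterations: np.ndarray  # G int


@dataclass
class ObservationWeights:
    """Per-observation weights ``w_gi`` in (0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.values, dtype=float)
        if np.any(w < 0) or np.any(w > 1) or not np.all(np.isfinite(w)):
            raise ValueError("observation weights must lie in [0, 1]")
        self.values = w


def _loglik_rows(y: np.ndarray, mu: np.ndarray, phi: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    """Row sums of (weighted) NB log-pmf terms; phi below ~1e-12 uses the Poisson limit."""
    phi_col = phi[:, None] if phi.ndim == 1 else phi
    pois = phi_col <= _POISSON_PHI
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_safe = np.where(pois, 1.0, phi_col)
        r = 1.0 / phi_safe
        ll_nb = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + y * np.log(phi_safe * mu / (1.0 + phi_safe * mu))
            - r * np.log1p(phi_safe * mu)
        )
        ll_pois = y * np.log(mu) - mu - gammaln(y + 1.0)
    ll = np.where(pois, ll_pois, ll_nb)
    if w is not None:
        ll = ll * w
    return ll.sum(axis=1)


def nb_log_likelihood(y, mu, phi: float, weights=None) -> float:
    """(Weighted) NB log-likelihood of one feature's count vector.

    ``phi = 0`` is the Poisson limit.  Each observation's log-pmf is
    multiplied by its weight; unit weights give the plain log-likelihood.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)) or not np.all(np.isfinite(y)):
        raise ValueError("means must be positive and inputs finite")
    w = None if weights is None else np.atleast_1d(np.asarray(weights, dtype=float))[None, :]
    return float(_loglik_rows(y[None, :], mu[None, :], np.array([phi]), w)[0])


def _initial_beta(y: np.ndarray, X: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """One-step linearized start: least squares of log((y+0.5)/N) on X."""
    t = np.log(y + 0.5) - offsets
    beta, *_ = np.linalg.lstsq(X, t.T, rcond=None)
    return beta.T


def irls_fit(
    counts,
    design,
    offsets: np.ndarray,
    dispersions: np.ndarray,
    weights=None,
    max_iter: int = 50,
    tol: float = 1e-6,
    beta_init: np.ndarray | None = None,
) -> GLMFit:
    """Fit one NB GLM per feature by Fisher scoring with optional weights.

    Parameters
    ----------
    counts : CountMatrix or (G, n) array
    design : DesignMatrix or (n, p) array shared by all features
    offsets : (n,) or (G, n) natural-log effective library sizes
    dispersions : (G,) non-negative NB dispersions, one per feature
    weights : ObservationWeights or (G, n) array, optional
    beta_init : warm start for the coefficients, optional

    A feature is converged when the max-norm of its weighted score
    ``X'[W]z`` falls below ``tol``.  Steps that decrease the weighted
    log-likelihood are halved (up to 10 times).  Features with a singular
    weighted information matrix keep their last stable coefficients and are
    flagged unconverged.
    """
    y = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    X = design.values if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(dispersions, dtype=float), (G,)).copy()
    if np.any(phi < 0):
        raise ValueError("dispersions must be non-negative")
    offsets = np.asarray(offsets, dtype=float)
    off = np.broadcast_to(offsets, (G, n)) if offsets.ndim <= 1 else offsets
    if weights is None:
        w = np.ones((G, n))
    else:
        w = weights.values if isinstance(weights, ObservationWeights) else np.asarray(weights, dtype=float)
        w = np.broadcast_to(w, (G, n))

    beta = _initial_beta(y, X, off) if beta_init is None else np.array(beta_init, dtype=float)

    def mu_of(b: np.ndarray) -> np.ndarray:
        eta = np.clip(b @ X.T + off, np.log(_MIN_MU), _MAX_ETA)
        return np.exp(eta)

    mu = mu_of(beta)
    ll = _loglik_rows(y, mu, phi, w)
    converged = np.zeros(G, dtype=bool)
    failed = np.zeros(G, dtype=bool)
    iterations = np.zeros(G, dtype=int)
    phi_col = phi[:, None]

    for _ in range(max_iter):
        active = ~(converged | failed)
        if not np.any(active):
            break
        ya, mua, wa = y[active], mu[active], w[active]
        pa = phi_col[active]
        denom = 1.0 + pa * mua
        z = (ya - mua) / denom
        score = (wa * z) @ X
        newly_conv = np.max(np.abs(score), axis=1) < tol
        idx_active = np.flatnonzero(active)
        converged[idx_active[newly_conv]] = True
        still = ~newly_conv
        if not np.any(still):
            break
        idx = idx_active[still]
        ya, mua, wa, pa = ya[still], mua[still], wa[still], pa[still]
        score = score[still]
        om = wa * mua / (1.0 + pa * mua)
        info = np.einsum("gn,np,nq->gpq", om, X, X)
        try:
            delta = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.zeros_like(score)
            for k in range(info.shape[0]):
                try:
                    delta[k] = np.linalg.solve(info[k], score[k])
                except np.linalg.LinAlgError:
                    failed[idx[k]] = True
        bad = ~np.all(np.isfinite(delta), axis=1)
        delta[bad] = 0.0
        failed[idx[bad]] = True

        # step-halving keeps the weighted likelihood non-decreasing
        step = np.ones(len(idx))
        beta_old = beta[idx]
        ll_old = ll[idx]
        for _half in range(11):
            beta_try = beta_old + step[:, None] * delta
            eta = np.clip(beta_try @ X.T + off[idx], np.log(_MIN_MU), _MAX_ETA)
            mu_try = np.exp(eta)
            ll_try = _loglik_rows(y[idx], mu_try, phi[idx], w[idx])
            worse = ll_try < ll_old - 1e-10
            if not np.any(worse):
                break
            step[worse] *= 0.5
        beta[idx] = beta_old + step[:, None] * delta
        eta = np.clip(beta[idx] @ X.T + off[idx], np.log(_MIN_MU), _MAX_ETA)
        mu[idx] = np.exp(eta)
        ll[idx] = _loglik_rows(y[idx], mu[idx], phi[idx], w[idx])
        iterations[idx] += 1

    # final check for features that converged exactly at max_iter
    denom = 1.0 + phi_col * mu
    z = (y - mu) / denom
    score = (w * z) @ X
    converged |= np.max(np.abs(score), axis=1) < tol
    converged &= ~failed

    om = w * mu / denom
    info = np.einsum("gn,np,nq->gpq", om, X, X)
    sign, logdet = np.linalg.slogdet(info)
    fisher_log_det = np.where(sign > 0, logdet, -np.inf)
    ll = _loglik_rows(y, mu, phi, w)
    return GLMFit(
        coefficients=beta,
        fitted_means=mu,
        log_likelihood=ll,
        working_weights=mu / denom,
        score_residuals=z,
        fisher_log_det=fisher_log_det,
        converged=converged,
        iterations=iterations,
    )


def fitted_log_fold_changes(fit: GLMFit, design: DesignMatrix) -> np.ndarray:
    """Coefficients of interest on the log2 scale (reported log-fold-changes)."""
    cols = design.coef_of_interest
    return fit.coefficients[:, cols] / np.log(2.0)
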