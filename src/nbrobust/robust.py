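"""Observation-weight robustification of the NB GLM pipeline.

Outlying counts are down-weighted smoothly rather than removed: Pearson
residuals from the current fit pass through the Huber weight function

    w(r) = 1            if |r| <= k
    w(r) = k / |r|      if |r| >  k

and the weights feed the next round of dispersion estimation and GLM
fitting.  The loop runs a fixed number of iterations (default six); with
replication of at least three samples per condition the scheme dampens the
influence of single extreme observations on both the fold-change and the
dispersion estimates while losing little efficiency on clean data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CountMatrix, DesignMatrix, LibrarySizeSet
from .dispersion import DispersionConfig, DispersionEstimates, tagwise_dispersion
from .nb_glm import GLMFit, ObservationWeights, irls_fit

__all__ = [
    "RobustConfig",
    "RobustResult",
    "pearson_residuals",
    "deviance_residuals",
    "huber_weights",
    "estimate_robust",
    "outlier_scores",
]


@dataclass
class RobustConfig:
    """Settings for the re-weighted estimation loop.

    ``tuning_constant`` is the Huber ``k`` (1.345 gives 95% efficiency in
    the Gaussian location problem); ``n_iterations`` is the fixed stopping
    rule; ``weight_floor`` optionally bounds weights away from zero to guard
    the information matrix rank at tiny sample sizes.
    """

    tuning_constant: float = 1.345
    n_iterations: int = 6
    residual_type: str = "pearson"
    weight_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.tuning_constant <= 0:
            raise ValueError("tuning_constant must be positive")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.residual_type not in ("pearson", "deviance"):
            raise ValueError("residual_type must be 'pearson' or 'deviance'")


@dataclass
class IterationState:
    """Snapshot of one robust iteration for trend/weight diagnostics."""

    iteration: int
    tagwise: np.ndarray
    trended: np.ndarray
    abundance: np.ndarray
    weights: np.ndarray  # weights produced by this iteration's residuals


@dataclass
class RobustResult:
    fit: GLMFit
    dispersion: DispersionEstimates
    weights: ObservationWeights
    trace: list[IterationState] = field(default_factory=list)


def pearson_residuals(counts, fit: GLMFit, dispersions: np.ndarray) -> np.ndarray:
    """Pearson residuals ``(y - mu) / sqrt(mu (1 + phi mu))``."""
    y = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    mu = fit.fitted_means
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError("fitted means must be finite and positive")
    phi = np.asarray(dispersions, dtype=float)[:, None]
    return (y - mu) / np.sqrt(mu * (1.0 + phi * mu))


def deviance_residuals(counts, fit: GLMFit, dispersions: np.ndarray) -> np.ndarray:
    """Signed square-root NB unit deviances (alternative residual choice)."""
    y = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    mu = fit.fitted_means
    phi = np.asarray(dispersions, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylog = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        nb = 2.0 * (ylog - (y + 1.0 / np.where(phi > 0, phi, 1.0)) * np.log((1.0 + phi * y) / (1.0 + phi * mu)))
        pois = 2.0 * (ylog - (y - mu))
    dev = np.where(phi > 0, nb, pois)
    dev = np.maximum(dev, 0.0)
    return np.sign(y - mu) * np.sqrt(dev)


def huber_weights(residuals: np.ndarray, k: float = 1.345) -> ObservationWeights:
    """Huber weights ``min(1, k/|r|)``; the identity region is inclusive at ``|r| = k``."""
    if k <= 0:
        raise ValueError("tuning constant must be positive")
    r = np.abs(np.asarray(residuals, dtype=float))
    with np.errstate(divide="ignore"):
        w = np.where(r > k, k / r, 1.0)
    return ObservationWeights(np.minimum(w, 1.0))


def _group_sizes(design: DesignMatrix) -> np.ndarray | None:
    X = design.values
    if X.shape[1] < 1 or not np.all(np.isin(X, (0.0, 1.0))):
        return None
    if not np.allclose(X[:, 0], 1.0):
        return None
    sizes = X[:, 1:].sum(axis=0)
    return np.concatenate([[X.shape[0] - sizes.sum()], sizes])


def estimate_robust(
    counts: CountMatrix,
    design: DesignMatrix,
    libs: LibrarySizeSet | None = None,
    disp_cfg: DispersionConfig | None = None,
    robust_cfg: RobustConfig | None = None,
) -> RobustResult:
    """Iterative re-weighted estimation of dispersions and coefficients.

    Each iteration (1) re-estimates trended and moderated tagwise
    dispersions with the current observation weights, (2) fits the weighted
    GLM at those dispersions, (3) computes residuals and (4) converts them
    to Huber weights for the next iteration.  Initial weights are all one,
    and the returned weights are those produced by the final fit's
    residuals.  The trace records per-iteration dispersions, abundances and
    weights for trend-trajectory diagnostics.
    """
    disp_cfg = disp_cfg or DispersionConfig()
    robust_cfg = robust_cfg or RobustConfig()
    if libs is None:
        libs = LibrarySizeSet.from_counts(counts)
    sizes = _group_sizes(design)
    if sizes is not None and np.any(sizes < 3) and len(sizes) > 1:
        warnings.warn(
            "fewer than three samples in some condition; robust down-weighting "
            "has limited leverage below three replicates per group",
            stacklevel=2,
        )
    offsets = libs.offsets
    G, n = counts.values.shape
    w = np.ones((G, n))
    trace: list[IterationState] = []
    residual_fn = pearson_residuals if robust_cfg.residual_type == "pearson" else deviance_residuals

    fit = None
    disp = None
    for t in range(1, robust_cfg.n_iterations + 1):
        disp = tagwise_dispersion(counts, design, offsets, weights=w, cfg=disp_cfg)
        fit = irls_fit(counts, design, offsets, disp.tagwise, weights=w)
        r = residual_fn(counts, fit, disp.tagwise)
        w_next = huber_weights(r, robust_cfg.tuning_constant).values
        if robust_cfg.weight_floor > 0:
            w_next = np.maximum(w_next, robust_cfg.weight_floor)
        trace.append(
            IterationState(
                iteration=t,
                tagwise=disp.tagwise.copy(),
                trended=disp.trended.copy(),
                abundance=disp.abundance.copy(),
                weights=w_next.copy(),
            )
        )
        w = w_next

    return RobustResult(fit=fit, dispersion=disp, weights=ObservationWeights(w), trace=trace)


def outlier_scores(weights, residuals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outlier evidence per observation and per feature.

    The observation score is ``1 - w`` with ties (notably the untouched
    ``w = 1`` block) broken by residual magnitude; the feature score is the
    maximum over its observations.  Larger means more outlying, suitable for
    ROC evaluation against a truth mask.
    """
    w = weights.values if isinstance(weights, ObservationWeights) else np.asarray(weights, dtype=float)
    r = np.abs(np.asarray(residuals, dtype=float))
    if w.shape != r.shape:
        raise ValueError("weights and residuals must have the same shape")
    obs = (1.0 - w) + 1e-9 * r / (1.0 + r)
    return obs, obs.max(axis=1)
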