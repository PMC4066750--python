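"""Dispersion estimation via the Cox-Reid adjusted profile likelihood (APL).

For feature *g* the APL at candidate dispersion ``phi`` is

    APL_g(phi) = l(phi; y_g, beta_hat_g) - 1/2 log |I_g|

where ``beta_hat_g`` is the coefficient vector refitted at that ``phi`` and
``I_g`` the Fisher information; the penalty corrects the profile likelihood
for the estimated regression coefficients.  With observation weights both
the log-likelihood and the information are weighted, so down-weighted
observations lose influence on the dispersion as well as on the fit.

Three estimators share this objective:

* common — maximize the APL averaged over all features;
* trended — common dispersions in equal-occupancy abundance bins, smoothed
  against average log-CPM (the dispersion-mean trend);
* moderated tagwise — per feature, maximize the feature's own APL plus
  ``prior_df`` times the mean APL of its abundance neighbours, which shrinks
  individual estimates toward the local trend.

Everything is evaluated on a shared log-spaced dispersion grid with
warm-started coefficient refits, then refined off-grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import CountMatrix, DesignMatrix, LibrarySizeSet
from .nb_glm import ObservationWeights, irls_fit
from .normalization import average_log_cpm

__all__ = [
    "DispersionConfig",
    "DispersionEstimates",
    "adjusted_profile_likelihood",
    "apl_profile",
    "maximize_apl",
    "common_dispersion",
    "trended_dispersion",
    "tagwise_dispersion",
]

_PHI_FLOOR = 1e-6


@dataclass
class DispersionConfig:
    """Tuning knobs for dispersion estimation.

    ``prior_df`` is the weight given to the shared (local) likelihood when
    moderating tagwise estimates; ``common_weight`` plays the same role for
    shrinkage toward the global common dispersion.  ``neighbor_window``
    defaults to ``max(50, ceil(0.05 G))`` nearest features by abundance.
    """

    prior_df: float = 10.0
    common_weight: float = 20.0
    n_bins: int = 20
    neighbor_window: int | None = None
    grid_min: float = 1e-6
    grid_max: float = 100.0
    grid_points: int = 201
    trend_span: float = 0.5
    inner_max_iter: int = 25
    residual_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.prior_df < 0:
            raise ValueError("prior_df must be non-negative")
        if not (0 < self.grid_min < self.grid_max):
            raise ValueError("grid bounds must be positive and increasing")

    def grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.grid_min), np.log10(self.grid_max), self.grid_points)

    def window(self, n_features: int) -> int:
        if self.neighbor_window is not None:
            return min(int(self.neighbor_window), n_features)
        return min(max(50, int(np.ceil(0.05 * n_features))), n_features)


@dataclass
class DispersionEstimates:
    """Common, trended and moderated tagwise dispersions with the trend curve."""

    common: float
    trended: np.ndarray
    tagwise: np.ndarray
    trend_curve: Callable[[np.ndarray], np.ndarray]
    abundance: np.ndarray
    config: DispersionConfig = field(default_factory=DispersionConfig)

    @property
    def bcv(self) -> np.ndarray:
        """Biological coefficient of variation, sqrt(phi)."""
        return np.sqrt(self.tagwise)


def _as_arrays(counts, design, weights):
    y = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    X = design.values if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    if weights is None:
        w = None
    else:
        w = weights.values if isinstance(weights, ObservationWeights) else np.asarray(weights, dtype=float)
    return y, X, w


def _apl_at(y, X, off, phi_vec, w, max_iter=25, beta_init=None):
    """APL value per feature at a per-feature dispersion vector.

    Returns ``(apl, beta)``; a singular information matrix gives -inf.
    Fits that merely hit the iteration cap contribute their achieved value.
    """
    fit = irls_fit(y, X, off, phi_vec, weights=w, max_iter=max_iter, beta_init=beta_init)
    apl = fit.log_likelihood - 0.5 * fit.fisher_log_det
    apl = np.where(np.isfinite(fit.fisher_log_det), apl, -np.inf)
    return apl, fit.coefficients


def adjusted_profile_likelihood(y, design, offsets, phi: float, weights=None) -> float:
    """Cox-Reid APL of a single feature at one candidate dispersion.

    Refits the coefficients at ``phi`` (weighted IRLS) and returns the
    weighted log-likelihood minus half the log-determinant of the weighted
    Fisher information.  A non-convergent refit returns ``-inf``.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = design.values if isinstance(design, DesignMatrix) else np.asarray(design, dtype=float)
    w = None if weights is None else np.atleast_2d(np.asarray(weights, dtype=float))
    fit = irls_fit(y, X, np.asarray(offsets, dtype=float), np.array([phi]), weights=w, max_iter=50)
    if not fit.converged[0] or not np.isfinite(fit.fisher_log_det[0]):
        return -np.inf
    return float(fit.log_likelihood[0] - 0.5 * fit.fisher_log_det[0])


def apl_profile(y, X, offsets, grid: np.ndarray, weights=None, inner_max_iter: int = 25) -> np.ndarray:
    """APL of every feature at every grid dispersion (``G x K`` matrix).

    The grid is scanned in ascending order and each candidate's coefficient
    refit warm-starts from the previous candidate's solution, which keeps the
    scan cheap: after the first grid point most refits converge in a couple
    of Fisher-scoring steps.
    """
    G = y.shape[0]
    K = len(grid)
    out = np.empty((G, K))
    beta = None
    for j, phi in enumerate(grid):
        phi_vec = np.full(G, phi)
        it = inner_max_iter * 2 if j == 0 else inner_max_iter
        out[:, j], beta = _apl_at(y, X, offsets, phi_vec, weights, max_iter=it, beta_init=beta)
    return out


def _golden_max(f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximization on log-dispersion in [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log(lo), np.log(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(np.exp(c)), f(np.exp(d))
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(np.exp(d))
    return float(np.exp((a + b) / 2.0))


def maximize_apl(objective, grid: np.ndarray, refine: bool = True) -> tuple[float, bool]:
    """Maximize a dispersion objective: grid argmax plus golden-section refinement.

    ``objective`` is either a callable ``phi -> value`` or a precomputed
    vector of grid values (in which case no off-grid refinement happens
    unless a callable is also available).  Returns ``(phi, estimable)``;
    ``estimable`` is False when the objective is -inf everywhere or the
    argmax sits on the grid boundary.
    """
    grid = np.asarray(grid, dtype=float)
    if callable(objective):
        values = np.array([objective(p) for p in grid])
        f = objective
    else:
        values = np.asarray(objective, dtype=float)
        f = None
    if not np.any(np.isfinite(values)):
        return float(grid[0]), False
    j = int(np.nanargmax(np.where(np.isfinite(values), values, -np.inf)))
    if j == 0 or j == len(grid) - 1:
        return float(grid[j]), False
    if refine and f is not None:
        return _golden_max(f, grid[j - 1], grid[j + 1]), True
    return float(grid[j]), True


def _parabolic_refine(values: np.ndarray, grid: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Vertex of the parabola through the grid argmax and its neighbours (log-phi scale)."""
    lg = np.log(grid)
    G = values.shape[0]
    rows = np.arange(G)
    interior = (j > 0) & (j < len(grid) - 1)
    out = grid[j].astype(float).copy()
    ji = j[interior]
    ri = rows[interior]
    x0, x1, x2 = lg[ji - 1], lg[ji], lg[ji + 1]
    y0, y1, y2 = values[ri, ji - 1], values[ri, ji], values[ri, ji + 1]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vert = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / denom
    ok = np.isfinite(vert) & (vert >= x0) & (vert <= x2)
    refined = np.where(ok, np.exp(vert), grid[ji])
    out[interior] = refined
    return out


def common_dispersion(counts, design, offsets, weights=None, cfg: DispersionConfig | None = None) -> float:
    """Dispersion maximizing the APL averaged over all features."""
    cfg = cfg or DispersionConfig()
    y, X, w = _as_arrays(counts, design, weights)
    grid = cfg.grid()
    apl = apl_profile(y, X, offsets, grid, w, cfg.inner_max_iter)
    mean_apl = apl.mean(axis=0)

    def objective(phi: float) -> float:
        vals, _ = _apl_at(y, X, offsets, np.full(y.shape[0], phi), w, max_iter=cfg.inner_max_iter * 2)
        return float(vals.mean())

    j = int(np.argmax(mean_apl))
    if j == 0 or j == len(grid) - 1:
        return float(grid[j])
    return _golden_max(objective, grid[j - 1], grid[j + 1])


def _equal_occupancy_bins(abundance: np.ndarray, n_bins: int) -> list[np.ndarray]:
    order = np.argsort(abundance, kind="stable")
    return [b for b in np.array_split(order, n_bins) if b.size]


def _fit_trend(bin_ab: np.ndarray, bin_phi: np.ndarray, span: float) -> Callable[[np.ndarray], np.ndarray]:
    """Loess-style smooth of log-dispersion against abundance, flat beyond the range."""
    log_phi = np.log(np.maximum(bin_phi, _PHI_FLOOR))
    if np.ptp(bin_ab) < 1e-9:  # degenerate: every bin at the same abundance
        const = float(np.exp(np.mean(log_phi)))

        def flat(a: np.ndarray) -> np.ndarray:
            return np.full(np.shape(a), max(const, _PHI_FLOOR), dtype=float)

        return flat
    if len(bin_ab) >= 4:
        sm = lowess(log_phi, bin_ab, frac=span, it=0, return_sorted=True)
        xs, ys = sm[:, 0], sm[:, 1]
    else:
        xs, ys = np.sort(bin_ab), log_phi[np.argsort(bin_ab)]

    def curve(a: np.ndarray) -> np.ndarray:
        return np.maximum(np.exp(np.interp(np.asarray(a, dtype=float), xs, ys)), _PHI_FLOOR)

    return curve


def _trend_from_profile(
    apl: np.ndarray, abundance: np.ndarray, grid: np.ndarray, cfg: DispersionConfig
) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray]:
    G = apl.shape[0]
    if G < cfg.n_bins:
        warnings.warn("fewer features than trend bins; using the common dispersion everywhere", stacklevel=3)
        mean_apl = apl.mean(axis=0)
        j = np.array([int(np.argmax(mean_apl))])
        phi_c = _parabolic_refine(mean_apl[None, :], grid, j)[0]
        curve = lambda a: np.full(np.shape(a), max(phi_c, _PHI_FLOOR), dtype=float)  # noqa: E731
        return curve, curve(abundance)
    bins = _equal_occupancy_bins(abundance, cfg.n_bins)
    bin_ab = np.array([abundance[b].mean() for b in bins])
    bin_mean = np.stack([apl[b].mean(axis=0) for b in bins])
    j = np.argmax(np.where(np.isfinite(bin_mean), bin_mean, -np.inf), axis=1)
    bin_phi = _parabolic_refine(bin_mean, grid, j)
    curve = _fit_trend(bin_ab, bin_phi, cfg.trend_span)
    return curve, curve(abundance)


def trended_dispersion(counts, design, offsets, weights=None, cfg: DispersionConfig | None = None):
    """Dispersion-mean trend: per-bin common dispersions smoothed over abundance.

    Returns ``(trend_curve, trended)`` with the curve evaluated at every
    feature's average log-CPM and floored at 1e-6.
    """
    cfg = cfg or DispersionConfig()
    y, X, w = _as_arrays(counts, design, weights)
    grid = cfg.grid()
    abundance = _abundance(counts, offsets, w)
    apl = apl_profile(y, X, offsets, grid, w, cfg.inner_max_iter)
    return _trend_from_profile(apl, abundance, grid, cfg)


def _abundance(counts, offsets, w) -> np.ndarray:
    y = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    off = np.asarray(offsets, dtype=float)
    eff = np.exp(off if off.ndim == 1 else off[0])
    cm = CountMatrix(np.round(y), None, None) if not isinstance(counts, CountMatrix) else counts
    libs = LibrarySizeSet(eff)
    return average_log_cpm(cm, libs, weights=w)


def tagwise_dispersion(
    counts,
    design,
    offsets,
    weights=None,
    cfg: DispersionConfig | None = None,
    shrink_to: str = "trend",
) -> DispersionEstimates:
    """Moderated tagwise dispersions (and the common + trended estimates).

    Per feature the objective is ``APL_g(phi) + prior_df * APL_S(phi)``
    where ``APL_S`` averages the APL over the feature's abundance
    neighbourhood (``shrink_to='trend'``) or over all features weighted by
    ``common_weight`` (``shrink_to='common'``, the older global-shrinkage
    strategy).  The per-feature argmax on the shared grid is refined by
    parabolic interpolation on the log-dispersion scale.
    """
    cfg = cfg or DispersionConfig()
    if shrink_to not in ("trend", "common"):
        raise ValueError("shrink_to must be 'trend' or 'common'")
    y, X, w = _as_arrays(counts, design, weights)
    G = y.shape[0]
    grid = cfg.grid()
    abundance = _abundance(counts, offsets, w)
    apl = apl_profile(y, X, offsets, grid, w, cfg.inner_max_iter)
    apl_f = np.where(np.isfinite(apl), apl, np.nan)
    col_mean = np.nanmean(apl_f, axis=0)

    # common dispersion from the shared profile
    jc = int(np.argmax(col_mean))
    common = float(_parabolic_refine(col_mean[None, :], grid, np.array([jc]))[0])

    trend_curve, trended = _trend_from_profile(apl, abundance, grid, cfg)

    if shrink_to == "common":
        shared = np.broadcast_to(col_mean, apl.shape)
        gamma = cfg.common_weight
    else:
        shared = _local_shared_apl(apl, abundance, cfg.window(G))
        gamma = cfg.prior_df

    objective = np.nan_to_num(apl, nan=-np.inf, neginf=-1e300) + gamma * shared
    j = np.argmax(objective, axis=1)
    tagwise = _parabolic_refine(objective, grid, j)
    tagwise = np.maximum(tagwise, _PHI_FLOOR)

    return DispersionEstimates(
        common=common,
        trended=trended,
        tagwise=tagwise,
        trend_curve=trend_curve,
        abundance=abundance,
        config=cfg,
    )


def _local_shared_apl(apl: np.ndarray, abundance: np.ndarray, window: int) -> np.ndarray:
    """Mean APL over each feature's abundance neighbourhood (window truncated at edges)."""
    G, K = apl.shape
    order = np.argsort(abundance, kind="stable")
    sorted_apl = np.nan_to_num(apl[order], nan=-1e300, neginf=-1e300)
    csum = np.vstack([np.zeros((1, K)), np.cumsum(sorted_apl, axis=0)])
    m = min(window, G)
    half = m // 2
    ranks = np.empty(G, dtype=int)
    ranks[order] = np.arange(G)
    lo = np.clip(ranks - half, 0, G - m)
    means = (csum[lo + m] - csum[lo]) / m
    return means
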