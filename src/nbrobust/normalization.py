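"""Library-size normalization and abundance summaries.

TMM (trimmed mean of M-values) computes a per-sample scaling factor as the
precision-weighted, doubly-trimmed mean of feature-wise log-ratios against a
reference sample, which absorbs composition bias into the effective library
size.  CPM and average log-CPM provide library-size-normalized abundances;
the log forms use a library-size-proportional prior count for stability at
zero counts.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import CountMatrix, LibrarySizeSet

__all__ = ["tmm_factors", "cpm", "average_log_cpm"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one sample against the reference sample."""
    pos = (obs > 0) & (ref > 0)
    if not np.any(pos):
        warnings.warn("sample shares no expressed features with the reference; factor set to 1", stacklevel=3)
        return 0.0
    o, r = obs[pos], ref[pos]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # delta-method binomial variance of M; inverse is the precision weight
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 0.0

    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = np.empty(n)
    rank_m[np.argsort(m, kind="stable")] = np.arange(1, n + 1)
    rank_a = np.empty(n)
    rank_a[np.argsort(a, kind="stable")] = np.arange(1, n + 1)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        warnings.warn("TMM trimming removed every feature for one sample; factor set to 1", stacklevel=3)
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> LibrarySizeSet:
    """TMM normalization factors and effective library sizes.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.  For each sample,
    30% of M-values and 5% of A-values are trimmed from each tail, and the
    remaining M-values are averaged with inverse delta-method variances as
    weights.  Factors are geometric-mean centred so their product is one.
    """
    y = counts.values
    lib = counts.library_sizes
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive total count")
    f75 = np.array([np.quantile(y[:, i] / lib[i], 0.75) for i in range(counts.n_samples)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log2f = np.array(
        [
            0.0 if i == ref else _tmm_pair(y[:, i], y[:, ref], lib[i], lib[ref], trim_m, trim_a)
            for i in range(counts.n_samples)
        ]
    )
    factors = 2.0 ** log2f
    factors /= np.exp(np.mean(np.log(factors)))
    return LibrarySizeSet(lib, factors)


def cpm(
    counts: CountMatrix,
    libs: LibrarySizeSet | None = None,
    log: bool = False,
    prior_count: float = 2.0,
) -> np.ndarray:
    """Counts per million, linear or log2 with a library-proportional prior.

    On the log scale the prior count for sample *i* is
    ``prior_count * effective_i / mean(effective)`` and the library is
    enlarged by twice that prior, so zero counts map to a finite value and
    relative abundances remain comparable across depths.
    """
    if libs is None:
        libs = LibrarySizeSet.from_counts(counts)
    eff = libs.effective_sizes
    y = counts.values
    if not log:
        return y / eff[None, :] * 1e6
    if prior_count < 0:
        raise ValueError("prior_count must be non-negative")
    if prior_count == 0 and np.any(y == 0):
        raise ValueError("log-CPM with prior_count=0 is undefined at zero counts")
    pc = prior_count * eff / eff.mean()
    return np.log2((y + pc[None, :]) / (eff + 2 * pc)[None, :] * 1e6)


def average_log_cpm(
    counts: CountMatrix,
    libs: LibrarySizeSet | None = None,
    prior_count: float = 2.0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-feature abundance: log2 of the (weighted) mean prior-adjusted CPM.

    This is the x-axis for the dispersion-mean trend and for power
    stratification.  Optional observation weights (``G x n``) give the robust
    loop a down-weighted abundance estimate.
    """
    if libs is None:
        libs = LibrarySizeSet.from_counts(counts)
    eff = libs.effective_sizes
    pc = prior_count * eff / eff.mean()
    adj = (counts.values + pc[None, :]) / (eff + 2 * pc)[None, :] * 1e6
    if weights is None:
        mean_cpm = adj.mean(axis=1)
    else:
        w = np.asarray(weights, dtype=float)
        mean_cpm = (adj * w).sum(axis=1) / w.sum(axis=1)
    return np.log2(mean_cpm)
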