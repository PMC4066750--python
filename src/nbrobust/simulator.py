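"""NB count simulation with empirically-shaped parameters and outlier injection.

Datasets are simulated from ``Y_gi ~ NB(mu_gi, phi_g)`` where the joint
(mean, dispersion) pairs are resampled from a *parameter seed*.  A seed can
be estimated from a user-supplied real count table, or synthesized from a
configurable dispersion-mean trend ``phi(mu) = d0 + a/mu`` with
multiplicative lognormal noise, emulating the decreasing BCV-versus-
abundance shape seen in real RNA-seq datasets.  Seeds are filtered to drop
extreme dispersions and very low means before resampling, analogous to the
count filters applied in real analyses.

Differential expression is injected by multiplying one group's mean by a
fold factor for a fixed fraction of features (half up, half down by
default).  Outliers are added by three mechanisms:

* S (simple): a feature is selected with probability ``p_outlier`` and one
  random observation is multiplied by a factor drawn uniformly in the
  configured range;
* R (random): every observation is independently inflated with probability
  ``p_outlier``;
* M (model): every observation is independently replaced, with probability
  ``p_outlier``, by a draw from a second NB with mean multiplied by the
  factor.  R and M induce the same overall outlier rate by construction.

Clean and outlier-injected counts are recorded separately, together with
the truth labels and the outlier mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CountMatrix, DesignMatrix, LibrarySizeSet, make_group_design

__all__ = [
    "SimulationConfig",
    "ParameterSeed",
    "SimulatedDataset",
    "synthesize_seed",
    "load_seed_from_estimates",
    "filter_seed",
    "simulate_counts",
    "inject_outliers",
    "simulate",
]


@dataclass
class SimulationConfig:
    """Simulation settings (feature count, DE proportion/size, outliers)."""

    n_tags: int = 10000
    group_sizes: tuple[int, ...] = (5, 5)
    p_diff: float = 0.1
    fold_diff: float | tuple[float, float] = 3.0
    p_up: float = 0.5
    p_outlier: float = 0.1
    outlier_mech: str = "S"
    outlier_factor_range: tuple[float, float] = (1.5, 10.0)
    library_size_range: tuple[float, float] = (8e6, 12e6)
    seed: int = 0
    disp_filter_quantile: float = 0.10
    low_mean_filter: float = 10.0  # min expected count at the reference depth

    def __post_init__(self) -> None:
        for name in ("p_diff", "p_up", "p_outlier"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.outlier_factor_range
        if lo < 1.0 or hi < lo:
            raise ValueError("outlier factors must satisfy 1 <= lo <= hi")
        if self.outlier_mech not in ("S", "R", "M", "none"):
            raise ValueError("outlier_mech must be one of S, R, M, none")
        if self.n_tags < 1 or any(s < 1 for s in self.group_sizes):
            raise ValueError("need at least one feature and one sample per group")

    @property
    def groups(self) -> list[str]:
        return [f"grp{j + 1}" for j, s in enumerate(self.group_sizes) for _ in range(s)]


@dataclass
class ParameterSeed:
    """(relative abundance, dispersion) pairs to resample simulation parameters from."""

    abundances: np.ndarray  # relative abundance per feature (arbitrary scale)
    dispersions: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        d = np.asarray(self.dispersions, dtype=float)
        if a.shape != d.shape or a.ndim != 1:
            raise ValueError("abundances and dispersions must be matching vectors")
        if np.any(a <= 0) or np.any(d < 0):
            raise ValueError("abundances must be positive and dispersions non-negative")
        self.abundances, self.dispersions = a, d

    @property
    def n_pairs(self) -> int:
        return self.abundances.size


@dataclass
class SimulatedDataset:
    clean_counts: CountMatrix
    truth_de: np.ndarray  # {"none","up","down"} per feature
    fold_change: np.ndarray  # realized fold factor (1 for non-DE)
    true_mu: np.ndarray  # G x n
    true_phi: np.ndarray  # G
    library_sizes: np.ndarray
    groups: list[str]
    outlier_counts: CountMatrix | None = None
    outlier_mask: np.ndarray | None = None
    config: SimulationConfig = field(default_factory=SimulationConfig)

    @property
    def counts(self) -> CountMatrix:
        """The analysis input: outlier-injected counts when present, else clean."""
        return self.outlier_counts if self.outlier_counts is not None else self.clean_counts

    def design(self) -> DesignMatrix:
        return make_group_design(self.groups)

    @property
    def is_de(self) -> np.ndarray:
        return self.truth_de != "none"


def synthesize_seed(
    n_pairs: int = 5000,
    trend_params: tuple[float, float] = (0.15, 2.0),
    noise_sd: float = 0.4,
    seed: int | None = None,
    lcpm_shape: float = 2.0,
    lcpm_scale: float = 2.0,
    reference_depth: float = 1e7,
) -> ParameterSeed:
    """Synthetic parameter seed with a dispersion-mean trend.

    Abundances are right-skewed on the log2-CPM scale (a shifted gamma);
    dispersions follow ``phi = d0 + a/mu`` — evaluated at the expected count
    for a reference sequencing depth — times lognormal noise with standard
    deviation ``noise_sd`` on the log scale.
    """
    if n_pairs < 100:
        raise ValueError("need at least 100 parameter pairs")
    rng = np.random.default_rng(seed)
    d0, a = trend_params
    lcpm = 0.5 + rng.gamma(lcpm_shape, lcpm_scale, size=n_pairs)
    rel = 2.0 ** lcpm / 1e6
    mu_bar = rel * reference_depth
    trend = d0 + a / mu_bar
    noise = np.exp(rng.normal(0.0, noise_sd, size=n_pairs)) if noise_sd > 0 else 1.0
    return ParameterSeed(rel, trend * noise, provenance="synthetic-trend")


def load_seed_from_estimates(counts: CountMatrix, groups=None, design: DesignMatrix | None = None) -> ParameterSeed:
    """Estimate a parameter seed from a real count table.

    Runs the non-robust estimation pipeline (TMM, trended + moderated
    tagwise dispersion) and extracts (average CPM, tagwise dispersion)
    pairs.
    """
    from .dispersion import tagwise_dispersion
    from .normalization import tmm_factors

    if design is None:
        if groups is not None:
            design = make_group_design(groups)
        else:  # intercept-only when no grouping is supplied
            design = DesignMatrix(np.ones((counts.n_samples, 1)), ["intercept"], [])
    libs = tmm_factors(counts)
    disp = tagwise_dispersion(counts, design, libs.offsets)
    rel = 2.0 ** disp.abundance / 1e6
    return ParameterSeed(rel, disp.tagwise, provenance="estimated")


def filter_seed(
    seed: ParameterSeed,
    disp_filter_quantile: float = 0.10,
    low_mean_filter: float = 0.0,
    reference_depth: float = 1e7,
) -> ParameterSeed:
    """Drop extreme-dispersion and low-mean pairs before resampling.

    Removes pairs whose dispersion exceeds the ``1 - q`` quantile and whose
    expected count at the reference depth falls below ``low_mean_filter``.
    """
    if not 0.0 <= disp_filter_quantile < 1.0:
        raise ValueError("disp_filter_quantile must be in [0, 1)")
    keep = np.ones(seed.n_pairs, dtype=bool)
    if disp_filter_quantile > 0:
        thr = np.quantile(seed.dispersions, 1.0 - disp_filter_quantile)
        keep &= seed.dispersions <= thr
    if low_mean_filter > 0:
        keep &= seed.abundances * reference_depth >= low_mean_filter
    return ParameterSeed(seed.abundances[keep], seed.dispersions[keep], seed.provenance + "+filtered")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) deviates; phi = 0 falls back to Poisson."""
    phi = np.broadcast_to(phi, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if np.any(pois):
        out[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        size = 1.0 / phi[~pois]
        p = size / (size + mu[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def simulate_counts(cfg: SimulationConfig, seed_params: ParameterSeed) -> SimulatedDataset:
    """Simulate clean NB counts with injected differential expression.

    Exactly ``floor(p_diff * n_tags)`` features are differentially
    expressed, ``floor(p_up * n_DE)`` of them up (group 2 mean multiplied by
    the fold factor) and the rest down (group 1 mean multiplied instead).
    Fold factors are fixed or drawn uniformly from an interval.  Library
    sizes are uniform in ``library_size_range`` and ``mu_gi`` is
    proportional to relative abundance times library size.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_tags
    groups = cfg.groups
    n = len(groups)
    group_idx = np.array([int(g[3:]) - 1 for g in groups])

    pick = rng.integers(0, seed_params.n_pairs, size=G)
    # abundances stay on the seed's counts-per-library scale so that a
    # feature's expected count is abundance x library size; renormalizing to
    # a unit simplex would deflate every mean whenever the resampled tail is
    # heavy and recreate the near-zero features the seed filter removed
    rel = seed_params.abundances[pick].astype(float)
    phi = seed_params.dispersions[pick].astype(float)

    n_de = int(np.floor(cfg.p_diff * G))
    if cfg.p_diff > 0 and n_de < 1:
        warnings.warn("p_diff * n_tags < 1: no DE features generated", stacklevel=2)
    n_up = int(np.floor(cfg.p_up * n_de))
    de_idx = rng.choice(G, size=n_de, replace=False)
    truth = np.full(G, "none", dtype=object)
    truth[de_idx[:n_up]] = "up"
    truth[de_idx[n_up:]] = "down"

    if isinstance(cfg.fold_diff, (tuple, list)):
        lo, hi = cfg.fold_diff
        fold = np.ones(G)
        fold[de_idx] = rng.uniform(lo, hi, size=n_de)
    else:
        fold = np.where(truth != "none", float(cfg.fold_diff), 1.0)

    lib = rng.uniform(*cfg.library_size_range, size=n)
    mu = rel[:, None] * lib[None, :]
    up = truth == "up"
    down = truth == "down"
    # up: higher mean in group 2; down: higher mean in group 1
    mu[np.ix_(up, group_idx == 1)] *= fold[up][:, None]
    mu[np.ix_(down, group_idx == 0)] *= fold[down][:, None]

    y = _nb_draw(rng, mu, phi[:, None])
    counts = CountMatrix(y, [f"g{g + 1}" for g in range(G)], [f"{grp}_s{i + 1}" for i, grp in enumerate(groups)])
    ds = SimulatedDataset(
        clean_counts=counts,
        truth_de=truth.astype(str),
        fold_change=fold,
        true_mu=mu,
        true_phi=phi,
        library_sizes=lib,
        groups=groups,
        config=cfg,
    )
    return ds


def inject_outliers(dataset: SimulatedDataset, cfg: SimulationConfig | None = None, rng=None) -> SimulatedDataset:
    """Fill ``outlier_counts`` and ``outlier_mask`` according to the mechanism.

    The mask records every position selected for injection (whether or not
    the integer count changed, e.g. a zero multiplied by a factor).
    """
    cfg = cfg or dataset.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 1)))
    y = dataset.clean_counts.values.copy()
    G, n = y.shape
    mask = np.zeros((G, n), dtype=bool)
    lo, hi = cfg.outlier_factor_range

    if cfg.outlier_mech == "S" and cfg.p_outlier > 0:
        chosen = rng.random(G) < cfg.p_outlier
        cols = rng.integers(0, n, size=G)
        factors = rng.uniform(lo, hi, size=G)
        rows = np.flatnonzero(chosen)
        mask[rows, cols[rows]] = True
        y[rows, cols[rows]] = np.floor(y[rows, cols[rows]] * factors[rows] + 0.5)
    elif cfg.outlier_mech == "R" and cfg.p_outlier > 0:
        mask = rng.random((G, n)) < cfg.p_outlier
        factors = rng.uniform(lo, hi, size=(G, n))
        y[mask] = np.floor(y[mask] * factors[mask] + 0.5)
    elif cfg.outlier_mech == "M" and cfg.p_outlier > 0:
        mask = rng.random((G, n)) < cfg.p_outlier
        factors = rng.uniform(lo, hi, size=(G, n))
        mu2 = dataset.true_mu * factors
        redraw = _nb_draw(rng, mu2, dataset.true_phi[:, None])
        y[mask] = redraw[mask]

    out = CountMatrix(y, list(dataset.clean_counts.feature_ids), list(dataset.clean_counts.sample_ids))
    return replace(dataset, outlier_counts=out, outlier_mask=mask)


def simulate(cfg: SimulationConfig, seed_params: ParameterSeed | None = None) -> SimulatedDataset:
    """Seed (synthetic unless supplied), filter, simulate and inject outliers."""
    if seed_params is None:
        seed_params = synthesize_seed(seed=cfg.seed)
    seed_params = filter_seed(seed_params, cfg.disp_filter_quantile, cfg.low_mean_filter)
    ds = simulate_counts(cfg, seed_params)
    if cfg.outlier_mech != "none" and cfg.p_outlier > 0:
        ds = inject_outliers(ds, cfg)
    else:
        ds = replace(
            ds,
            outlier_counts=ds.clean_counts,
            outlier_mask=np.zeros(ds.clean_counts.values.shape, dtype=bool),
        )
    return ds
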