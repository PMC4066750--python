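"""Weighted likelihood-ratio testing and downstream inference.

The LRT compares nested weighted NB GLM fits sharing the same moderated
dispersions and observation weights: ``LR = 2 (l_full - l_reduced)`` is
referred to a chi-squared distribution with as many degrees of freedom as
coefficients dropped.  With observation weights, likelihood-ratio statistics
retain their approximate chi-squared null distribution, so no degrees-of-
freedom correction is applied.

Also here: Benjamini-Hochberg adjustment and a hypergeometric enrichment
test of per-sample down-weighted gene sets against functional categories,
used to ask whether the outliers in one sample share biology (or a
technical artefact such as GC-content bias).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix, DesignMatrix, LibrarySizeSet
from .nb_glm import ObservationWeights, fitted_log_fold_changes, irls_fit
from .normalization import average_log_cpm

__all__ = ["lrt", "bh_adjust", "down_weighted_sets", "category_enrichment", "write_results"]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment; NaN entries are preserved
    and excluded from the number of tests."""
    p = np.asarray(p_values, dtype=float)
    fdr = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return fdr
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    fdr[ok] = adj
    return fdr


def lrt(
    counts: CountMatrix,
    full_design: DesignMatrix,
    reduced_design: DesignMatrix,
    dispersions: np.ndarray,
    weights=None,
    libs: LibrarySizeSet | None = None,
    na_policy: str = "exclude",
) -> pd.DataFrame:
    """Per-feature weighted likelihood-ratio tests of nested designs.

    Both models are fitted with the same dispersions and observation
    weights.  Features whose full or reduced fit fails to converge get an
    NA p-value; ``na_policy='exclude'`` drops them from the BH adjustment,
    ``na_policy='one'`` sets them to 1 instead (parity option with pipelines
    that never drop features).

    Returns a data frame with columns feature_id, logFC, aveLogCPM, LR, df,
    PValue, FDR, min_weight, n_downweighted, status.
    """
    if na_policy not in ("exclude", "one"):
        raise ValueError("na_policy must be 'exclude' or 'one'")
    if libs is None:
        libs = LibrarySizeSet.from_counts(counts)
    offsets = libs.offsets
    phi = np.asarray(dispersions, dtype=float)
    w = None
    if weights is not None:
        w = weights.values if isinstance(weights, ObservationWeights) else np.asarray(weights, dtype=float)

    full = irls_fit(counts, full_design, offsets, phi, weights=w)
    reduced = irls_fit(counts, reduced_design, offsets, phi, weights=w)
    df = full_design.n_coefficients - reduced_design.n_coefficients
    if df < 0:
        raise ValueError("reduced design has more coefficients than the full design")

    lr = np.maximum(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    # identical designs: a zero-df test carries no evidence
    p = stats.chi2.sf(lr, df) if df > 0 else np.ones_like(lr)
    ok = full.converged & reduced.converged
    status = np.where(ok, "ok", "not_converged")
    if na_policy == "exclude":
        p = np.where(ok, p, np.nan)
        lr_rep = np.where(ok, lr, np.nan)
    else:
        p = np.where(ok, p, 1.0)
        lr_rep = lr

    lfc = fitted_log_fold_changes(full, full_design)
    lfc1 = lfc[:, 0] if lfc.shape[1] else np.zeros(counts.n_features)
    w_used = np.ones_like(counts.values) if w is None else w
    table = pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "logFC": lfc1,
            "aveLogCPM": average_log_cpm(counts, libs),
            "LR": lr_rep,
            "df": df,
            "PValue": p,
            "FDR": bh_adjust(p),
            "min_weight": w_used.min(axis=1),
            "n_downweighted": (w_used < 1.0).sum(axis=1),
            "status": status,
        }
    )
    return table


def down_weighted_sets(
    weights, feature_ids: list[str], sample_ids: list[str], cutoff: float = 1.0
) -> dict[str, set[str]]:
    """Per-sample sets of features whose weight in that sample falls below ``cutoff``."""
    w = weights.values if isinstance(weights, ObservationWeights) else np.asarray(weights, dtype=float)
    return {
        sample_ids[i]: {feature_ids[g] for g in np.flatnonzero(w[:, i] < cutoff)}
        for i in range(w.shape[1])
    }


def category_enrichment(
    selected_sets: dict[str, set[str]],
    categories: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each selected set in each category.

    For sample selection of size ``n`` from a universe of size ``M``
    containing ``K`` category members, the p-value is
    ``P(overlap >= observed)``.  Empty categories get p = 1 and a flag.
    """
    M = len(universe)
    rows = []
    for sample, selected in selected_sets.items():
        sel = selected & universe
        for cat, members in categories.items():
            mem = members & universe
            K, n_sel = len(mem), len(sel)
            overlap = len(sel & mem)
            if K == 0:
                rows.append((sample, cat, 0, 0, n_sel, 1.0, "empty_category"))
                continue
            p = float(stats.hypergeom.sf(overlap - 1, M, K, n_sel))
            rows.append((sample, cat, overlap, K, n_sel, min(p, 1.0), "ok"))
    return pd.DataFrame(
        rows, columns=["sample", "category", "overlap", "category_size", "selected_size", "PValue", "status"]
    )


def write_results(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a results table as TSV, optionally with a leading ``#`` comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA")
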