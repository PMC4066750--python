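# nbrobust

Outlier-robust differential expression for count-based sequencing data
(bulk or single-cell RNA-seq), built on a negative binomial GLM with
per-observation weights.

## The problem

Count-based DE methods share information across features — most notably by
moderating per-feature dispersion estimates toward a dispersion–mean trend —
to gain power at small sample sizes. That sharing has a cost: a single
aberrant count can simultaneously distort a feature's fold-change estimate
*and* drag its moderated dispersion below its honest value, producing
confident false discoveries; in sufficient numbers, outliers shift the whole
trend. `nbrobust` dampens outliers smoothly instead of discarding features.

## The model

Counts follow `Y_gi ~ NB(mu_gi, phi_g)` with `var = mu + phi mu^2` and a log
link `log mu_gi = x_i' beta_g + log N_i`, where `N_i` is the TMM-normalized
effective library size. Estimation couples:

* **Weighted IRLS** — Fisher scoring
  `beta <- beta + (X'[W Omega]X)^{-1} X'[W]z` with working weights
  `Omega = diag(mu/(1+phi mu))`, score residuals `z = (y-mu)/(1+phi mu)`
  and observation weights `W`;
* **Weighted Cox–Reid adjusted profile likelihood** for the dispersion,
  `APL(phi) = l_W(phi; y, beta_hat) - 1/2 log|X'[W Omega]X|`, maximized on a
  log-spaced grid to give common, trended (binned + loess) and moderated
  tagwise estimates (`argmax APL_g + prior_df * mean APL over abundance
  neighbours`);
* **Huber down-weighting** — Pearson residuals
  `r = (y - mu)/sqrt(mu(1+phi mu))` are converted to weights
  `w = min(1, k/|r|)` with `k = 1.345`, which feed the next round of
  dispersion estimation and fitting. Six fixed iterations are used.
* **Weighted likelihood-ratio tests** of nested designs against a
  chi-squared null, with Benjamini–Hochberg adjustment.

The package also ships the matching NB count **simulator** (empirically
shaped dispersion–mean parameter seeds; DE injection; S/R/M outlier
mechanisms), an **evaluation battery** (FD curves, partial ROC, power and
achieved FDP at nominal FDR cutoffs, outlier-position strata), and a
hypergeometric enrichment test for per-sample down-weighted gene sets.

## Worked example

```python
import numpy as np
from nbrobust import SimulationConfig, run_de
from nbrobust.simulator import simulate

cfg = SimulationConfig(n_tags=500, group_sizes=(5, 5), p_diff=0.1,
                       fold_diff=3.0, p_outlier=0.1, outlier_mech="S", seed=42)
ds = simulate(cfg)                       # 10% DE at fold 3; 10% of features
res = run_de(ds.counts, groups=ds.groups)  # get one inflated observation

print(res.table.sort_values("PValue").head(5)[
    ["feature_id", "logFC", "aveLogCPM", "LR", "PValue", "FDR", "min_weight"]
].to_string(index=False))
```

```
feature_id     logFC  aveLogCPM        LR       PValue          FDR  min_weight
       g75  2.122516   8.423634 36.741742 1.348607e-09 6.743034e-07    0.954001
       g87 -1.968414   4.079389 31.818798 1.692468e-08 1.964592e-06    1.000000
       g32 -2.038948  13.697976 31.768133 1.737198e-08 1.964592e-06    0.459127
      g345  2.277055   2.568291 31.728032 1.773439e-08 1.964592e-06    1.000000
      g214  1.985830   7.705642 31.407129 2.092113e-08 1.964592e-06    0.503317
```

`logFC` is the tested coefficient on the log2 scale, `aveLogCPM` the
abundance used for trend fitting, `LR` the weighted likelihood-ratio
statistic, and `min_weight` the smallest observation weight in the row —
g32 and g214 each contained an observation down-weighted to ~0.5 yet remain
confidently DE on the strength of the other samples. Summaries from the same
run:

```
down-weighted observations: 12.1%
trended dispersion, first -> final iteration: 0.204 -> 0.160
features declared DE at 5% FDR: 46 (truly DE among them: 45)
```

The drop in the mean trended dispersion is the global effect of removing
outlier influence from the trend; 46 declarations with 45 true positives is
an achieved false-discovery proportion of ~2% at the 5% nominal cutoff.

## Command line

```sh
nbrobust de --counts counts.tsv --groups groups.tsv --out-prefix out   # DE analysis
nbrobust simulate --n-tags 10000 --p-outlier 0.1 --out-prefix sim      # simulator
nbrobust benchmark --config grid.yaml --seed 1 --out metrics.tsv       # method grid
```

`--no-robust` runs the classical (unit-weight) pipeline; `--k` and
`--iterations` expose the Huber constant and the fixed iteration count.

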