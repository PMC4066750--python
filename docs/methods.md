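# Methods

## Model and estimation

Counts are modelled as `Y_gi ~ NB(mu_gi, phi_g)` with variance
`mu + phi mu^2`; `sqrt(phi)` is the biological coefficient of variation
(BCV). The mean is linked to a linear predictor through
`log mu_gi = x_i' beta_g + log N_i` with the effective library size `N_i`
as offset. Coefficients are estimated by Fisher scoring (IRLS); with
observation weights `W = diag(w_gi)`, both the score `X'[W]z` and the
information `X'[W Omega]X` are weighted, so a weight of zero is exactly
observation deletion and unit weights reproduce the classical fit (the two
paths are the same code).

IRLS details: coefficients start from a least-squares fit of
`log((y+0.5)/N)` on the design; convergence is a weighted-score max-norm
below 1e-6 with a 50-iteration cap; steps that lower the weighted likelihood
are halved up to 10 times (Fisher scoring can overshoot when `phi mu` is
large). The linear predictor is clamped to keep `mu` in
`[1e-8, exp(60)]`; all-zero features ride the lower clamp and are flagged.
A singular weighted information matrix flags the feature unconverged and
keeps the last stable coefficients; downstream tests report NA for flagged
features and exclude them from the BH denominator (an option reassigns
p = 1 instead, for parity with pipelines that never drop features).

## Dispersion estimation

The Cox–Reid adjusted profile likelihood
`APL_g(phi) = l(phi; y_g, beta_hat_g) - 1/2 log |I_g|` corrects the profile
likelihood for the estimated coefficients; with weights, `l` and `I` are
both weighted. Every estimator works from one `G x 201` matrix of APL
values on a log-spaced grid `[1e-6, 100]`, scanned in ascending order with
the coefficient refit warm-started from the previous candidate (inner cap
25 iterations; the first grid point gets 50). An inner refit that merely
hits its cap contributes its achieved value — a hard `-inf` would poison
every bin and neighbourhood average that includes the feature — while a
singular information matrix does yield `-inf`.

* **Common**: argmax of the feature-averaged APL, refined by golden-section
  on log-phi within the bracketing grid interval.
* **Trended**: features are split into 20 equal-occupancy bins by average
  log-CPM; each bin's common dispersion (parabolic refinement of the grid
  argmax) is smoothed by lowess on log-dispersion versus abundance with
  span 0.5 and interpolated at each feature's abundance (flat beyond the
  fitted range, floor 1e-6). Fewer features than bins falls back to the
  common dispersion with a warning.
* **Moderated tagwise**: per feature, argmax of
  `APL_g(phi) + prior_df * APL_S(phi)` where `APL_S` averages the APL over
  the `max(50, 0.05 G)` nearest features by abundance (window truncated at
  the edges, the feature itself included). `prior_df` defaults to 10.
  Refinement is parabolic on the log-phi grid: golden-section per feature
  would require a full neighbourhood refit per probe, and the parabolic
  vertex through three grid points is accurate to a fraction of the grid
  spacing for these smooth, locally quadratic objectives (verified against
  a 10x finer grid in the tests). Shrinkage toward the single global common
  dispersion is available as an alternative mode but is not the default.

## The robust loop

Each of a fixed number of iterations (default six — convergence is not
tested, most features stabilize within a few passes):

1. trended + moderated tagwise dispersions with the current weights;
2. weighted GLM fit at those dispersions;
3. Pearson residuals `r = (y - mu)/sqrt(mu(1 + phi mu))` (a signed-deviance
   alternative is available; Pearson is the default);
4. Huber weights `w = min(1, k/|r|)`, `k = 1.345`, feeding the next pass.

Initial weights are all one; the returned weights come from the final fit's
residuals, and the per-iteration trace (dispersions, abundances, weights)
supports trend-trajectory diagnostics. TMM factors are computed once from
the raw counts and not revisited after down-weighting. Below three
replicates per condition a warning is raised — with two, a single outlier
cannot be told apart from a group effect, the limit of any robust procedure.

With `k = 1.345`, roughly the 13–18% tail of near-Gaussian Pearson
residuals falls outside the identity region even on clean data; that
down-weighting is mild (weights below 0.5 are ~1% of observations) and the
robust and classical log-fold-changes remain tightly correlated (~0.97 and
median absolute difference < 0.05 on clean simulations). An optional weight
floor guards the information-matrix rank at very small n (default off).

Inference: `LR = 2(l_W,full - l_W,reduced)`, both fits sharing the same
moderated dispersions (not re-estimated under the null) and weights,
referred to chi-squared with the difference in coefficient count as degrees
of freedom; no df correction is applied for the weighting, relying on the
standard weighted-likelihood asymptotics. Identical designs give p = 1.

## Normalization

TMM: the reference sample minimizes the distance of its 75th-percentile
count fraction from the mean of those; per sample, log2 ratios (M) and mean
log2 abundances (A) over features expressed in both sample and reference
are doubly trimmed (30% of M, 5% of A, each tail) and averaged with inverse
delta-method binomial variances as weights; factors are geometric-mean
centred. Verified against an independent brute-force transcription of the
algorithm; exact scale invariance does not hold (the precision weights are
depth-dependent by construction) but factors agree to <0.5% under pure
depth changes. Log-CPM uses a library-proportional prior count (default 2)
with the library enlarged by twice the prior; average log-CPM is the log2
of the (optionally weight-averaged) prior-adjusted CPM across samples.

## Simulator

Parameter pairs (relative abundance, dispersion) are resampled with
replacement from a seed. The synthetic seed draws log2-CPM abundances from
`0.5 + Gamma(2, 2)` (right-skewed, CPM ~1.4 to a few thousand) and sets
`phi = d0 + a/mu` at a reference depth of 1e7 with multiplicative lognormal
noise; defaults `d0 = 0.15`, `a = 2`, `sd = 0.4` give a common dispersion
near 0.2 (BCV ~0.45), the scale typical of unrelated human samples, with a
rising BCV at low abundance. A seed can instead be estimated from any real
count table by running the classical pipeline. Seeds are filtered before
use: the top 10% of dispersions and means below 10 expected counts at the
reference depth are dropped, mirroring standard count filters; without the
low-mean filter, near-all-zero features make the weighted profile
likelihood monotone in phi (down-weighting the lone positive count removes
the only evidence bounding the dispersion) and destabilize the trend.

Expected counts are `abundance x library size` (libraries uniform on
[8e6, 1.2e7]); exactly `floor(p_diff * n_tags)` features are DE
(`floor(p_up * n_DE)` up), with the higher group's mean multiplied by the
fold factor (fixed, or uniform over an interval). Outliers: S selects a
feature with probability `p_outlier` and multiplies one random observation
by `U(1.5, 10)` (rounded half-up); R applies the same inflation
per-observation; M redraws the observation from NB with the inflated mean,
so R and M share the same expected mask rate. Clean counts, injected
counts, truth labels and the mask are all recorded.

What the simulator does not emulate: zero inflation (deliberately out of
scope), correlated features, per-sample composition or GC biases, and
uncertainty in the seed estimates. Passing tests therefore demonstrate
correct behaviour under the NB-with-contamination model, not under every
failure mode of real data.

## Evaluation battery

Scores (p-value-like, smaller = more DE; NA ranks last) drive FD curves,
ROC curves with tie-grouping (AUC equals the Mann–Whitney statistic;
partial AUC to FPR 0.4, raw and cap-normalized), power and achieved FDP at
nominal FDR cutoffs {0.02, 0.05, 0.1}, and stratified power: five
equal-size abundance bins, and truly-DE features split by outlier position
(DEupOutlier — outlier in the higher-expressed group, inflating apparent
DE; DEdownOutlier — in the lower-expressed group, cancelling it;
DEnoOutlier). The benchmark runner derives one seed per
(configuration, replicate) from a base seed so every method sees identical
datasets, and emits a tidy long-format table.

## Problem sizes

The replicated study behind `scripts/acceptance.py` uses 2000 features,
5 versus 5, 10% S-outliers and five seeds — small enough to run in minutes
while leaving each outlier-position stratum populated; the null-uniformity
check uses 5000 features with the true dispersions supplied so that
p-value calibration is assessed free of estimation error.

## Known limitations

* The nominal FDR is not always achieved by the classical pipeline on
  contaminated data, and the robust pipeline, while much closer, can remain
  slightly liberal; no small-sample correction is attempted.
* Dispersion search is bounded to [1e-6, 100]; estimates at those bounds
  are flagged rather than extrapolated.
* Quasi-likelihood F-tests, shrunken fold-changes, zero-inflated models and
  Cook's-distance-style feature exclusion are out of scope.
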