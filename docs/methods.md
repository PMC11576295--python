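# Methods

This note documents the statistical models, the numerical choices and the
known limitations of `ipvkit`, in the spirit of a package vignette.

## The two-model IPV procedure

IPV compares a **general factor model** (one factor over the whole item
pool) with a **correlated factor model** (one factor per sub-pool,
factors free to correlate), both fitted separately by maximum likelihood
to the same sample covariance. The center distance of an item,

    cd_i = (lambda_spec_i^2 - lambda_gen_i^2) / lambda_gen_i^2,

uses the completely standardized loadings of the two fits; the pool-level
aggregate

    acd = (sum lambda_spec^2 - sum lambda_gen^2) / sum lambda_gen^2

is algebraically the lambda_gen^2-weighted mean of raw item cds and
therefore always lies between the smallest and largest item cd. These
formulas are not unique in the literature; they are fixed here by exact
numerical agreement with the published reference item table this package
reproduces (e.g. the MHC-SF aggregate 0.104 and the PERMA mean 0.039
follow from the printed loading pairs only under this arithmetic).

Two deliberate design choices follow the published two-step description
rather than plausible alternatives:

* **Separate fits, not a bifactor model.** lambda_gen and lambda_spec come
  from two independently estimated models on the same covariance. A
  simultaneous bifactor estimation would orthogonalize the general and
  specific factors and produce systematically different (and differently
  interpretable) loadings.
* **Instrument summaries pool facet-level loadings.** The per-instrument
  mean/aggregate pairs are computed from the facet-level specific
  loadings of each instrument's items (this is what reproduces the
  published pairs); the separate instrument-level four-factor fit
  contributes only the latent correlations between the instruments.

**Negative center distances.** Sampling error can make lambda_spec
slightly smaller than lambda_gen, giving a small negative raw cd. The
default policy floors these at zero, flags the item and logs a warning;
`policy="keep-raw"` preserves the raw value. Aggregate cds always use the
raw loadings. The epsilon guard (default |lambda_gen| > 0.05) refuses the
cd ratio for near-zero general loadings, where the proportional increase
is numerically meaningless.

**Sign alignment.** Factor loading signs are indeterminate in ML; each
factor is reflected so its loading sum is positive, which for positively
keyed wellbeing items makes the general factor correlate positively with
the total score and prevents spurious center distances from sign flips.

## The CFA engine

The discrepancy F_ML = ln|Sigma(theta)| + tr(S Sigma^-1) - ln|S| - p is
minimized over simple-structure loadings, factor correlations and
uniquenesses, with factor variances fixed to 1 (so the solution is
directly standardized and matches how loading tables are reported).
chi-square is (n-1) * F_min, the classic convention (some software uses
n). Numerical choices:

* **Parameterization.** Uniquenesses are optimized on the log scale
  (bounded below at 1e-6; a uniqueness pinned at the bound is reported as
  a Heywood case, never silently). Factor correlation matrices are
  parameterized by hyperspherical Cholesky angles, which guarantees a
  positive semi-definite matrix with unit diagonal at every iterate —
  important here because the flourishing facets correlate at 0.85-0.98,
  close to the boundary of the elliptope.
* **Optimizer.** L-BFGS-B with analytic gradients (gradient tolerance
  1e-8, at most 10000 iterations), initialized deterministically from
  per-block principal components and composite correlations; there is no
  randomness in fitting. The convergence flag is set from the optimizer
  status and the final gradient norm.
* **Scale invariance.** The model is scale invariant, so estimation
  internally rescales S to a correlation matrix; chi-square and all fit
  measures are unchanged and fitting a correlation matrix directly gives
  the same standardized solution (tested to 1e-5).
* **Likert responses are treated as continuous**, as is standard in this
  literature for items with five or more categories; polychoric
  correlation estimation is out of scope. The synthetic-data module
  quantifies the resulting attenuation (below).

**Satorra-Bentler scaling.** When raw data are available, the asymptotic
covariance Gamma of the sample moments is estimated from fourth-order
sample moments and the scaled statistic chi2/c is computed with
c = tr(U Gamma)/df, U the normal-theory residual weight projector. The
per-column standardizing constants are treated as fixed when forming
Gamma; this matches the correlation-scale fit and is exact to first
order, but is not bit-identical to SEM software that propagates the
randomness of the standard deviations. For df = 0 the factor is undefined
and reported as 1 with a flag. Robust RMSEA and CFI use the
population-corrected (mean-scaled) formulas, e.g.
RMSEA_robust = sqrt(max(0, (chi2 - c*df)/(df*(n-1)))); because published
tables rarely state which robust variant they print, both naive and
robust values are always reported side by side and robust index values
are treated as context, not exact targets. The RMSEA 90% CI inverts the
noncentral chi-square CDF in its noncentrality parameter (Steiger-Lind).

**Independent cross-check.** Single-factor ML solutions are verified in
the test suite against `statsmodels`' maximum-likelihood factor analysis
(an EFA with one factor is the same model), with agreement to about 1e-6
on standardized loadings.

## The instrument registry

The default registry declares the four instruments with 47 items in 11
facets (MHC-SF: EWB 3, SWB 5, PWB 6; PERMA: P/E/R/M/A 3 each; FS: 8;
WBCF: PC 6, PF 4 — the two-factor WBCF solution; the three-factor variant
is expressible in a config file but not the default). Item wording is
copyrighted and not stored; items are identified positionally
(`MHC-SF-SWB-4`). Response ranges are 0-5 (MHC-SF), 0-10 (PERMA), 1-7
(FS) and mixed 0-4 / 0-3 / 0-10 for the WBCF; which WBCF positions carry
the 4-point and 11-point formats is a registry convention documented in
`data/registry.yaml`. `WBCF-PC-2` is the single reverse-coded item and is
recoded as max + min − x during validation (an involution).

Validation assumes a forced-response design: any missing cell is an
error, as is any out-of-range code. Composites are item means; WBCF
composites z-score items first because its items mix response formats
(which is why its published composite mean is ~0). Whether composites for
the other instruments are means or sums is not stated in the reference
analysis; means match the printed score ranges and are used. All
variances and covariances use the n−1 (unbiased) convention, consistent
with the standard definitions of Cronbach's alpha and Pearson r.

## The synthetic-data generator

The generator defines the study conditions for every downstream test:
n = 698 respondents (the reference study's sample size), 47 items on 11
correlated facet factors. Facet loadings default to the published
correlated-model loadings, so the generator's ground truth is directly
comparable to the published item table. The facet correlation matrix is
built as Phi = g g' + diag(1 - g^2) from per-facet "general saturations"
g in [0.92, 0.995] (WBCF facets highest, social wellbeing and engagement
lowest), giving off-diagonals in [0.85, 0.98] — a strong general factor
emerges from the facet correlations rather than from an explicit bifactor
structure, which keeps published loadings usable as truth. Uniquenesses
are 1 − lambda^2, so the latent covariance has unit diagonal.

Latent scores are multivariate normal and discretized through per-item
thresholds into each instrument's integer range; the reverse-worded item
is emitted in raw (reversed) coding so that validation restores it, as
with real data. Default thresholds give equal category probabilities; a
`skewed` preset tilts mass toward high categories, because real wellbeing
items are left-skewed. No real-data moments beyond published means/SDs
exist to calibrate thresholds against, so these defaults are
conventional, not estimated. A single integer seed drives all
randomness; simulation is bit-reproducible for a fixed seed.

**What the generator does not emulate:** non-normal latent distributions,
acquiescence and other response styles, missing data, demographic
heterogeneity. Tests passing on this generator therefore demonstrate
correctness of the estimation machinery under a well-specified factor
model with ordinal coarsening — not robustness to the many ways real
survey data misbehave.

**Attenuation.** Discretizing normal scores biases Pearson correlations —
and hence recovered loadings — toward zero. The per-item attenuation
factor a_i = corr(discretized, latent) is estimated by seeded simulation;
pairwise correlations attenuate by approximately a_i * a_j (exactly, in
the small-correlation limit; the classic 2/pi for two median splits).
With the default equal-probability thresholds a_i is about 0.8-0.97
depending on category count, which is why parameter-recovery tests use
continuous (undiscretized) draws when they assert tight (+/-0.05) bounds.

**Population ground truth.** The population center distances attach the
model's own facet loadings to general loadings obtained by fitting the
single-factor model to the population covariance itself (the
infinite-data limit), not to invented numbers.

## Visualization

All chart geometry is package-defined plumbing: the published figures do
not specify their scaling. Item charts place facets in contiguous angular
sectors sized by item count with rays linear in cd and dotted rings every
0.1 cd; every second ray's label is offset for legibility. The nested
chart offsets each instrument circle from the chart center by
radius + scale * aggregate_cd, assigns angular slots by ascending
aggregate cd (so the geometry is a pure function of the numbers), places
facet markers inside their circle proportionally to facet aggregate cd —
meaningful only within that circle — and annotates latent correlations
midway between circle pairs. Circle radius is constant: no claim is made
that published circle sizes encode anything recoverable. Styling lives in
one style mapping so tests compare geometry, not aesthetics; SVG output
is byte-stable for identical layout and style.

## Verification against the published table, and its limits

The packaged reference table carries, for each of the 47 items, the two
printed standardized loadings and the printed center distance, plus the
four printed mean/aggregate pairs. Loadings are printed to 3 decimals, so
recomputed cds can legitimately deviate by up to about 0.005;
verification uses that tolerance per item and 0.002 for pool pairs
(observed: at most 0.004 and 0.002 respectively). The WBCF block is
excluded from the item-level check: several of its printed rows are
mutually inconsistent at 3-decimal precision (e.g. loadings 0.691 →
0.688 printed with cd 0.007, while 0.473 → 0.475 prints 0.000), which no
rounding of the stated arithmetic explains; whether those rows went
through an additional correction step is not documented. The WBCF pool
still participates in the ordering check (its aggregate is far below the
others under any reading).

Published fit indices, reliabilities and latent correlations were
estimated from the original restricted survey data and are not
desk-reproducible; the test suite instead checks the corresponding
machinery on synthetic data with known truth (perfect-fit identity,
parameter recovery within +/-0.05 at n = 5000 continuous observations,
Satorra-Bentler scaling factor within [0.9, 1.1] under normality at
n = 20000, aggregate-cd identity to 1e-12, and a complete 698 x 47
pipeline run). Problem sizes for these checks were chosen so that Monte
Carlo error is comfortably inside the asserted tolerances (e.g. the
block-diagonal factor-correlation recovery uses n = 10000, where the
sampling error of correlations between weakly determined 3-item facets
is well below the 0.05 band).

## Known limitations

* Ordinal (polychoric / WLSMV) estimation is not implemented; with
  coarse scales (the WBCF's 4-point items) continuous-ML loadings are
  attenuated.
* The robust RMSEA/CFI variant printed by any given SEM package may
  differ from the population-corrected formulas used here.
* The Satorra-Bentler Gamma treats standardizing constants as fixed (see
  above).
* Cross-loadings, modification indices, measurement invariance and full
  SEM with structural paths are out of scope.
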