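# Methods

This note records the statistical models implemented in `wordfx`, the
defaults and why they were chosen, the numerical strategies, and what the
synthetic-data tests do and do not establish.

## Constrained factor mixture screens

Both screens are two-class Gaussian mixtures whose within-class structure
is a one-factor model, y = ν_k + λ_k f + ε, f ~ N(α_k, Φ_k),
ε ~ N(0, diag ψ) with ψ shared across classes.  Class 1 is the
inconsistent class; its recoded negative items load negatively.  Because
the sign structure is part of the model, the class labels are identified
structurally — no post-hoc label switching is needed or possible.

Two constraint systems are provided:

| | sign-flip-linked ("steinmann") | unit-loading ("arias") |
|---|---|---|
| positive λ | shared across classes, λ > 0 | fixed +1 both classes |
| negative λ | λ₂⁻ > 0 free, λ₁⁻ = −λ₂⁻ | fixed −1 (class 1), +1 (class 2) |
| ν | positives shared; negatives free per class | all shared |
| α | α₂ = 0; α₁ free | both 0 |
| Φ | Φ₂ = 1; Φ₁ free | both free |
| free parameters (5+5 items) | 38 | 23 |

Item codes are treated as continuous within class.  With a rare class
(≈8% of ~600 respondents) a categorical-indicator mixture would need
numerical integration on very little data; the continuous treatment is the
standard choice for this screening task and classification depends only on
point estimates and posteriors.  For the same reason no standard errors
are reported for mixture parameters.

### Estimation

Maximum likelihood by a **generalized EM** algorithm.  The E-step is the
usual responsibility update.  The M-step has no closed form under the
equality/sign links, so the expected complete-data loglikelihood is
maximized numerically (L-BFGS with analytic gradients on a transformed
parameter vector: log for ψ, Φ and loading magnitudes — which also
enforces the λ > 0 bounds — and a closed-form update with a 1/(2N) floor
for the mixing weight).  An L-BFGS step that fails to improve the
expected loglikelihood is rejected, so the observed loglikelihood is
non-decreasing across iterations; this is asserted on every fit.
Convergence: absolute loglikelihood change < 1e-7 or 5000 iterations.

Multistart: `n_starts` random initializations (moment-based bases with
multiplicative/additive perturbations) each run a short initial stage
(15 EM iterations); the best tenth continue to convergence.  The number of
final-stage runs replicating the best loglikelihood (within 1e-2) is
reported so users can judge whether to raise the start count.  The default
200/20 is a scaled-down version of the tens of thousands of starts used
with commercial software on the original data; on the synthetic problems
in the test suite a handful of starts already replicates the optimum.

### Classification statistics

Relative entropy E = 1 − Σ(−p log p)/(N log K) quantifies posterior
sharpness.  Modal assignment breaks posterior ties (exactly 0.5) toward
the consistent class — a deliberately conservative screening rule.
Cohen's κ between two screens is computed from the 2×2 cross-table and
banded (≤0 none, ≤0.20 none-to-slight, ≤0.40 fair, ≤0.60 moderate,
≤0.80 substantial, ≤1 almost perfect).

## Polychoric correlations

Two-step estimator: thresholds from the inverse-normal of cumulative
marginal proportions, then the latent correlation by maximizing the
bivariate-normal contingency likelihood with thresholds fixed, using
bounded scalar optimization on (−0.999, 0.999).  Two-step agrees with
joint ML to about 1e-3, is much faster, and matches what standard software
does.  The bivariate normal CDF uses the trigonometric single-integral
form with 48-node Gauss–Legendre quadrature (the sin substitution removes
the endpoint singularity, giving near machine precision over the whole
correlation range).

Empty categories are merged into their neighbours by default (mirroring
the common practice of collapsing sparse categories), or raise under
`empty_policy="error"`.  A single-category item is always an error.
Perfect-association tables return ±(1−1e-3) with a warning.  An indefinite
pairwise matrix is repaired by clipping eigenvalues at 1e-6 and rescaling
to unit diagonal; the `smoothed` flag records that repair happened.

## Dimensionality

Eigenvalues come from the full (non-reduced) correlation matrix.
Parallel analysis builds each comparison set by independently permuting
every item's column — preserving margins exactly, so the per-item
thresholds can be reused inside the loop — computes the polychoric matrix
and its eigenvalues per set, and averages across sets rank by rank (the
mean criterion, 1000 sets by default).  Retention is sequential: stop at
the first rank where the empirical eigenvalue no longer exceeds the mean
random one.  A Pearson fast mode exists for tests; it is off by default.
Scree data (both series) are exported for plotting; visual scree
interpretation is left to the user.

## Confirmatory models

Three structures on the polychoric matrix — one factor; two correlated
factors split by item polarity; and RIIFA, one substantive factor plus an
orthogonal method factor with loadings fixed to +1/−1 whose single free
variance yields one shared standardized method-loading magnitude.  Each
can free one error covariance θ (default pair p4–p5).  Degrees of freedom
for 10 items: 35 / 34 / 34, minus one with θ.

Point estimation minimizes the least-squares discrepancy between sample
and implied correlations over the off-diagonal (the implied diagonal is
exactly 1 by construction).  Two weightings are available: unweighted
(default) and diagonally weighted with 1/(1−r²)² — the large-sample
variance proxy for a correlation — which mirrors the diagonally weighted
estimators used for categorical data and reproduces published
mean-and-variance-adjusted WLS point estimates to about ±0.01 from a
2-dp printed matrix.  θ estimates and error-covariance SEPCs are reported
as residual correlations (covariance over the product of residual SDs).

χ² statistics for fit indices are the normal-theory ML discrepancy
evaluated at the least-squares solution, times (n−1).  This is an
approximation: it supports CFI/TLI/RMSEA/SRMR comparison across models on
the same matrix but does not reproduce scaled (mean-and-variance-adjusted)
test statistics, which require raw data.  The baseline is the
zero-correlation independence model (df = p(p−1)/2); the RMSEA 90% CI
inverts the noncentral χ² CDF; SRMR is the RMS of the off-diagonal
residuals.  Heywood cases (communality > 1) warn and are reported as
estimated, never silently bounded.

Modification indices are expected χ² drops obtained by re-optimizing the
ML discrepancy with the candidate parameter freed, warm-started at the
fitted solution (an iterated score statistic).  A one-step quadratic score
statistic was evaluated and rejected: it overshoots the realized χ² change
badly once the omitted parameter is large (ratio ≈ 2 at a residual
correlation of 0.4), whereas the iterated version tracks the refit within
a few percent at all magnitudes while remaining a local, cheap
computation.  Candidates are all fixed error covariances plus, in the
two-factor model, the zero cross-loadings.

## Reliability

Categorical omega works on the observed ordinal metric: writing an item as
X = 1 + Σ_c 1{Z > τ_c}, the covariance of two thresholded items under
latent correlation ρ is Σ_{c,d}[Φ₂(τ_c, τ_d; ρ) − Φ(τ_c)Φ(τ_d)].  Omega is
the ratio of the implied true-score variance of the sum (latent
correlations λᵢλⱼ, diagonal λᵢ²) to the implied total variance (full
implied polychoric, unit diagonal).  A freed θ counts toward total but not
true-score variance — correlated error, the conservative reading — and
both the with-θ and without-θ omegas are reported since either convention
is defensible.  Negative loadings are treated as mirror-coded items and
normalized (loading flipped, thresholds mirrored) before scoring, making
omega invariant to item coding direction.

Cronbach's α and item-rest correlations are computed on the integer codes
for comparability with older literature.  BCa bootstrap intervals
(default B = 1000, 95%) resample respondents; a degenerate bootstrap
distribution falls back to the percentile method with a warning.

## Synthetic data

The generator draws class membership by a mixing weight, then continuous
responses from the class's side of the chosen constraint system, then
discretizes by per-item thresholds (category c on (τ_{c−1}, τ_c]).
Defaults mirror the motivating study's structure: 10 items (5+5), 4
response categories, n = 632, mixing weight 0.08, consistent-class
standardized loadings in the 0.45–0.78 band, intercepts skewed toward
agreement, and cut points placed at cumulative proportions (0.05, 0.15,
0.45) to give the right-shifted margins typical of self-esteem items.
Class factor variances default to (0.5, 1.0).  Under the sign-flip-linked
mechanism the inconsistent class's negative-item intercepts are shifted
down one item SD, reproducing the lower observed negative-item means of
flagged respondents.  A continuous-output mode skips discretization for
clean parameter-recovery tests.

These are test conveniences, not claims about any real population: the
generator draws exactly from the fitted model family (no cross-loadings,
no residual dependence beyond an optional θ, Gaussian latent responses,
classes exactly two).  Passing recovery tests therefore show the
estimators are correct under their own assumptions; they do not show
robustness to the ways real questionnaire data violate them.

## Problem sizes in the test suite

Test and acceptance runs use scaled-down but statistically meaningful
sizes chosen once: mixture fits with 4–50 starts on n = 400–2000;
parameter recovery over 200 replicates at n = 1000; parallel analysis
with 50–100 permutation sets; omega's simulation oracle at n = 200,000
draws; bootstrap coverage at 200 replications of B = 600.  The published
reanalysis (eigenvalues, factor correlations, method loadings) is exact
arithmetic on the packaged matrices and runs in seconds.

## Known limitations

* Only two-class mixtures; no >2-class exploration.
* No categorical-indicator (integration-based) mixture estimation and no
  robust standard errors; scaled χ² statistics are not reproduced.
* No missing-data handling (the motivating data had none).
* Polychorics have no polyserial/Pearson fallback; degenerate items follow
  the threshold policy rather than being dropped automatically.
* Measurement-invariance sequences and MIMIC structural models are out of
  scope.
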