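# Methods

## Scaling by an estimated CDF

For one variable with observed values x₁,…,xₙ, the scaled value of v is
an estimate of P_X(v), the variable's cumulative distribution function
at v. The estimate is a four-parameter generalized logistic curve

L(x) = (1 + Q·e^{−B(x−M)})^{−1/ν},  Q, B, ν > 0,

fitted to the empirical CDF P̂_X(v) = n⁻¹ Σ 1[xᵢ ≤ v] by minimizing
η(B, M, Q, ν) = Σᵢ (L(xᵢ) − P̂_X(xᵢ))². All n sample points enter the
sum: tied values contribute one identical residual per occurrence, and
the point at the sample maximum (ECDF height exactly 1, unattainable by
L) is kept — its residual is simply part of η. The model makes no
distributional assumption; the curve is just a smooth, strictly
monotone, (0,1)-bounded surrogate for whatever CDF produced the data.

Assumptions worth stating: values of a variable are treated as i.i.d.
draws from one continuous distribution, each variable is scaled
independently (no joint/copula modeling), and a fit on a training
partition is applied unchanged to any later data.

## Optimization

η is smooth but non-convex. It is minimized by L-BFGS-B with the
analytic gradient; Q, B, ν are optimized on the log scale, which
enforces positivity without projections. The gradient components are the
four partial-derivative sums in (B, M, Q, ν); they are evaluated in log
space (`logaddexp`) so that arguments deep in either tail can neither
overflow nor destroy the curve evaluation — the same log-space path is
used for L itself, whose outputs are additionally clamped to the open
interval (0, 1) at the floating-point boundary.

Stopping rules (defaults of `FitConfig`): projected-gradient max-norm
1e−8, relative objective-decrease 1e−10, at most 500 iterations. These
are conservative for a 4-parameter problem; typical fits converge in
15–40 iterations. On a non-converged fit the best iterate is returned
with a warning rather than an exception, and the final objective is
never allowed to exceed its value at the initialization (if the
optimizer returns something worse, the initialization is kept).

## Initialization

The starting point anchors the curve at three order statistics:

* M₀ = x_med forces the curve's center onto the sample median, and
  ν₀ = log₂(1 + Q₀) then makes L(x_med) = 0.5 an exact identity for
  every Q₀ > 0, since (1 + Q₀)^{−1/log₂(1+Q₀)} = ½.
* B₀ = [ln((1+Q₀)^{log₂10} − 1) − ln Q₀]/(x_med − x_min) makes
  L(x_min) = 0.1 exact, again for every Q₀ > 0.
* Q₀ is chosen so that L(x_max) = 0.9, which after substituting ν₀ and
  B₀ is a one-dimensional root equation in Q₀.

The root is found by Newton's method on the log-residual
ln L(x_max) − ln 0.9 in ln Q₀ (analytic derivative), safeguarded by
bisection on a sign-change bracket located by geometric scan over
[1e−8, 1e8]; the starting guess Q₀ = 1 is exact under symmetric spacing
(x_max − x_med = x_med − x_min, where also ν₀ = 1 and
B₀ = ln 9/(x_med − x_min)). The log-residual form matters: the equation
in its raw form becomes ill-conditioned as Q₀ → 0, where a tiny raw
residual no longer implies L(x_max) ≈ 0.9.

**Existence caveat.** The root equation has a positive root only when
the spacing ratio ρ = (x_max − x_med)/(x_med − x_min) lies inside
roughly (0.365, 1.569) — the three-anchor constraint is otherwise
outside the reach of the curve family (e.g. for anchors (0, 1, 3) the
best achievable L(x_max) is ≈ 0.939). `init_q0` and `init_params`
report this honestly with a `ConvergenceError`. The fitting path
(`fit_gl`, and the `gl` scaler built on it) instead falls back to the
best-achievable Q₀ by grid argmin of |ln L(x_max) − ln 0.9| over
[1e−4, 1e4]: the 0.5 and 0.1 anchors remain exact, L(x_max) lands as
close to 0.9 as the family allows, and the least-squares fit — which is
the quantity that actually matters downstream — proceeds normally.
Strongly skewed variables (log-normal, zero-inflated) routinely take
this path.

## Degenerate features

The scaler layer never fails on a pathological column; it degrades and
flags:

* constant column → fallback record; transforms to 0.5 (`gl`) or 0
  (`minmax`, `zscore`), with a warning.
* fewer than 3 distinct values → no curve fit; fallback 0.5.
* median equal to the minimum (e.g. zero-inflated counts) → the center
  anchor moves to the 75th percentile; median equal to the maximum → the
  25th. If the repaired anchor is still not strictly interior, fallback.

Min-max and z-score outputs are deliberately **not clipped** on unseen
data: values outside the training range map outside [0, 1] (min-max) or
arbitrarily far (z-score). Preserving this behavior is required for an
honest comparison with the bounded CDF map. Missing values are rejected
at load time with the offending row and column named, never imputed.

## Synthetic data

The generators define the study conditions for all tests and demos; all
randomness flows through numpy's PCG64 bit generator with explicit
integer seeds, so identical specs give bit-identical output.

* `sample_from_gl` — exact draws from a known curve by inverse-transform
  sampling (the closed-form inverse x = M − B⁻¹·ln((u^{−ν} − 1)/Q)).
* `gen_contaminated` — a base sample plus n_out outliers placed at
  base_max + magnitude·range. Each outlier moves the ECDF of the
  original points by exactly 1/(n + n_out) in sup-norm, which is the
  whole robustness mechanism in one line.
* `gen_two_class` — two 2-D clusters separated by the line x = 0, each
  sitting at ±separation/2 plus a log-normal excursion pointing away
  from the boundary, so the within-class density is highest where the
  classes meet; the second coordinate is pure standard-normal noise.
* `gen_benchmark_scenario` — the adversarial-for-linear-scaling
  composite used in the harness tests: `gen_two_class` with 60 points
  per class, the noise coordinate inflated ×10⁶, and 3 positive-class
  points pushed to 100× the informative coordinate's range. The
  defaults are the scenario; they are not tuning knobs.

What the generators do **not** emulate: feature correlation, label
noise, batch effects, missingness, and discreteness of real assay data.
A passing benchmark here shows the outlier/scale mechanism works as
described, not that the GL scaler wins on any particular real dataset.

## Benchmark harness

Stratified k-fold cross-validation (default k = 5, shuffled with a
fixed seed); per fold the scaler is fitted on the training rows only.
Classifiers are scikit-learn's logistic regression (L2, C = 1) and
linear SVM (hinge, C = 1) — the harness is glue by design; the science
is in the scalers. Metrics:

* AUROC of the held-out decision scores (Mann–Whitney statistic; ties
  count one half).
* Accuracy at a threshold chosen on the *training* scores: predict
  positive iff score ≥ t, candidates are the distinct training scores,
  and among thresholds attaining maximal training accuracy the minimum
  is taken. A candidate below all scores is unnecessary — it predicts
  identically to the minimum score.
* Aggregates are fold means with 95 % t-intervals,
  t₀.₉₇₅,k₋₁·sd/√k, labeled as such in the CLI output.

## Numerical and design choices

* Median for even n: mean of the two central order statistics.
* Z-score uses the n−1 denominator.
* Model files are JSON; floats serialize through shortest round-trip
  decimal representation, so save → load reproduces parameters
  bit-for-bit. Persisted models and provenance sidecars contain no
  timestamps: identical inputs and configuration give byte-identical
  artifacts.
* Problem sizes in the test suite (2000-point parameter recovery,
  5000-point normal-approximation and uniformization checks, 20-seed
  benchmark replicates) were chosen as the smallest sizes at which the
  checked tolerances are comfortably meaningful.

## Known limitations

* One curve per variable cannot represent multimodal CDFs well; the fit
  is the best monotone 4-parameter approximation, not a density model.
* The three-anchor initialization is exactly solvable only in the
  spacing band given above; outside it the fit starts from a boundary
  Q₀ and relies on the optimizer.
* The fit minimizes an unweighted sum of squares on the ECDF, so tails
  (few points) are fitted more loosely than the bulk — which is exactly
  what makes the map outlier-robust, but also means extreme quantiles
  are compressed.
* Local minima are accepted; no global-optimization guarantee is made
  or needed for the scaling use case.
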