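# Methods

This note documents the models, defaults and numerical choices behind
`dynconn`, and what the synthetic validation does and does not establish.

## The measurement problem

Dynamic FNC analyses estimate time-varying coupling between ICA-derived
network time courses from short, tapered windows, then summarize each
subject's trajectory through connectivity space. Every quantity of interest
(dwell time, number of transitions, meta-state fluidity and range) is a
nonlinear functional of noisy window-level estimates, so the pipeline is
validated end to end on cohorts whose hidden dynamics are planted and known.

## Synthetic cohort generator

A subject is a hidden Markov chain over S planted correlation states,
switching at TR resolution. Observations at each TR are zero-mean
multivariate normal draws with the active state's correlation, optionally
plus linear drift, a slow (~1.5 cycles/record) sinusoid, sparse impulses, and
white noise.

- **Planted states** are block-structured correlation matrices (shared block
  layout, state-specific within/between levels). Construction validates
  positive definiteness per block (within-block r must exceed −1/(b−1)) and
  globally, and reports the minimum pairwise city-block separation of the
  vectorized states — the key difficulty parameter for state recovery.
- **Switching at TR resolution** means analysis windows straddle state
  boundaries, as in real data; windows are *mixtures* near transitions, which
  is the honest version of the recovery problem.
- **Spikes** are expressed in multiples of the clean series' MAD so despiking
  efficacy is directly assertable.
- **Motion** is a 6-parameter random walk whose increment scale is calibrated
  so the expected mean framewise displacement (FD) matches a group-specific
  target (default 0.18 mm EP vs 0.12 mm HC, planting the usual patients-move-
  more contrast). FD follows the Power convention: the sum of absolute
  frame-to-frame parameter changes, rotations converted to arc length on a
  50 mm sphere; FD at the first TR is 0.
- **Clinical score**: score = intercept + slope·(true NT) + N(0, σ), with NT
  the subject's true number of TR-level state transitions. Linear-Gaussian is
  the simplest coupling whose recovery validates the partial-correlation
  stage. Antipsychotic dose (`cpz_equiv`) is drawn independently (truncated
  normal, patients only), so it is a pure nuisance.

The full cohort is a pure function of its spec, including the seed
(`numpy.random.SeedSequence` spawning per subject).

## Conditioning

Order: detrend → despike → low-pass, per component.

- **Detrend basis**: intercept, linear trend, and sine/cosine pairs at one
  half cycle and one full cycle over the record (six regressors; T ≥ 7
  required). The same basis provides the smooth fit for despiking.
- **Despiking**: residuals from the smooth fit with |r| ≤ c₁·σ_MAD pass;
  larger ones are compressed to c₁ + (c₂−c₁)·tanh((s−c₁)/(c₂−c₁)) MAD units
  (sign preserved) and re-added to the fit. Defaults c₁ = 2.5, c₂ = 4.0 (the
  reference despiking tool's documented defaults). σ_MAD = 1.4826·MAD; a
  zero-MAD series is returned unchanged.
- **Filtering**: fifth-order Butterworth, 0.15 Hz cutoff, applied
  forward–backward (zero phase; effective magnitude = squared single-pass
  response). Zero-phase was chosen because phase distortion would shift
  windowed correlations in time. Idempotence of the composite holds away from
  the filter's transition band and record edges; broadband content near the
  cutoff keeps attenuating on repeated passes, which is inherent to any
  finite-order filter.
- **QC**: subjects are excluded when maximum |translation| > 3.0 mm or
  |rotation| > 3.0° — strictly greater, so a subject exactly at the ceiling
  is kept. Missing motion traces are flagged and excluded, never silently
  kept.
- **Spectra**: multitaper (DPSS, time-bandwidth 3, 5 tapers ≤ 2·NW−1),
  one-sided, scaled so total power ≈ series variance. Detrending and spectrum
  estimation are deliberately separate operations; per-bin estimates have
  ~2K = 10 dof, so flatness checks must average sub-bands rather than compare
  single-bin extremes.

## Static FNC and covariate selection

z = arctanh(r) with r clipped to ±(1−10⁻⁷); diagonal 0; constant components
yield zero correlations with a warning. The group analysis PCA-reduces
standardized features to the axes holding 95% of variance (configurable — the
right number of dimensions is genuinely open), then backward-selects
predictors by Pillai-trace F (each predictor adjusted for the others),
removing the least significant until all survivors pass BH-FDR at α = 0.05.
Pillai's trace was chosen among the classical multivariate statistics for
robustness; the implementation is cross-checked against an independent MANOVA
implementation in the tests. Per-feature localization uses partial-F tests
(full vs reduced model) with BH-FDR across features and effect signs from the
full-model coefficient.

Null calibration: on pure-noise features (n = 60, four predictors) the
diagnosis retention rate sits at the nominal α (measured ≈ 0.045 over 200
nulls). Power at a 1-SD shift on 10% of 40 features is ≈ 0.9 at n = 60: PCA
on unstructured features keeps nearly all dimensions, which costs error
degrees of freedom.

## Windowed connectivity

- **Taper**: boxcar of `width` TRs convolved with a unit-area Gaussian of
  σ = `gauss_alpha` TRs, truncated to the window and renormalized (defaults
  30 TRs / σ = 3 / step 1; 0-based window starts; windows are inclusive TR
  ranges). The σ→0 limit is the uniform window.
- **Windowed covariance**: weighted mean removed, weights sum to 1.
- **Graphical lasso**: solved on the window correlation; the implied
  covariance is renormalized to correlation and Fisher-z transformed. Penalty
  0 *is* the weighted sample correlation (exact unpenalized limit). The
  penalty is selected per subject by maximizing held-out Gaussian
  log-likelihood over random half-splits of windows (default 10 repetitions,
  10 log-spaced penalties in [10⁻³, 1]). Ill-conditioned windows can break
  the coordinate-descent solver at small penalties; a tiny diagonal shrinkage
  ladder (0, 10⁻³, 10⁻², 5·10⁻²) stabilizes it, and failure at every penalty
  raises with the largest grid penalty suggested as fallback.
- **Motion regression** operates on the windowed connectivity series (not the
  raw time courses): each pair's window series is residualized by OLS on
  taper-weighted window summaries of FD and of each parameter's absolute
  derivative, with the intercept restored so only motion-locked fluctuation
  is removed. Constant regressors are dropped with a warning.

## Cluster states

k-means over all pooled windows with city-block distance and median centroid
updates — the metric-consistent pairing, and the same geometry the meta-state
metrics use (squared-Euclidean/mean is available as an option). k-means++-
style seeding under the chosen metric, best of `n_replicates` restarts
(default 100), deterministic given the seed; empty clusters are re-seeded at
the farthest point. All windows are clustered (no exemplar subsampling):
simpler and deterministic. States are relabeled by decreasing occupancy for
stability. Defaults k = 5 with a k ∈ {4, 5, 6} sweep helper.

Metrics per subject: mean dwell = mean maximal-run length per state (in
windows, 0 + visited-flag for unvisited states), fraction time, and NT = the
number of adjacent unequal assignments. Per-state group contrasts compare
subjects' state-conditional mean z per pair with two-sample t tests; subjects
with no window in a state are excluded from that state's tests, and a state
occupied by fewer than two subjects of either group is skipped. Raw α = 0.05
per state by default, optional BH-FDR.

## Meta-states

Pooled windows are decomposed into `model_order` (default 5) maximally
independent connectivity patterns: each window's FNC vector is a mixture of
the patterns with independent weights across windows, estimated by FastICA;
patterns are the mixing-matrix columns, normalized to unit norm with the
dominant entry positive. Per-window weights come from least-squares
projection onto the patterns (so held-out subjects can be projected onto a
fitted model). Weights are discretized by signed quartiles of |weight| pooled
over all subjects' windows (global quartiles; per-subject quartiles would
destroy between-subject comparability of the occupied vectors) — each weight
maps to sign·quartile ∈ {±1..±4}, zeros to +1, degenerate tie boundaries
nudged apart by a stable ε with a warning.

Metrics per subject: number of distinct meta-states, number of changes
(fluidity), span = largest city-block distance between occupied vectors, and
total distance = summed city-block step lengths (range). Invariants:
total ≥ span, changes ≥ states − 1, all metrics invariant to coordinate
permutations and sign flips of patterns.

Measurement attenuation is the dominant practical issue: per-window weight
noise produces quartile flips unrelated to true switching, so the correlation
between true TR-level transitions and computed fluidity grows with the number
of components (more pairs stabilize the projection) and shrinks when the
model order exceeds the true state count. The brain-behavior validation
therefore uses 25 components and five planted states at model order 5.

## Group statistics

- **Test choice**: Shapiro–Wilk in each group; any p < .05 → Mann–Whitney U;
  otherwise Levene's test chooses Welch (p < .05) vs Student t. Counts get
  Pearson χ² without continuity correction. The gate p-values are recorded in
  the result.
- **Box–Cox** is applied only when Shapiro–Wilk rejects (p < .05); data are
  shifted by 1 − min when any value ≤ 0; λ by profile ML.
- **Partial correlation**: x and y residualized on nuisance + intercept;
  Spearman flavor rank-transforms x, y and nuisance first; p from t with
  n − k − 2 df. An outcome collinear with the nuisance to machine precision
  is flagged (warning, r = 0, p = 1) rather than fatal.
- **DAP correction**: r̄_j = mean |correlation| of endpoint j with the
  others, clamped to [0, 1]; m_eff = m^(1−r̄_j);
  p′ = 1 − (1−p)^m_eff capped at 1. Bounded between the raw p (r̄ = 1) and
  Šidák (r̄ = 0). Absolute correlations keep m_eff ∈ [1, m].
- **BH-FDR** (statsmodels step-up) and plain Bonferroni (min(1, m·p)) for the
  family-wise correction.

## Validation problem sizes

The acceptance checks run at desk scale, chosen as the smallest problems
where the effects are unambiguous:

- Planted-state recovery: 20+20 subjects, 10 components, 3 states (stay 0.98
  vs 0.96), 300 TRs, window 30/σ 3, glasso grid {0.01, 0.1}, k = 3, 20
  restarts. Measured: pooled window-label agreement ≈ 0.93 after Hungarian
  matching; matched centroid–planted correlations ≥ 0.98.
- Dwell-difference recovery: 12+12 subjects, 250 TRs, state-1 stay 0.985 vs
  0.93; Mann-Whitney on the recovered state-1 dwell over 10 seeds.
- Brain-behavior recovery: 96+56 subjects, 25 components, 5 states at model
  order 5, 200 TRs, coupling slope −1/noise 1; partial correlations of the
  score with n_changes and total_distance (dose as nuisance), DAP-corrected
  over the four meta-state endpoints, over 10 seeds.
- The dwell/NT/meta-state metrics are checked exactly against brute-force
  enumeration on 1000 random sequences/trajectories (length ≤ 50).

The windowed stage in the two detection runs uses penalty 0 (the weighted
sample correlation): those checks target the metric and statistics stages,
and the unpenalized limit is itself verified separately to 10⁻⁴.

## What passing does and does not show

The generator produces Gaussian switching data with exact block-correlation
states, white-plus-drift artifacts, and a linear score coupling. Passing
recovery tests shows the pipeline's stages are correct and calibrated under
that model. It does not establish performance under hemodynamic filtering,
spatially structured or temporally autocorrelated noise, scanner drift
spectra, non-Markovian state dynamics, or model-order misspecification in
real fMRI — and the synthetic states are far better separated than empirical
cluster states typically are.

## Known limitations

- FastICA convergence on hard (low-SNR, near-Gaussian-weight) data can stop
  at the iteration cap; the fit is still deterministic given the seed, and
  convergence warnings are suppressed in favor of the rank precondition.
- The k-means cost surface is non-convex; determinism is per seed, and
  restart counts below ~20 can return visibly suboptimal states on hard
  instances.
- Penalty selection assumes windows are exchangeable across the record; under
  strong nonstationarity the held-out likelihood is biased toward heavier
  penalties.
- Dwell times of rarely visited states are noisy (few runs per subject); the
  per-state group tests exclude non-visitors, which changes the effective n
  per state and is reported in each result.
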