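# Methods

`couplingbench` benchmarks estimators of interregional coupling in
resting-state fMRI along two axes: sensitivity to residual head-motion
artifact (QC-FC) and utility for predicting behavior (kernel ridge
regression). Because the cohorts this class of analysis is usually run on
are access-restricted, the package ships a synthetic cohort generator that
plants every structure the benchmark is supposed to detect, so the whole
pipeline is testable end to end against known ground truth.

## Synthetic cohorts

**Latent dynamics.** Each cohort shares one ground-truth network: a stable
VAR(1) system `x_t = A x_{t-1} + e_t` with diagonal innovation covariance
`Q`. Off-diagonal couplings are Bernoulli(`edge_density`) with N(0, 0.25²)
weights; diagonal decay is uniform in [0.2, 0.6]; `A` is rescaled to
spectral radius 0.9 when it exceeds that, guaranteeing stationarity. The
stationary covariance solves the discrete Lyapunov equation
`S = A S Aᵀ + Q`, which the tests use as an exact oracle. Region centroids
are uniform in a 140 mm cube, giving a realistic interregional distance
range for distance-dependence checks.

**Observation model.** The latent process (≥200 burn-in steps discarded) is
convolved per region with a canonical double-gamma hemodynamic response
(peak 6 s, undershoot 16 s, peak/undershoot ratio 6, truncated at 32 s,
sampled at the TR), then white measurement noise of standard deviation
`noise_sd` (default 0.5) is added.

**Motion.** Six rigid-body traces are built as AR(1) drift + a respiratory
sinusoid at 0.37 Hz (the midpoint of the 0.31–0.43 Hz respiratory band the
FD filter targets) + white jitter, in relative amplitudes 1 : 0.8 : 0.3.
Traces are generated in displacement units and rescaled so the unfiltered
mean framewise displacement equals the subject's drawn severity (uniform in
`motion_severity_range`, default 0.05–0.3 mm). Rotations are stored in
radians (displacement ÷ 50 mm head radius).

**Motion contamination of edges.** Edge susceptibility is `exp(-d_ij/L)`
with e-folding length `L = artifact_distance_scale` (default 35 mm), so
short edges are most vulnerable. A single shared motion regressor — the
demeaned FD trace divided by a fixed 0.1 mm reference fluctuation — is
added to each region with weight `gain · w_i · sd_i`, where `w` is the
leading eigenvector of the susceptibility matrix (nonnegative by
Perron–Frobenius); the induced edge contamination therefore scales with
`w_i w_j`, a rank-one proxy for the susceptibility. Dividing by a fixed
reference rather than each subject's own fluctuation is essential: it makes
contamination amplitude proportional to the subject's motion, which is the
across-subject gradient QC-FC detects. `artifact_gain = 0` returns the
series untouched.

**Sites and families.** Multi-site structure is injected as a site-specific
random region-weight pattern driving a per-subject shared time course,
which produces site-shared edge offsets for ComBat to remove. Families are
contiguous blocks assigned to sites round-robin; behavioral noise shares a
family-level random intercept with ICC 0.3, so family-blind
cross-validation folds would leak.

**Behavior.** Each behavior is `r·s + loadings·(age, sex, FD) + family
intercept + noise`, where `s` is a standardized weighted sum of the
subject's clean-series Pearson edges (a sparse random 10% of edges carry
weight) and the variance budget is closed so the population correlation
with `s` is `behavior_effect_r`. Covariate loadings (0.2 each on age, sex,
mean FD) give the train-fold confound regression real signal to remove.

**What the generator does not emulate:** voxel-level artifacts and their
interaction with registration, regionally varying hemodynamics,
non-Gaussian BOLD noise (cardiac pulsation, scanner drift beyond AR(1)),
realistic behavioral measurement error, or site effects that interact with
covariates. Passing tests therefore demonstrate the *pipeline's* ability to
recover structure it is designed for, not estimator performance on real
cohorts.

## Preprocessing tail

Nuisance regression (24-parameter motion expansion `[p, Δp, p², Δp²]`, plus
optional surrogate global signal and its derivative) precedes an ideal
(Fourier rectangular) 0.008–0.08 Hz bandpass; DC is always zeroed.
Framewise displacement is the sum of absolute frame-to-frame differences of
the six parameters with rotations mapped to arc length on a 50 mm sphere;
before differencing, a frequency-domain band-stop removes 0.31–0.43 Hz
respiratory content (a band-pass mode is available, since "filtering the
respiratory band" is ambiguous; removal is the default because that is the
filter's stated purpose). Exclusions use three strict rules: mean FD >
0.3 mm, more than 20% of frames above 0.2 mm, any frame above 5 mm.

Global-signal regression is off by default in the pipeline: removing the
global mean costs about one dimension of region space, which is negligible
at 300 regions but collapses full partial correlations toward −1 at the
tens-of-regions scale the benchmark runs at.

## Estimators

* **Pearson / Spearman** — product-moment correlation of raw or
  rank-transformed (ties averaged) series; Fisher r-to-z applied by
  default to these two only.
* **Partial correlation** — `−P_xy/√(P_xx P_yy)` from the inverse sample
  covariance; pseudo-inverse with a warning if singular.
* **GLASSO** — L1-penalized precision (off-diagonal penalty only) via the
  graphical lasso on internally standardized series; λ = 0 falls back to
  direct inversion. λ-range selection runs a wide log grid on a subset of
  up to 20 subjects scored by extended BIC (γ = 0.5), then a tight re-grid
  around the median optimum; the eBIC criterion is this package's choice
  where the original procedure names none.
* **Spectral coherence** — Welch averaged periodogram (Hann taper, default
  window `min(frames/4 → power of two, 256)`, 50% overlap), magnitude-squared
  coherence, unweighted mean over 0.008–0.08 Hz bins.
* **Wavelet coherence** — Morlet CWT (ω₀ = 6, 12 voices/octave), auto- and
  cross-spectra smoothed by a scale-dependent Gaussian in time (implemented
  circularly via the FFT) and a 0.6-octave boxcar in scale; coherence
  averaged over in-band scales and all time points, cone of influence
  included. Without smoothing wavelet coherence is identically 1; a test
  asserts the smoothed estimator is not degenerate.
* **Frequency-domain MI** — `φ = 1 − exp(−2δ)` with
  `δ = |(1/2π)∫ log(1 − C(Ω)) dΩ|` over the band (trapezoid, Ω in rad/s).
  The integrand is negative for coherence in (0, 1), so the absolute value
  is required for φ ∈ [0, 1); the verbatim-sign variant sits behind a
  `signed=` flag. The coherence input defaults to the time-averaged
  wavelet spectrum and can share one transform with the wavelet-coherence
  metric.
* **Time-domain MI** — plug-in entropies on Freedman–Diaconis binnings
  (width `2·IQR·n^(−1/3)`; Sturges fallback at zero IQR), natural log, MI =
  `H(X) + H(Y) − H(X,Y)` with marginals read off the joint histogram so MI
  is exactly nonnegative. An optional joint-entropy normalization exists.
* **PID redundancy/synergy** — for each pair, the 4-variable lagged system
  (X_t, Y_t, X_{t+lag}, Y_{t+lag}), lag 1 frame by default, under a
  Gaussian covariance-determinant MI. Redundancy is the minimum of the two
  marginal past→joint-future MIs; synergy is the joint MI minus the union
  information. Rank-deficient 4×4 covariances get a 1e−8·tr/4 ridge with a
  warning.
* **rDCM** — per target region, Bayesian linear regression in the
  frequency domain: the spectrum of the region's discrete temporal
  derivative (transfer `(e^{iωΔt} − 1)/Δt`, DC dropped) on all source
  spectra, real and imaginary parts stacked. Conjugate Gaussian–Gamma
  variational updates iterate to 1e−6 with an ELBO that must not decrease;
  a `fixed_tau` mode reproduces the closed-form Bayesian ridge exactly and
  anchors the tests. Priors: off-diagonal N(0, 1), self-connection
  N(−1, 1) (enforcing decay), τ ~ Gamma(2, 1) — exposed in `RdcmPriors`.
  No driving inputs (resting state) and no explicit HRF in the design: with
  identical regional hemodynamics the HRF cancels between target and source
  spectra; regional HRF variability is a known caveat of this
  simplification. The three EC views are all off-diagonal entries (full),
  the lower directed triangle (incoming) and the upper (outgoing), so each
  triangle view matches the undirected FC feature count.

## Harmonization

ComBat with parametric empirical Bayes: per-edge location/scale model with
site indicators plus covariates (age centered, sex as an indicator),
standardization by the covariate-adjusted grand mean and pooled variance,
normal prior on site locations and inverse-gamma on site scales with
moment-matched hyperparameters, solved by the standard iterative
conditional posterior means to 1e−6. Single-site input is returned
unchanged; a site with fewer than two subjects is an error naming the site.
EB shrinkage makes harmonization only approximately idempotent; the
residual re-adjustment scales with the data scale and shrinks as site
effects become heterogeneous across edges (which makes the prior
informative), so the idempotence test uses heterogeneous planted offsets.
The harmonization fixtures use cross-subject edge noise of SD 0.1, the
typical across-subject variability of Fisher-z correlation edges.

## QC-FC and similarity

QC-FC is the per-edge product-moment correlation across subjects between
edge strength and mean (respiration-filtered) FD; Spearman is available by
flag. Summaries are the mean and the population variance (divisor n) over
valid edges; zero-variance edges become NaN and are counted. Distance
dependence is the Spearman correlation of QC-FC against Euclidean centroid
distance. Sparsity matching keeps each subject's top-k edges by absolute
weight (negative partials are strong connections), ties broken toward the
lower edge index. Metric similarity correlates group-mean edge vectors and
orders them by average-linkage clustering on 1 − r; directed stacks are
mapped onto undirected edges by averaging the two directions first.

## Prediction

The subject-similarity kernel is the correlation between subjects'
vectorized coupling features. Nested cross-validation is family-blocked
(greedy bin-packing of shuffled, size-sorted families into folds — members
of a family never straddle folds) with, at full scale, 20 outer × 20 inner
folds repeated 20 times; the ridge penalty is chosen per outer fold from a
16-point log grid in [1e−4, 1e4] by mean inner-fold accuracy (ties to the
smaller λ), and accuracy is the correlation between true and predicted
scores on the held-out fold. Behavior is residualized on [1, age, sex,
mean FD] with coefficients fit on the training rows only — anti-leakage is
asserted bit-for-bit in the tests. Permutation significance permutes
behavior blockwise by family (same-size families exchange members jointly)
and re-runs a reduced 10-inner/20-outer scheme;
`p = (1 + #{null ≥ observed})/(1 + n_perm)`. Benjamini–Hochberg FDR is
applied across behaviors within a metric.

One eigendecomposition per training set serves the whole λ grid, which is
what keeps the 1,000-permutation scheme tractable.

## Numerical choices and test scales

* Fisher z inputs clipped to ±(1 − 1e−7); coherence clipped to [0, 1] and
  to 1 − 1e−10 inside the log integral.
* Correlation estimators enforce exact output symmetry by averaging with
  the transpose; diagonals are stored as NaN.
* Tests and the acceptance script run reduced problem sizes chosen to keep
  the statistical checks well-powered: QC cohorts of 200 subjects ×
  16 regions × 256 frames (8–12 seeds per condition), prediction cohorts
  of 400 subjects × 20 regions (planted r = 0.3, 5 outer folds),
  permutation-uniformity at 48 subjects with 99 permutations × 120
  repeats, rDCM recovery at 5 regions × 2,000 samples × 30–50 replicates,
  and closed-form MI checks at n = 50,000. The pipeline's default
  benchmark configuration (200 subjects × 50 regions × 500 frames) runs
  all 13 metric columns.

## Known limitations

* The rank-one (leading-eigenvector) contamination model tracks the
  distance-decaying susceptibility only approximately.
* The Gaussian PID estimator cannot capture non-Gaussian redundancy or
  synergy; the full 16-atom information decomposition is out of scope —
  only the redundancy and synergy matrices the benchmark analyzes are
  computed.
* rDCM here is the resting-state regression backbone, not the full
  toolbox: no sparsity-inducing variant, no driving inputs, no explicit
  hemodynamic model.
* ComBat is the parametric EB variant only (no GAM or longitudinal forms).
* Wavelet smoothing is circular in time; edge effects are shared between
  numerator and denominator but not eliminated.
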