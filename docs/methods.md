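# Methods

`osaprog` predicts, at any moment of sleep, the probability distribution of the
time remaining until the next obstructive-sleep-apnea (OSA) onset, using only
the beat-to-beat (RR) interval series of a single subject. This note records
the model, its assumptions, the tunable parameters, and the design choices
made where the design was genuinely open.

## Signal model and features

The method assumes minute-wise apnea annotations (the clinical scoring
granularity) and works on two HRV quantifiers computed per non-overlapping
minute window:

* **NPSD** — the fraction of the RR tachogram's spectral power in the
  low-frequency band 0.04–0.12 Hz, which is elevated under the cyclic
  sympathetic activation of apneic episodes. The tachogram is cubic-spline
  resampled to 4 Hz, linearly detrended, and a Welch periodogram integrated;
  the numerator band is [0.04, 0.12] Hz and the denominator
  [0.003, 0.5] Hz. Band-edge power is obtained by interpolated trapezoidal
  integration, so the value is insensitive to how band edges fall relative to
  the frequency grid. NPSD is unitless in [0, 1], invariant to amplitude
  scaling and offset of the tachogram.
* **LVM** — the longest vertical line of the recurrence plot of the resampled
  minute window, a measure of laminarity/intermittency. Defaults:
  embedding dimension 3, delay 1 sample, fixed off-diagonal recurrence rate
  0.10 (the distance threshold ε is the corresponding quantile of the
  pairwise distances), minimum counted line 2, line of identity excluded.
  Units are resampled-grid samples. These are common RQA defaults and are
  all configurable; no canonical values exist for this application.

A two-sample Kolmogorov–Smirnov screen (default α = 0.01) verifies that a
feature separates apneic from non-apneic minutes; in the original feature
battery this screen is what singled out NPSD and LVM.

## State space

Feature series are embedded by multivariate delay reconstruction: the state at
minute *t* stacks, per feature, the values at *t*, *t−δ*, …, *t−(L−1)δ*.
Defaults are L = 5 lags per feature and δ = 1 min, i.e. a 10-dimensional state,
consistent with the dimension indicated by the false-nearest-neighbors (FNN)
test on HRV feature data. The FNN estimator uses the Kennel criteria
(rtol = 15, atol = 2, threshold 1%, Theiler window 1 min) and is validated on
classic systems (a sinusoid needs 2 dimensions, the Lorenz x-coordinate 3).
Gaps in the minute index (minutes with too few beats) split the series into
segments embedded independently.

## Learned components

* **Apnea/non-apnea partition.** A soft-margin RBF-SVM on standardized state
  vectors (defaults γ = `scale`, C = 1), with stratified k-fold
  cross-validated sensitivity/specificity reported.
* **DPMG.** A Dirichlet-process mixture of Gaussians clusters the states:
  collapsed Gibbs sampling under a conjugate Normal–Inverse-Wishart base
  (μ₀ = data mean, κ₀ = 0.1, ν₀ = d+2, Ψ₀ = diag of the data variance),
  concentration α = 1, 500 sweeps by default. The sampler is initialized with
  every point in its own cluster — single-site Gibbs merges clusters easily
  but splits them very slowly, so a fully split start avoids under-clustered
  modes. The modal partition (the most frequently visited canonicalized
  assignment over the second half of the sweeps) defines the clusters.
* **Local GPs.** Each cluster with ≥ 5 members receives a Gaussian process
  (squared-exponential + white noise, hyperparameters by marginal-likelihood
  maximization, one restart) regressing the next state on the current state.
  Because a GP fitted on a handful of points interpolates its training data
  and reports near-zero predictive variance even when the one-minute dynamics
  are genuinely stochastic, the closed-form leave-one-out residual
  *covariance* of each cluster's GP is added to its predictive covariance.
  This both floors the variance at an honest estimate of the irreducible
  one-step noise and preserves the cross-dimension correlation of regime
  jumps, which a shared-kernel multi-output GP cannot represent. Clusters
  with < 5 members fall back to the global mean one-step map with twice the
  global successor covariance.

A query state is assigned to the existing cluster with maximal posterior
predictive membership (cluster size × Student-t predictive density); no new
cluster is opened at prediction time, so prediction is defined everywhere.

## Block graph and transition estimation

States are quantized on a uniform lattice of 20 bins per dimension
(left-closed bins, last bin right-closed; only occupied cells are
materialized — a dense 20¹⁰ lattice is infeasible and unnecessary). Each
occupied cell is a graph node, labeled apneic/non-apneic by the SVM partition
evaluated at the cell's member-state centroid (annotation-majority labeling,
ties to non-apneic, is available for evaluation).

Three transition estimators are provided:

* `empirical` — first-order counts between consecutively visited blocks with
  0.5 pseudo-counts over *observed* successors only. At minute resolution a
  night of data leaves roughly one state per occupied cell, so this chain
  degenerates to a deterministic replay of the training trajectory; it is
  retained for densely sampled regimes and for testing.
* `dpmg` — row *i* is the DPMG one-step predictive distribution from block
  *i*'s centroid, propagated through the quantizer by Monte-Carlo: samples
  from the full-covariance Gaussian predictive are assigned to their lattice
  cell (samples in unvisited cells go to the nearest occupied block, exactly
  as live queries are handled). Sampling preserves the predictive's
  correlations; integrating marginal CDFs over cells would not.
* `blend` (default) — empirical counts plus the `dpmg` row scaled to one
  pseudo-observation: the observed successors anchor the transitions the
  data actually made, while the model supplies dispersion where a single
  visit would otherwise make the chain deterministic.

A Laplacian eigenmap of the symmetrized weights W = (P+Pᵀ)/2 (symmetric
normalized Laplacian, eigenvectors V₂–V₄, signs fixed by making each
eigenvector's largest-magnitude entry positive) provides the low-dimensional
coordinates in which strongly connected blocks lie close together. On a
disconnected graph the degenerate zero eigenspace is replaced by the
canonical piecewise-constant basis so each component receives constant,
distinct coordinates. The projection is used for visualization and block
layout; the time-to-onset computation runs on the block chain itself, keeping
the Markov estimate exact.

## Time to onset

From a non-apneic block *k* the time *T* until first entry into the apneic
block set is discrete phase-type:

    Pr[T = t | k] = e_kᵀ Q^{t−1} r,   t = 1, 2, …

with Q the transition matrix restricted to non-apneic blocks and
r = 1 − Q·1 the one-step apneic-entry probabilities. This closed form equals
the explicit concatenation of all transient paths weighted by their
transition products; the test suite enforces three-way agreement between the
matrix form, brute-force path enumeration, and Monte-Carlo first-passage
histograms. The default horizon is H = 120 min; mass beyond the horizon is
reported separately, the expectation is computed on the renormalized
within-horizon mass (flagged when > 5% of mass is truncated), the 95% CI is
the pair of discrete quantiles (smallest t with renormalized CDF ≥ 0.025 /
≥ 0.975), and the risk indicator at t minutes is the raw cumulative
probability Pr[T ≤ t]. An apneic current block yields a degenerate
"onset now" distribution.

## Pipeline protocol

The first 60% of a record's minutes (chronological, to avoid leakage) train
the partition, the DPMG and the block graph; per-minute predictions are
emitted for the remainder and scored by R², 95%-CI coverage and residuals
binned by true horizon. "Onset now" outputs — minutes whose state falls in an
apneic block — are detections rather than prognoses (the time-to-onset
distribution is defined from non-apneic blocks) and are excluded from the
time-to-onset evaluation.

## Synthetic data

The generator emulates the statistical structure the method relies on:
minute labels follow a two-state Markov chain switching at minute boundaries
(defaults p_enter = 0.15, p_exit = 0.30, i.e. stationary apnea fraction 1/3
and mean bout ≈ 3.3 min, between the severities of the two public apnea
databases); apneic minutes carry a sinusoidal RR modulation at 0.08 Hz with
60 ms depth; non-apneic minutes carry weak smoothed-noise wander
(≈ 3 s correlation, amplitude depth/8) plus 5 ms white jitter; the default
record is 400 minutes at mean RR 1000 ms. All output is a pure function of
the configuration and seed.

What the generator does **not** emulate — and what passing tests therefore do
not show about real data:

* **No pre-onset physiology.** Because the label chain is memoryless and
  non-apneic minutes carry noise only, the true time-to-onset from any
  non-apneic minute is Geometric(p_enter) *independently of the observable
  past*. A calibrated model therefore attains R² ≈ 0, and the mean risk
  indicator evaluated at the true distance t follows the geometric CDF
  1−(1−p_enter)ᵗ, *increasing* with t. On real recordings, pre-onset
  autonomic changes make states informative, which is what produces high R²
  and risk indicators that decline with distance to onset; demonstrating that
  requires real data. What the synthetic pipeline does demonstrate is
  *calibration*: the 95% CI of the predicted distribution covers the observed
  time-to-onset at the nominal rate.
* Under the fixed-recurrence-rate normalization, the periodic apneic
  modulation yields *shorter* longest-vertical-lines than the aperiodic
  background wander, so the LVM contrast is reversed relative to real apnea
  (the KS screen and the classifier are direction-agnostic, so the pipeline
  is unaffected).
* No ECG morphology, sleep stages, arousals, SpO₂ or respiratory coupling.

Markov block-graph fixtures (random Dirichlet rows, designated absorbing
apneic blocks, rejection-sampled for reachability) provide analytically known
first-passage laws, including the exact geometric case used as the anchor
test.

## Numerical choices and problem sizes

Tolerances: transition rows sum to 1 within 1e-9; oracle equivalence of the
first-passage forms is enforced at 1e-12; eigendecompositions are compared to
dense oracles at 1e-8 up to sign. Ties: equidistant nearest-block queries go
to the lexicographically smaller block id; annotation-majority ties label a
block non-apneic. Degenerate inputs: constant tachogram windows return
NPSD 0 with a warning; zero-range state dimensions collapse to one bin;
blocks with no observed successor become self-loops with a warning.

The shipped tests and the acceptance script run on 400-minute simulated
nights (two nights pooled for evaluation, ≈ 140 scored minutes), 120–500
Gibbs sweeps, and 200 000 Monte-Carlo trajectories for the first-passage
check; these sizes give stable statistics on a single CPU in minutes.

## Known limitations

* The DPMG transition rows are estimated from a point model; parameter
  uncertainty of P itself is not propagated into the time-to-onset CI.
* The Gaussian (single-mode) predictive per cluster approximates what is
  really a jump mixture; the LOO-covariance floor widens it appropriately
  but cannot make it bimodal.
* WFDB support is limited to text headers, format-16 signals and the
  minute-wise apnea annotation dialects; other formats need conversion.
* Quantization at 20 bins/dimension in the full embedded space leaves ~one
  state per occupied cell at single-night sample sizes; all distributional
  structure then comes from the DPMG component of the transition estimate.
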