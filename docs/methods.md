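# Methods

`connage` implements a functional brain-age pipeline on component
time courses: post-ICA denoising, static and tapered sliding-window dynamic
functional network connectivity (sFNC / dFNC), cross-validated brain-age
regression at wide-brain and sub-network level, and covariate-adjusted
association of brain-age gaps (BAG) with cognitive scores under
Benjamini–Hochberg FDR control. Because the cohorts this class of analysis
targets (UK Biobank, HCP, clinical multi-site samples) are access-controlled,
the package ships a synthetic-cohort generator with known ground truth; every
stage is validated against that ground truth and against independent
brute-force oracles.

## Time-course preparation

Each scan is a frames × components matrix with a repetition time (TR). The
denoising chain runs in a fixed order:

1. **Polynomial de-trending** — least-squares removal of the constant plus
   linear, quadratic and cubic terms over normalized time. Output is exactly
   mean-free per component.
2. **Nuisance regression** (optional) — residualization on an intercept plus
   supplied regressors (e.g. realignment parameters), with backward-difference
   temporal derivatives appended (first row zero). Rank-deficient designs are
   rejected naming the collinear columns.
3. **Outlier removal** — values beyond `median ± 3.5 · 1.4826 · MAD` per
   component are clipped to the bound. Clipping (rather than censoring) is
   deterministic and shape-preserving, which keeps window bookkeeping intact;
   the threshold is configurable. Constant components pass through with a
   warning.
4. **Low-pass filtering** — 5th-order Butterworth below 0.15 Hz, applied
   forward–backward (zero phase) with odd-symmetric padding of length
   3 × order. On white noise at TR 0.72 s, less than 2% of the output power
   remains above 0.18 Hz.

A note on idempotence: the chain is idempotent (second pass changes RMS by
< 0.1%) only for signals inside the filter passband. Broadband input keeps
losing transition-band power on every pass — a Butterworth filter is −3 dB
at its cutoff by construction — so the idempotence check uses band-limited
Gaussian input.

Scans from heterogeneous protocols are harmonized by **tail truncation to
the shortest duration** (min over scans of frames × TR), each scan keeping
its leading `floor(duration/TR)` frames in native sampling. No resampling is
performed: connectivity is TR-agnostic once windows are specified in TR
units. With protocol durations of (490 × 0.735 s, 1200 × 0.72 s,
1100 × 0.8 s, 162 × 2.0 s) the common duration is 324 s = 5.4 min.

## Connectivity

**Static FNC** is the Pearson correlation between every component pair over
the full scan; for the 53-component NeuroMark template this gives a 53 × 53
matrix and C(C−1)/2 = 1378 upper-triangle features. Vectorization uses
row-major strict-upper-triangle order and is exactly invertible.

**Dynamic FNC** computes the same correlation inside a tapered sliding
window: a rectangle of `width_tr` frames (default 20 TR — 14.7 s at the
UK-Biobank-like TR of 0.735 s) convolved with a Gaussian kernel of σ = 3 TR
truncated at ±3σ, normalized to sum 1 (support 20 + 2·9 = 38 frames). The
taper weights the correlation *moments* (weighted means, variances,
covariance) rather than multiplying the data; this choice makes the
uniform-taper case reduce exactly to the static formula, and a full-width
uniform window reproduces the static matrix bit-for-bit. Only fully
supported window placements are used (no partial edge windows), stride 1 TR
by default; T = floor((frames − support)/stride) + 1 windows stack into a
C × C × T array.

Source descriptions of this family of pipelines are inconsistent about the
window width (20 vs 40 TR appear in different places); the default here is
20 TR, with the width fully configurable. No Fisher z-transform is applied
by default (available as `fisher_z`).

**Sub-network blocks** restrict the matrix (or array) to one of the seven
canonical networks — subcortical (5 components), auditory (2), sensorimotor
(9), visual (9), cognitive control (17), default mode (7), cerebellar (4) —
shipped as a two-column CSV following the NeuroMark fMRI 1.0 labeling.
Within-network features are the block's strict upper triangle; restriction
and vectorization commute.

## Brain-age models

Three regressor families share one protocol, implemented as scikit-learn
estimators (`fit(X, y, groups)` / `predict`):

* **`RidgeBrainAge`** — standardized features into ridge regression. A fast,
  closed-form, fully deterministic baseline (not part of the original
  modeling suite; used for smoke tests and calibration studies).
* **`GraphConvBrainAge`** — the connectivity matrix serves both as graph and
  node features: A = row-normalized |FNC| propagates, H₀ = FNC rows, each
  layer computes `H ← relu(A H W + b)` (default widths 64, 32), node
  representations are global-mean-pooled, and a linear readout predicts age.
* **`BiLSTMBrainAge`** — the sequence of vectorized window correlations runs
  through stacked bidirectional LSTM layers (default 3 layers × 128 hidden
  units, dropout 0.1 between layers); the concatenated final hidden states
  of both directions feed a linear readout. For desk-scale runs an
  unsupervised top-variance edge reduction keeps sequences small.

Both neural families are trained with Adam on mean absolute error (learning
rate 1e−3, batch size 64, 100 epochs by default), targets standardized
internally. The networks are implemented directly in NumPy with analytic
backpropagation (verified against numerical gradients to < 1e−5 relative
error), which makes training single-threaded and bit-reproducible under a
fixed seed.

**Protocol.** K = 5-fold cross-validation (GroupKFold when subjects
contribute multiple scans, so no subject spans folds); per-fold validation
MAE curves are recorded; each fold's best epoch is the arg-min of validation
MAE; the final model is refit on all data at the median best epoch. A fold
ensemble is available via `ensemble=True`; refit is the default so one
deployable model results. Validation r/MAE are reported from pooled
out-of-fold predictions.

Sub-network models train one predictor per network on within-network edges
only (the graph family takes the component-restricted matrix).

## Synthetic cohorts

The generator plants the structure the pipeline must recover:

* **Base connectivity**: a random correlation matrix (Wishart draw shrunk
  halfway to the identity for headroom).
* **Aging edges**: a random 15% of edges drift linearly in correlation with
  *effective age* at `aging_slope` (default 0.005/yr) around the age-range
  midpoint. Each per-subject covariance is projected to the nearest valid
  correlation matrix (eigenvalue clipping at 0, diagonal renormalization);
  constructions needing clipping beyond `psd_repair_tol` are refused with
  advice to lower the slope.
* **Connectivity states**: a first-order Markov chain (self-transition
  1 − 1/dwell) switches among covariance states that perturb a *separate*
  random edge set by ±0.2. Drawing the state edges apart from the aging
  edges is deliberate: if states perturbed the aging edges themselves,
  random state-occupancy fluctuations would shift every aging edge
  coherently — common-mode noise worth ~6 y of age signal that no amount of
  edge averaging can remove.
* **Aging modes**: `shared` (default) applies the age shift identically in
  all states. `state_specific` partitions the aging edges across states.
  `early_scan` confines the shift to the first `aging_envelope_fraction` of
  frames, emulating time-on-scan nonstationarity (e.g. arousal decay): the
  full-scan average then sees only the envelope-diluted signal while
  windowed connectivity time-resolves it. This is the regime in which the
  sequence model demonstrably outperforms ridge-on-static — for stationary
  Gaussian state mixtures, every linearly accessible dynamic signal is
  equally present in the full-scan correlation, so a genuine dFNC advantage
  requires temporal structure of this kind.
* **Effective age** = chronological age + 7 y × diagnosis + N(0, `accel_sd`²)
  individual acceleration (default 7 y, the scale of brain-age deviations
  reported for clinical populations). True BAG is exactly effective minus
  chronological age. The continuous acceleration term is essential: were
  diagnosis the only source of BAG, the BAG–cognition association would be
  identically zero after diagnosis adjustment.
* **Sites**: per-site per-component mean shifts, N(0, 0.1²).
* **Cognition**: attention and working-memory scores are
  `−0.5 × trueBAG + noise`, with independent noise per score sized
  (SD 11.1) so the planted partial correlation is −0.30. The instruments are
  abstract and unit-free; intercepts are zero.

Cohort defaults mirror a healthy adult training population: ages uniform on
22–100, 490 frames at TR 0.735 s, 53 components, 7 sites, no diagnosed
subjects. Everything is drawn from a single seeded generator, so identical
configs give byte-identical cohorts.

What the generator does *not* emulate: hemodynamics, spatial maps, motion,
non-Gaussian marginals, autocorrelated noise within states, scanner drift.
Passing tests therefore demonstrate correctness of the estimators and the
statistical machinery under the planted model, not performance on real
fMRI.

## BAG association analysis

BAG = predicted − chronological age, joined one-to-one on subject id. The
association GLM regresses a cognitive score on
`[intercept, BAG, age, sex, site dummies, age², age×sex, diagnosis]` by OLS,
restricted to participants older than 38 y (brain-age models are unreliable
in under-represented young adults). Age is mean-centered before squaring and
interacting — pure conditioning, the BAG coefficient is unaffected. The
reported effect is the BAG coefficient (β, SE, t, two-sided p, 95% CI from
the t distribution) plus the partial correlation `r = t/√(t² + df)` — the
only definition under which a single GLM yields both β and r. No BAG bias
correction (residualization on age) is applied by default since age terms
are already covariates; `correct_bag_bias` implements the standard
correction for sensitivity analyses.

FDR families follow the analysis design: per outcome, the two wide-brain
modality tests form one Benjamini–Hochberg family and the 7 × 2
network-modality tests another. Adjusted p-values are step-up BH (via
statsmodels, verified against a hand-applied step-up oracle); significance
is adjusted p < 0.05.

Under the null, the BH family-wise rejection rate sits at ≈ α by
construction, so calibration checks use the binomial band [0.02, 0.09]
around α = 0.05 rather than a point threshold.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the acceptance script (the
package's own choice of study sizes): recovery cohorts of n = 400 subjects
with 20 components and 150–450 frames; GLM calibration at n = 150 with 100
(recovery) and 200 (null) replicates; the demo pipeline at n = 120 with 10
components. The neural families run reduced architectures at this scale
(graph widths 32/16 at 150 epochs; biLSTM 32 hidden × 1 layer at 60 epochs
over top-50-variance edges) — with them, all three families recover planted
aging at validation r ≥ 0.87, against a ceiling of ~0.95 set by
finite-scan correlation noise.

Ridge regularization deserves a note: for BAG *association* work, heavy
shrinkage (α ~ 10³ on standardized features) is preferable — prediction
shrinkage toward the mean is absorbed by the GLM's age covariates, while the
variance reduction sharpens the BAG's correlation with true acceleration.
For recovering the *scale* of a group shift (e.g. the planted +7 y diagnosis
effect), light shrinkage (α ~ 10²) preserves the regression slope better at
the cost of noisier gaps.

Other numerics: correlations are clipped to [−1, 1] against floating-point
spill; degenerate (zero-variance) components raise errors naming the
component; weighted correlations require strictly positive weighted
variance; LSTM forget-gate biases initialize to 1; Adam uses the standard
(β₁, β₂, ε) = (0.9, 0.999, 1e−8).

## Known limitations

* The graph-convolution architecture is one reasonable reading of
  "connectivity matrix as graph + node features"; published variants differ
  in propagation operators and pooling.
* Whether sub-network models should see all edges touching a network rather
  than only within-network edges is a design choice; within-network is used.
* Tail truncation discards late-scan data from longer protocols rather than
  resampling; cross-TR comparability relies on windows defined in TR units.
* The generator's Gaussian state-switching model cannot express
  hemodynamic or spectral differences between cohorts; TR enters only
  through filtering and window arithmetic.
* Neural training is CPU-bound NumPy; it is meant for desk-scale cohorts
  (hundreds of subjects), not biobank-scale data.
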