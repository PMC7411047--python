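# Methods

This note documents the models, estimators, and numerical choices behind
`flashgrab`, and what the synthetic-data generators do and do not emulate.

## Conventions

All angles are degrees; polar angle is 0° at the upper vertical meridian,
positive clockwise, wrapped to [−180°, 180°). Times are milliseconds
relative to flash onset; EEG amplitudes are microvolts; fMRI amplitudes are
arbitrary response units standing in for GLM betas. All randomness flows
from explicit integer seeds; every generator expands its seed into
per-subject substreams (`numpy.random.SeedSequence.spawn`), so enlarging a
study never changes earlier subjects' data.

## Psychometric model and TAE

The observer model is the four-parameter logistic
`p(x) = γ + (1 − λ − γ)/(1 + e^{−β(x−α)})` fitted by least squares to
per-angle response proportions — the quantity the experiments plot — rather
than by trial-level likelihood.

Estimator details:

* **PSE ≡ α**, the logistic's inflection, not the x where p = 0.5. The two
  differ when γ ≠ λ; α is shift-equivariant and is what the TAE contrast
  needs.
* **Bounds**: β ∈ (0, 100]; γ, λ ∈ [0, 0.06]; α within the tested angle
  range extended by two range-widths. The tight asymptote bound follows
  standard psychometric-fitting practice: with only seven test angles, wide
  guess/lapse bounds let a four-parameter least-squares fit reach
  near-interpolating solutions (γ/λ absorbing response levels, β pinned
  steep, α dragged toward the inner test angles), which destroys the
  identifiability of the PSE. Restricting the asymptotes to plausible lapse
  rates removes that failure mode; parameter-recovery simulations in the
  test suite quantify the residual small-sample bias.
* **Optimization**: multi-start trust-region least squares (analytic
  Jacobian) from α ∈ {25th, 50th, 75th percentile of the test angles} ×
  β ∈ {0.5, 2, 8}; winner by lowest residual SS, ties by smallest |α|;
  SS tolerance 1e−8, iteration cap 200 evaluations per start. A fit with
  residual SS ≤ 1e−10 is reported converged even if the optimizer exhausted
  its iterations wandering the (flat) manifold of perfect fits.
* **Degenerate data** (all proportions identical) raise an error rather
  than returning an arbitrary slope.

TAE = |PSE₊ − PSE₋| / 2 over the two adaptation directions; it is symmetric
in its arguments and invariant to a common shift of both PSEs.
Adjustment-task summaries sign-align settings by rotation direction,
average within subject, and report the mean and SD across subject means;
subjects missing a direction are excluded with a warning, not imputed.
Group statistics are the standard paired t with Cohen's d on the
differences and Holm step-down multiplicity adjustment.

## fMRI polar-angle and laminar analysis

Voxels enter as a table (area, polar-angle preference, cortical depth
fraction, response per illusion condition); GLM fitting, retinotopic
mapping and depth estimation are upstream and out of scope.

* **Binning**: 1°-wide half-open bins [k, k+1); bin value = mean amplitude
  of member voxels; empty bins filled by circular linear interpolation
  (configurable off).
* **Equal-area estimate**: within a hemifield window (upper = [−90°, 90°),
  lower = complement), the angle where cumulative area reaches half the
  window total, treating each bin as a uniform 1° slab with linear
  interpolation inside the crossing bin. Negative bins are clipped to zero
  first (the statistic needs a measure) and the clip count is surfaced as a
  warning. A single occupied bin therefore yields its slab midpoint (e.g.
  bin [10, 11) → 10.5°). The estimate is computed on raw (unnormalized)
  curves by default; normalization does not change it when applied jointly.
* **Condition difference**: absolute circular difference of the CW and CCW
  equal-area angles — the summed clockwise plus counter-clockwise
  displacement, i.e. twice the per-direction shift.
* **Layers**: depth bins S [0, 0.4), M [0.4, 0.8), D [0.8, 1.0]
  (right-open except the last). Per area × layer, CW and CCW curves are
  jointly min–max normalized (one shared scale, preserving every
  between-condition ordering), then
  `illusory = (mean_{[6,14]}(CW−CCW) + mean_{[−14,−6]}(CCW−CW)) / 2` — the
  two mirrored windows averaged so a consistent perceptual rotation gives
  one positive scalar — and `input = mean_{[−4,4]}((CW+CCW)/2)`. Windows
  take bins whose centers lie inside the closed interval.
* **Hamming smoothing** (60° unit-sum circular kernel) exists for display
  only and never feeds estimates or indices.
* **Within-subject CIs** use the Cousineau transform: subtract each
  subject's mean across conditions, add the grand mean, then take
  per-condition t-based intervals of the transformed values. (No Morey
  cell-count correction is applied; the transform itself is the contract.)

## EEG analysis

* **Preprocessing**: per-trial zero-phase (forward–backward) 4th-order
  Butterworth band-pass 1–35 Hz — zero-phase so component latencies are
  preserved; baseline correction over [−100, 0] ms; rejection of trials
  whose absolute excursion at the ocular channel (VEO) within
  [−100, 300] ms exceeds 75 μV.
* **Electrode selection**: the n = 5 posterior electrodes with the largest
  absolute grand-ERP amplitude in the C1 window (60–100 ms, configurable);
  ties break by channel name.
* **Difference waves**: per trial, the contralateral hemisphere follows the
  trial's side label; the wave is the condition-averaged contra − ipsi
  signal averaged over homologous pairs, default
  (P3,P4), (P5,P6), (PO5,PO6), (PO7,PO8), (O1,O2). Background-only trials
  are labeled by rotation direction — the side a bar *would* have been
  perceived. Relabeling every trial's side flips the wave's sign exactly.
* **Mini-ERPs**: k trials drawn without replacement within one sample,
  independently across samples; n_samples per class. Averaging k i.i.d.
  trials divides the noise SD by √k (3-fold at the default k = 9). As a
  deterministic special case, k = 1 with n_samples equal to the class size
  returns the raw trials exactly once.
* **Decoding**: per subject and time point, stratified 10-fold CV at the
  raw-trial level; mini-ERPs built independently inside the training and
  test portions of each fold; per-electrode standardization fitted on
  training samples only (the leakage-free reading of an ambiguous
  procedure); linear SVM with C = 1.0 (liblinear primal). Ocular channels
  are excluded from the feature set.
* **Cross-decoding**: raw trials (k = 1) on a decimated grid (default every
  10th sample); across conditions the classifier trains on all trials of
  one condition and tests on all of the other; within one condition every
  matrix entry is computed across stratified folds so no entry reuses
  training trials.
* **Inter-subject correlation**: Pearson r across subjects between the
  instantaneous difference-wave amplitude and illusion size, per time
  point; zero-variance sizes yield NaNs with a warning.

## Cluster-mass permutation inference

Mass-univariate t (or r) maps are thresholded — two-tailed t critical value
at the cluster-defining p (default 0.05; one-tailed available by flag), or
|r| > 0.5 for correlations — and maximal same-sign connected components
form clusters (1D adjacency; 4-neighbour lattice for 2D maps, 8-neighbour
by flag). Cluster mass is the sum of the raw statistic (Fisher-z for r by
flag). The null records, per permutation, the maximum and minimum cluster
mass (0 when a permutation has no cluster, which keeps the percentiles
defined); critical values are the 97.5th percentile of the max and 2.5th of
the min distributions, computed as outward-rounded order statistics so the
discrete permutation distribution cannot make the test liberal;
significance requires strictly exceeding the critical value (ties lose). Within-subject left/right label exchange equals
a sign flip of the paired difference, so one sign-flip engine implements
both schemes; when 2ⁿ ≤ n_perm all sign patterns are enumerated exactly
(the test is then exact), otherwise random patterns are drawn with the
observed labelling included in the null — the standard guarantee of test
validity. Degenerate zero-variance points are masked to t = 0. Bootstrap
bands resample subjects with replacement (default 1000 draws) and take
percentile intervals of the resampled mean; percentile intervals undercover
mildly for small n (≈0.90 at n = 15, ≈0.95 by n = 50), which the test suite
documents.

## Synthetic-data generators

The generators produce data with the statistical structure the analyses
assume — they are calibration instruments, not models of physiology. In
particular: psychophysical observers are exactly the logistic the fitter
assumes; voxel tuning and EEG component shapes are smooth bumps chosen for
analyzability; noise is Gaussian (white, plus 1/f for EEG). Passing tests
therefore demonstrate estimator correctness and calibration on in-model
data, not robustness to the messiness of real recordings (drifts, artifacts
beyond the modeled VEO excursions, correlated noise, non-logistic
observers).

* **2AFC**: Bernoulli draws from the four-parameter logistic at the seven
  printed test angles (±6.9, ±2.3, ±1.1, 0), 20 trials per angle by
  default.
* **Adjustments**: per-subject true tilt ~ Normal(15.55°, 7.54°) matching
  the printed group statistics; settings add Normal(0, 2°) within-subject
  noise — a plausible motor/criterion jitter, unstated in the source — and
  are signed by rotation direction; 8 subjects × 5 settings per direction.
* **Voxel tables**: voxels are allocated to the three depth layers in
  proportion to layer thickness; each layer tiles polar angle on its own
  uniform grid while depth fractions are uniform within the layer's range
  (hence uniform marginally). Per condition, amplitudes are unit-peak
  tuning bumps centred at the meridian ± the layer's illusory shift. The
  default tuning profile is a raised cosine with compact support (±2×
  the width parameter, default width 25°): with exactly zero tails,
  hemifield-window truncation cannot bias the equal-area estimate, so
  noiseless tables reproduce configured shifts *exactly* — the oracle the
  property suite relies on. A Gaussian profile is available by option.
  Default shifts put most displacement in superficial layers and in
  extrastriate areas (V1 S/M/D = 8/1/4°, V2 ≈ V3 ≈ 12–16°), qualitatively
  matching the laminar feedback account; they are generator conditions,
  not estimates.
* **EEG**: 64-channel Neuroscan-style montage (incl. VEO/HEO), 1000 Hz,
  epochs −100 to 500 ms. Three conditions × two sides per subject: an
  early lateralized component supported on 46–98 ms (retinal condition), a
  mid-latency component on 118–161 ms (background, also present in
  illusory), and a late component on 178–400 ms whose amplitude is
  gain × illusion size (illusory only), with illusion sizes ~
  Normal(6.25°, 2.35°). Component time courses are raised cosines supported
  exactly on their windows; lateralization loads ±amplitude/2 on two
  disjoint posterior channel groups (P3/P5/PO5/PO7/O1 vs. homologues) so
  the contra-minus-ipsi wave equals the nominal amplitude exactly. Noise is
  white (5 μV) plus 1/f-shaped (5 μV) Gaussian per channel and trial —
  1/f keeps decoding nontrivial; there is no forward head model, no
  inter-channel correlation structure, and no hemodynamic or ocular
  physiology.

## Problem sizes used in calibration runs

The calibration suite uses the study's sample sizes where they are the
point of the check (12 subjects and 200 trials/class for chance-level
decoding; 8 subjects for psychophysics recovery; 1,000 null datasets ×
1,000 permutations for the family-wise error rate) and a 50-point EEG time
grid (every 12th sample of the 600-sample epoch) for the decoding
calibration, since chance-level behaviour is time-point-exchangeable.
Recovery targets average 50 (TAE) and 100 (adjustment) independent
replicate studies.

## Known limitations

* The psychometric fit is least squares on proportions; no trial-level
  likelihood, no Bayesian/adaptive estimation, no staircases.
* The equal-area estimator needs a non-negative curve; strongly negative
  BOLD responses are clipped, which biases the split if clipping is heavy.
* The permutation engine assumes exchangeability under sign flips of
  per-subject maps; it offers no TFCE or random-field corrections.
* Cross-decoding trains on full conditions (no per-entry recalibration);
  within-condition matrices are fold-averaged, so off-diagonal entries mix
  temporally adjacent training folds.
* The EEG generator's two-group lateralization is the simplest structure
  that exercises every analysis; topographic realism (volume conduction,
  reference effects) is out of scope.
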