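# Methods

This note documents the models, numerical choices and limitations of
`prosorew`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Design and coding

The task is a 2 × 2 × 2 within-participant factorial: beneficiary
(self −0.5 / other +0.5), magnitude (small −0.5 / large +0.5), time
(immediate −0.5 / delayed +0.5).  All analyses share one canonical cell
ordering (beneficiary slowest, time fastest) and one 8 × 8 cell-by-term
design matrix whose columns (intercept, three mains, three two-ways,
three-way) are mutually orthogonal under the centred ±0.5 coding.  The
matrix is invertible, so term coefficients and cell means are
interchangeable representations; the generator, the mixed models and the
contrast machinery all use the same matrix, which is what makes noiseless
round-trip recovery exact.

## Synthetic cohorts

The generator emulates feedback-locked EEG from this task, not EEG in
general.  Per participant:

* **Deflections** (reward positivity, P3): a temporal Gaussian
  (peak latency, FWHM) times a spatial Gaussian over 2-D electrode
  positions.  Defaults: RewP peak 310 ms / FWHM 100 ms centred at FCz; P3
  370 ms / 120 ms at Pz; spatial spread 0.35 head-radius units, chosen so
  the two-channel scoring ROI carries >80% of the source amplitude.
* **Bursts** (delta 2 Hz at CPz, theta 5.5 Hz at FCz): Gaussian-enveloped
  sinusoids with per-trial uniform random phase, so they contribute to
  single-trial power but largely cancel in the ERP average; a phase-locked
  fraction is configurable (default 0).
* **Amplitudes** follow the factorial model: population term coefficients
  plus participant-level Gaussian deviations on a configurable subset of
  terms plus trial-level Gaussian noise.  The ERP coefficient defaults
  (e.g. magnitude +2.49 μV, beneficiary −2.51 μV on the RewP, with a
  positive three-way term) reproduce the qualitative egoism-bias pattern —
  magnitude effect self > other when rewards are immediate, comparable when
  delayed — at a realistic single-trial noise level (8 μV SD).  Burst
  coefficients are specified in μV of oscillatory amplitude; their effect
  sizes in normalized-power units are emergent, not set directly.
* **Background**: 1/f^α noise (α default 1.0) synthesized by spectral
  shaping of white noise plus white sensor noise (2 μV SD).  The shaping
  includes a Gaussian spectral roll-off above 60 Hz emulating the steep
  high-frequency decay of scalp recordings; without it, shaped noise
  retains enough broadband energy to produce sample-to-sample steps that no
  artifact-free recording shows.
* **Artifacts**: per-trial Bernoulli injection of four classes — a
  one-sample 80 μV spike (step), a smooth 250 μV excursion (range), a
  frozen 150 ms stretch (flatline), a ±160 μV linear ramp (drift) — each
  comfortably beyond its screening threshold.  Ground truth records every
  flag; an injection may incidentally trip a second rule, as real artifacts
  do.
* **Ratings**: one latent Gaussian value per cell around the participant's
  cell means, rounded and clipped to the 1–9 scale.

What the generator does **not** emulate: ocular/muscle physiology, volume
conduction from dipolar sources (spatial profiles are Gaussian, not
forward-modelled), channel-correlated noise, bad channels, or continuous
(pre-epoch) recording structure.  Passing recovery tests therefore shows
the *analysis chain* is correct and calibrated, not that it is robust to
every pathology of real recordings.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning (one child per participant), so
cohorts are bit-identical across reruns.

## Preprocessing

* Band-pass: Butterworth order 2 (12 dB/octave) applied forward-backward
  (`sosfiltfilt`, odd-reflection padding), i.e. zero-phase with doubled
  effective attenuation.  Filtering operates on epochs; with a 0.1 Hz
  corner the impulse response is long relative to an epoch, so slow-edge
  effects are possible near epoch boundaries — a documented compromise of
  epoch-wise filtering (continuous-data filtering is out of scope).
* Artifact screen: strict inequalities at all four thresholds (a value
  exactly at threshold does not fire).  Flatline means: some 100-ms window
  (sliding one sample at a time) on some channel in which every
  consecutive-sample difference is < 0.5 μV.  Drift is the per-channel
  least-squares slope expressed as μV over the whole epoch, compared
  against 100 μV; the per-epoch unit is a package choice where the
  convention is ambiguous, and the threshold is a parameter.
* Pipeline order is re-reference → artifact screen → filter → baseline:
  the screen runs on unfiltered voltages because a 35 Hz low-pass smears
  step artifacts below the 50 μV/sample criterion, which would blind the
  rule that exists to catch them.
* Rejection drops a trial if any enabled rule fires on any channel; the
  report lists the firing rules per trial, and an all-rejected outcome is a
  warning state, never a silent success.

## Single-trial scoring

Mean amplitude over a fixed window and ROI; window endpoints are inclusive
on the sample grid (260–360 ms at 500 Hz = 51 samples).  Scores carry μV
for ERP measures and welded-z units for band power.  Split-half
reliability: trials are split within each design cell (stratified), the
per-participant half-means are correlated across participants and
Spearman-Brown corrected (2r/(1+r)); the default averages 100 random
splits, with an odd/even option.  The random-split default is a package
choice where splitting schemes differ across labs; with small cohorts the
corrected estimate is noisy and can legitimately fall below zero.

## Time–frequency decomposition

Complex Morlet bank: 30 frequencies geometrically spaced 1→30 Hz, cycle
counts geometrically spaced 3→10 and paired index-wise, so temporal SD is
cycles/(2πf).  Wavelets are truncated at ±3.5 temporal SD and scaled so
the frequency response peaks at gain 2: a unit-amplitude sinusoid at a bank
frequency then yields unit peak power at any frequency, making power read
as amplitude² on the ridge.  Epochs are reflection-padded by one
half-wavelet at the lowest frequency before FFT convolution; an epoch
shorter than that raises an error naming the required padding.  The 3.5-s
epoch window (−1500…+2000 ms) exists precisely so that 1 Hz edge artifacts
stay clear of the −500…+1000 ms analysis range.

**Welding baseline.**  For each channel × frequency, the baseline-window
(−500…−300 ms) power samples of *all* trials are pooled into a single long
vector; its mean μ and SD σ standardize every sample of every trial:
z = (p − μ)/σ.  After normalization the pooled baseline has mean 0 and
SD 1 exactly, and the transform is invariant to any positive rescaling of
raw power.  The pooled (rather than per-trial) reference avoids the bias
of dividing by a handful of noisy, heavy-tailed per-trial baseline
samples — a property the test suite demonstrates on lognormal power.  The
"z-score" reading (subtract pooled mean, divide pooled SD) is implemented
as the literal interpretation; where only mean-division is wanted the raw
power and pooled statistics are all accessible.

## Time-resolved RSA

Per timepoint, condition-mean topographies over the 60 scalp channels are
compared with Mahalanobis distances.  The whitening covariance is estimated
once per participant from trial-level residuals (trial minus its cell mean)
pooled over all timepoints, with Ledoit-Wolf shrinkage toward a scaled
identity (analytic intensity; a fixed intensity or an explicit covariance
can be supplied, and a singular unshrunk covariance is an error that
advises shrinkage).  Distances are not cross-validated; under noise they
carry a positive floor, which inflates all RDM entries roughly equally and
leaves the regression structure informative (a crossnobis option is a
natural extension, not implemented).

The 28-entry upper triangles of the neural and the three binary model RDMs
are z-scored and the neural vector is regressed on all model vectors
jointly with an intercept (≈0 after z-scoring).  **Note**: the z-scored
upper-triangle vectors of the binary factor models are *not* orthogonal —
each pair correlates at exactly −1/6 in the full design and −1/2 in the
2 × 2 split design (orthogonality would hold only for full-matrix
vectorization including the diagonal and both triangles).  The joint
regression is unaffected: the vectors are linearly independent, so
coefficients are exactly identified, and a neural RDM equal to one model
recovers (1, 0, 0).

Group inference: per predictor, the participants' coefficient series enter
a one-sample cluster test — t statistic per timepoint, two-sided
cluster-forming threshold at p < .05 (exposed), clusters as maximal
contiguous same-sign supra-threshold runs with mass = summed t, null from
1000 random coherent participant-wise sign flips of the whole series,
cluster p = (1 + #{null max-mass ≥ observed})/(1 + n_perm).  The
implementation is cross-checked in the tests against MNE-Python's
`permutation_cluster_1samp_test` (identical cluster extents, p-values
agreeing to Monte-Carlo precision) and calibrated under a 200-replicate
null simulation (familywise error ≤ 0.075 at nominal .05).

Conditioning on reward time gives 4 × 4 RDMs (6-entry upper triangle) with
beneficiary and magnitude as the two model predictors.

## Mixed models and contrasts

Fixed effects: the seven coded terms plus intercept.  Random effects start
maximal (by-participant intercept + three first-level slopes, fully
correlated).  If the fit fails to converge or the random-effect covariance
is numerically singular, the structure is simplified deterministically:
first the correlations are dropped (diagonal covariance), then the slope
with the smallest estimated variance, repeating until convergence; the
trail is recorded on the result so any fit can be audited.  Estimation is
REML via statsmodels' MixedLM.

Fixed-effect p-values use the normal approximation to t = β/SE; an
optional reference df switches to a t distribution.  Mixed-model df
methods differ across software, so p-values near thresholds are
approximation-dependent — the βs and SEs are the stable quantities.

EMM-style contrasts are linear combinations of the fixed effects under the
±0.5 coding (e.g. the simple magnitude effect within a beneficiary × time
cell is β_M + B·β_BM + T·β_MT + B·T·β_BMT with B, T the cell's codes),
with covariance-propagated SEs; Benjamini–Hochberg FDR is applied within
each declared contrast family (one family per measure).  The ratings get a
classical 2×2×2 within-participant ANOVA: each term's F is the squared
paired-t of the participant-level contrast (identical to the
sums-of-squares decomposition for 1-df terms), df (1, n−1),
η²p = F/(F + df₂); a zero-variance nonzero contrast is reported as F = ∞
with a degeneracy flag.

Self–other correlations of the magnitude effect (large − small per
beneficiary × time cell, per participant) are Pearson correlations across
participants, computed separately for immediate and delayed rewards, with
one FDR family spanning all measures and both time levels.  The two
correlations are compared with z = (z₁ − z₂)/√(2/(n − 3)) on
Fisher-transformed values — a two-independent-samples approximation that
ignores the dependence between correlations computed on the same
participants; it is mildly conservative when the correlations are
positively dependent, and the exact test behind published z values of this
kind is rarely stated.

## Problem sizes and budgets

Tests and the acceptance script size their simulations to what the
properties need: tiny cohorts for exactness checks, 20 participants × 200
replicates × 1000 permutations for the cluster-calibration property,
24 participants × 128 trials for the split-design RSA recovery, and the
full 40 × 320 design at 250 Hz for the acceptance run (sampling rate is a
parameter everywhere; 250 Hz halves cost with no effect on any windowed
measure).  The acceptance run computes single-trial TFR on the two scoring
ROI channels (FCz, CPz) — the RSA uses broadband topographies, not TFR, so
the full trial × channel × frequency × time array over 62 channels is
never needed.

## Known limitations

* No ICA/ocular pipeline: the generator emits no ocular components, and
  real data would need artifact correction upstream of this package.
* Mahalanobis distances are not cross-validated (positively biased under
  noise); between-condition *differences* of bias largely cancel in the
  model regression but are not exactly zero.
* Satterthwaite/Kenward-Roger df are not implemented; p-values are
  normal-approximation based.
* Epoch-wise 0.1 Hz high-pass filtering is a compromise (see above).
* The drift rule's slope unit (per epoch) is one of two defensible
  readings; both the unit and threshold are parameters.
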