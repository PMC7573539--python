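# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `deltareach`. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic experiment

One generated "subject" is a continuous session of center-out trials.
Trial timeline (seconds from trial start): condition cue at 2.0, direction
cue at 2.5, cursor movement onset ~ Normal(3.23, 0.18) truncated to
[2.7, 4.0], movement duration ~ Normal(0.49, 0.13) truncated to
[0.2, 1.0]. 360 trials split evenly over 2 conditions (execution `exe`,
observation `obs`) x 4 directions; when the trial count is not divisible
by 8 the remainder is distributed one trial at a time over the cells in
fixed (condition, direction) order. Signals are emitted directly at
200 Hz (EEG/EOG) and 60 Hz (cursor); the acquisition-rate detail of
recording faster and resampling down is irrelevant to analysis
correctness.

### Forward model

A homogeneous conducting sphere (radius 9.5 cm, conductivity 0.33 S/m)
replaces a boundary-element head model. The dipole potential is the
moment-gradient of the internal monopole Green's function of the
insulated sphere, evaluated as a Legendre series truncated at order 80
(geometric convergence for the 0.72 R source shell; the unit tests check
it against an independent scipy-special-function evaluation at order
600). Electrodes sit quasi-uniformly on the upper scalp cap with a small
seeded placement jitter; 200 source voxels (3 orientations each) sit on
an upper-hemisphere shell. Voxels are labeled by anatomical sector into
8 regions of interest — parieto-occipital cortex (PO), superior parietal
lobule (SPL), premotor cortex (PM), primary sensorimotor cortex (SM1),
left/right — each receiving at least 5 voxels at the default resolution.
The voxel grid is identical across subjects (only electrode jitter
varies), which is what licenses signed cross-subject averaging in source
space, mirroring template-anatomy group analyses.

### Source activity

* **MRCP**: Gaussian-rise (sigma 0.12 s) / exponential-decay (tau
  0.25 s) negativity in the SM1-L voxels (inward radial dipoles), peaking
  100 ms before the cursor movement onset. Amplitudes are calibrated in
  channel space: the most negative medial-central channel of the clean
  projection reaches −2.3 uV in `exe` and −0.7 uV in `obs` (the
  `obs`/`exe` ratio ~0.3). Trial-to-trial gain jitter (SD 0.15) is stored
  in the trial table so single-trial simulation stays deterministic. The
  rise/decay constants were chosen so the waveform is a steep ~0.4 s
  deflection, as MRCPs are; a much slower template would be largely
  removed by the 0.4 Hz high-pass of the preprocessing chain.
* **VEPs**: Gaussian bumps (sigma 0.08 s, 120 ms latency) in occipital
  voxels after both cues, identical across conditions and directions.
* **Direction tuning**: each PO voxel holds a preferred direction
  (golden-ratio spread over the circle); its response to a trial is the
  cosine of the angle between trial and preferred direction, a Gaussian
  bump 350 ms after the direction cue (sigma 0.08 s), calibrated to a
  0.5 uV maximal channel deflection. Opposite directions flip the tuned
  component exactly; the minimal model that yields linearly decodable
  horizontal/vertical factors.

All templates keep >= 95% of their energy below 3 Hz (asserted by
periodogram) so delta-band filtering preserves them.

### Noise and artifacts

Background EEG is 1/f-amplitude ("pink") noise from 24 random dipoles
mixed through the leadfield (spatially correlated, brain-like), scaled
to 4 uV RMS per channel, plus 0.8 uV white sensor noise. Eye artifacts
derive from three sources — horizontal gaze (35 uV per target
distance), vertical gaze (25 uV), blinks (120 uV raised-cosine pulses) —
mixed into six EOG channels with fixed polarities (a rightward saccade
makes the right-minus-left canthus derivative positive) and into the EEG
through a fixed, frontally dominant topography (exponential fall-off
from the front, antisymmetric across the midline for the horizontal
source). Gaze follows the cued target with a 190 ms catch-up saccade
(2.69 s trial time). EOG sensor noise is band-limited (~8 Hz), as
periocular noise is. The calibration recording contains 40 s rest, 16
scripted blinks and 15 scripted saccades, emulating the dedicated
calibration blocks of such experiments. Cursor traces are minimum-jerk
rises 0 → 1 with a constant per-trial resting offset and smooth jitter
(SD 0.008).

The generator exports `clean`, `noise` and `contamination` components on
request; their sum reproduces the emitted EEG exactly, and all
randomness derives from one integer seed (byte-identical regeneration is
asserted).

Synthetic data deliberately omit non-stationarity, inter-subject
anatomical variability, imperfect leadfields, muscle/movement artifacts
and saccadic spike potentials. Passing tests therefore demonstrate
pipeline correctness, not real-data effect sizes; single-trial decoding
accuracies on the synthetic cohort are markedly higher than published
EEG values, and the inverse-crime validation (same leadfield for
simulation and imaging) is confined to tests by design — a
mismatched-leadfield robustness mode is available by adding gain noise.

## Preprocessing chain

Fixed order, asserted at run time: zero-phase 4th-order Butterworth
high-pass at 0.4 Hz + 50 Hz notch → spherical-spline interpolation of
flagged channels (Perrin-style, stiffness 4, 50 Legendre terms) → eye
artifact subtraction → common average reference → HEAR → zero-phase
3 Hz low-pass → polyphase resampling to 10 Hz. Event times are stored in
seconds and survive resampling unchanged. The notch frequency (50 Hz)
is a European-mains choice; it is a parameter.

Eye correction is least-squares regression on four regressors derived
from the EOG channels: the horizontal derivative (right minus left outer
canthus), the two vertical derivatives (superior minus inferior per
eye), and the time course of the first principal component of the EOG
channels during scripted calibration blinks (sign fixed positive on the
superior electrodes). The model is always fitted on calibration data
and never on the task recording; EOG channels themselves are passed
through untouched for the behavioral analysis. With noisy EOG sensors
the regression exhibits the usual errors-in-variables attenuation, which
bounds how completely contamination can be removed — the tests that
check near-exact removal therefore use noise-free EOG.

HEAR (high-variance electrode artifact removal) compares each channel's
sliding-window variance (0.25 s) with its calibration variance and maps
the ratio to an artifact probability through a linear ramp p =
clip((ratio − 1)/(r_sat − 1), 0, 1) with r_sat = 5, so a tripled
variance gives p = 0.5; the output is the p-weighted mix of the channel
with the mean of its Delaunay neighbors. The ramp is the simplest
monotone, saturating map consistent with treating a tripled variance as
"probably artifactual". HEAR presumes ongoing activity dominates the
calibration variance; on near-noiseless synthetic data it would treat
the signal itself as an artifact, which is why chain-level tests run at
a realistic noise floor.

## Behavioral analysis

The cursor onset detector subtracts the baseline (mean over the last 1 s
of the preparation period), smooths with a zero-phase triangular FIR
(63 taps at the 200 Hz reference rate, i.e. a fixed 0.315 s duration at
any sampling rate), finds the first crossing of 0.05 normalized
distance, computes finite-difference derivatives over the preceding
1.75 s window, takes the earliest maximal-derivative point and intersects
its tangent with the zero line. Detection operates on the smoothed trace
throughout: taking the initial crossing on the raw trace would place the
tangent point inside the smoothing transition band and bias onsets late
(about +28 ms on noiseless minimum-jerk traces, versus ~no bias for the
smoothed-crossing variant; both measured before the test expectations
were frozen). The movement offset is the first time the distance to the
target drops below 0.1; trials whose onset-from-trial-start or duration
exceeds 2.5 robust standard deviations (median / 1.4826 x MAD; a zero
MAD flags every deviating trial) are marked outliers.

Eye movement onsets come from direction-averaged EOG derivatives:
first time after the 1–1.5 s baseline window at which the
direction-associated derivative exceeds baseline mean + 3 SD *and stays
above threshold for 50 ms*. The sustained-crossing requirement is a
robustness addition: a bare first-crossing rule false-triggers on
band-limited noise excursions in the ~1.2 s search window, something
visual inspection would catch in a manual analysis. Group behavioral
effects use a two-way repeated-measures ANOVA (statsmodels `AnovaRM`
behind the module surface, verified against hand-computed sums of
squares) with uncorrected degrees of freedom, plus Bonferroni-corrected
post-hoc paired t-tests.

## Epoching and artifact rejection

Epochs are cut with a half-open [a, b) convention (40 samples for
[0.75, 4.75) s at 10 Hz; 32 for [−2, 1.25)) under two alignments: trial
start and detected cursor movement onset. Rejection runs on broadband
epochs: (1) any sample beyond ±200 uV; (2–4) per-channel joint
probability (mean log-density under a Gaussian fitted to the channel's
pooled distribution — a deterministic stand-in for kernel density
variants), kurtosis and variance, each converted to robust z-scores
across trials (median/1.4826·MAD, the same robust convention as the
behavioral outlier rule) and thresholded at 6/6/5, maximized over
channels. The statistical criteria run twice, recomputing all statistics
after first-pass removal so subtle outliers masked by gross ones (e.g.
through an inflated pooled density fit) surface in the second pass. The
union of all masks is applied to the delta-band epochs; fewer than 5
survivors is an error.

## Encoding model

Factors are coded exe/obs = ±1, right/left = ±1 (horizontal),
up/down = ±1 (vertical), cells subsampled without replacement to the
minimum cell count (seeded), then z-scored with population SD so the
factor rows have exactly unit variance and zero mean. Consequences kept
under test: horizontal and vertical rows stay orthogonal, and the
intercept column of the coefficient matrix equals the across-trial mean
of the data *exactly*, because z-scoring makes the factor block of C_SS
orthogonal to the intercept and the scaled-identity shrinkage target
preserves that block structure.

C_SS uses Ledoit–Wolf analytic shrinkage toward (trace/p)·I (the
simplest admissible target; verified against an independently coded
textbook implementation and sklearn's `LedoitWolf`). The shrinkage
intensity can be overridden (0 recovers ordinary least squares; the
exact-recovery tests use that). Residual diagnostics are emitted as
per-channel skewness/excess-kurtosis summaries rather than plots, so
they are testable. A caveat recorded by the tests: with n = 2 centered
samples the Ledoit–Wolf dispersion estimate is degenerately zero (the
centered data are rank 1), so heavy shrinkage at extreme undersampling
is only guaranteed on the uncentered path the classifier actually uses.

## Source imaging

The sensor-noise covariance comes from the rest segment of the
preprocessed calibration recording, diagonally loaded with 10% of its
average eigenvalue. The inverse kernel is K = Gᵀ(GGᵀ + λC)⁻¹ with
λ scaled by trace(GGᵀ)/trace(C) (default 0.05), standardized per voxel
by the inverse matrix square root of the 3x3 resolution blocks (KG)_vv —
the sLORETA standardization, which the tests verify has zero
localization error for noiseless point sources by brute-force scan.
Eigenvalues of the resolution blocks are floored at 1e-12 of their
maximum before inversion.

The per-subject GFP constant is the median over repetitions (default
10,000; desk-scale runs use fewer) of the across-voxel SD of voxel
norms after averaging one random sample per trial; the same constant
normalizes activity and coefficient maps. Direction maps sum the
horizontal- and vertical-factor voxel norms. Group averages take the
signed coefficient average across subjects before norm extraction (noise
cancels); the condition contrast of direction encoding instead extracts
each subject's voxel norms first (so dipole orientations may differ
across subjects) and feeds ROI means into two-sided paired permutation
t-tests — 8 ROIs x 2 alignments = 16 tests.

## Decoding

`ShrinkageLda` is a scikit-learn-style classifier: pooled within-class
covariance with analytic shrinkage toward scaled identity, one linear
score per class with uniform priors, arg-max decision (multi-class is
the standard shared-covariance construction; shrinkage 1 reduces to
nearest class mean, shrinkage guarantees invertibility under duplicated
features). Leave-one-trial-out cross-validation fits N models per
time-point; windowed features concatenate the current and 5 preceding
time-points. Chance levels use 1000 label shuffles (95th percentile) of
the full cross-validation on a predeclared reference time-point; the
pipeline records them per subject. Peak search is restricted to the
cue-to-movement-offset interval, with the offset taken from the cohort's
detected behavioral means. Leave-one-out chance estimates on finite
samples scatter around 50% with an SD of a few percentage points per
seed, which is why chance-level checks average over many seeds.

## Permutation statistics

Sign-flip tests build the group null by flipping each subject's effect
before averaging and norm extraction; paired t-tests sign-flip the
paired differences. When 2^n_subjects fits inside the permutation
budget the null is enumerated exhaustively (unsmoothed p, minimum
1/2^n); otherwise p = (1 + #{null >= observed}) / (1 + n_perm), which
avoids p = 0 at a cost of at most 1/n_perm. Zero-variance differences
return p = 1 with a degeneracy flag. BH-FDR runs over one pooled family
of all group-level p-values per run (the family composition is logged);
with few subjects the sign-flip floor 1/2^n can exceed any BH threshold,
so desk-scale runs may legitimately report zero significant voxels.

## Pipeline scale

Defaults mirror the emulated study (15 subjects, 360 trials, 10,000
permutations/GFP repetitions, 1000 shuffles). `PipelineConfig.desk()`
is the configuration the test suite exercises end to end — 4–5 subjects,
80–120 trials, 96–120 voxels, hundreds of permutations — chosen so a
full cohort run completes in minutes on one CPU while every qualitative
contrast (PO direction peak after the cue, SM1 condition peak at
movement onset, cue-aligned > movement-aligned direction decoding)
remains stable under the fixed seeds. Within-subject stages can be
cached to disk; identical configuration and seeds give byte-identical
reports.
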