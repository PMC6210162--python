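# Methods

This note documents the models, numerical choices and known limitations of
`updrskit`, stage by stage.  Notation: FT/OC/PS are the three upper-limb
UPDRS tasks; a "cycle" is one full movement (closure → opening → closure);
CV denotes a coefficient of variation σ/μ (sample standard deviation).

## Synthetic motion model

The scalar task profile is a raised cosine per cycle,

    s(t) = b + A_i (1 − cos 2π τ/T_i) / 2,   τ ∈ [0, T_i),

with baseline aperture `b` (the aperture at full closure; marker centres
never coincide on a real hand; 0 by default so the degenerate checks stay
exact), per-cycle amplitude `A_i = A0 (1−r)^i (1+ε_i)`, `ε_i ~ N(0, CV_A)`,
decrement rate `r ∈ [0,1)`, and per-cycle period `T_i = T0 (1+η_i)`,
`η_i ~ N(0, CV_T)` (multipliers clipped at 0.05 and 0.2 to keep amplitudes
and periods positive under extreme draws).  Hesitations are flat holds of
fixed duration inserted before a cycle's beat with probability
`p_hes` — at the minima, where clinical halts occur.  Gaussian noise of
configurable SD is added last.  This makes the ground truth closed-form:
per-cycle amplitude `A_i`, duration `h_i + T_i`, and per-phase peak speed
`π A_i / T_i` (the derivative maximum of the raised cosine), which is what
every recovery test compares against.

The 3D embedding maps the profile onto a static hand rig (palm centre at
400 mm depth, five anatomical fingertip offsets): FT moves the index tip
along the fixed thumb→index direction so the thumb–index distance equals
the profile; OC scales the four finger offsets radially so the mean
tip–palm distance equals the profile; PS rotates the whole rig about the
vertical axis through the palm, after zeroing the pinky's rest azimuth so
the rotation profile *is* the pinky azimuth — each mapping is inverted
exactly by the corresponding signal extraction (round-trip error < 1e-6 at
the native sample rate).

Severity presets (packaged YAML, not hard-coded) define per-class uniform
parameter ranges.  The clinical ladder makes amplitude and frequency fall
and variability, decrement and hesitation rate rise monotonically from
class 0 to class 3, with healthy controls drawn like class 0 with tighter
variance — deliberately overlapping, as in a real cohort, where HC and a
PD patient scored 0 are clinically near-indistinguishable.  A second
`separated` variant (FT) pulls the class ranges apart and places HC
distinctly above class 0; it exists to validate the classification chain on
a problem that is separable by construction, not to represent a clinic.
Default conditions: 12–18 cycles per performance, 60 Hz sampling (a
short-range RGB-D camera's rate), 1 mm additive noise (typical colour-
marker tracking error at 400 mm).

What the generator does *not* emulate: tremor (excluded), fatigue-related
waveform shape changes beyond geometric amplitude decay, occlusions,
photorealistic appearance, and inter-rater label noise.  Passing tests
therefore demonstrate that the pipeline recovers what the model encodes;
they do not validate the presets against patients.

## Marker tracking

The tracker consumes RGB + 16-bit depth (mm) frames.  The hand is segmented
as all valid depth pixels within 150 mm of the nearest one (a hand's depth
extent), its centroid re-projected through the pinhole model
(`X = (u−cx)z/fx`, `Y = (cy−v)z/fy` — image origin top-left, v down, world
Y up; stated explicitly because image conventions are a classic source of
sign bugs).  Lighting is classified low/normal/high from the mean V of the
white palm marker (found by a circular Hough transform inside the hand
box) against tertile thresholds of the reference V, and mean-H/S/V ratios
provide colour-constancy scale factors.  Fingertip markers are segmented as
connected components inside per-colour HSV threshold triplets (≥ 10 px);
the shipped triplets suit the synthetic renderer's saturated markers and
are deliberately config-mandatory for real footage, where they must be
calibrated per lighting condition.

Frame-to-frame association uses CamShift — mean-shift of a search window
over the marker's hue-histogram back-projection (hue-only, 32 bins,
saturation/value floors to suppress the dark glove), window side adapted as
`2√M00`.  The final centroid is taken from the threshold-segmented blob
inside the converged window, which is what the re-projection averages over.
A marker that loses all probability mass is re-seeded from a fresh
whole-frame segmentation (nearest blob to its last position, which also
breaks ties between same-colour blobs); if that fails the frame is recorded
as a gap — positions are never fabricated.  The pipeline is deterministic.

On rendered sequences the full render → track → re-project loop recovers
fingertip positions to ≈ 0.5 mm at 400 mm depth (sub-pixel blob centroids
plus exact depth), against a 2 mm contract.

## Tracker accuracy metrics

Two trajectories resampled to a common uniform grid (cubic spline, 100 Hz
default, no extrapolation) are compared through the per-sample residuals
`r_i = y_i − x_i` after mapping the test device into the reference frame
with a Kabsch least-squares rigid transform (SVD with reflection guard;
configurations whose centred covariance has rank < 2 are rejected as
collinear).  The mean residual vector d̄ is subtracted before taking
`d_i = ‖r_i − d̄‖` — subtraction of the *vector*, not the scalar mean
distance, because a constant inter-device translation is a calibration
artefact; a scalar mode is available behind a flag for comparison.
Reported statistics: `D_MEAN`, `SD` (population convention, configurable
`ddof`), `MAD = max d_i`.  Masking keeps a sample when the *reference*
position lies inside the working volume (box or truncated frustum); the
devices are assumed clock-synchronized in this artifact's scope.
Set-level aggregation averages `D_MEAN` and `SD` over trajectories and
takes the maximum `MAD`.  The implementation is checked against an
independent per-sample brute-force loop to 1e-12 on random pairs.

## Kinematics

Task signals: FT `‖index − thumb‖`; OC mean fingertip-to-palm distance over
the four fingers (an index-height mode is provided, since the clinical
aperture definition is not standardized); PS the unwrapped
`atan2(x, z)` azimuth of the pinky−palm vector in the horizontal plane,
degrees.  Fingers are spline-resampled onto a shared 100 Hz grid; a finger
with more than 20% of its span lost to tracking gaps is rejected rather
than silently interpolated.

Cycle segmentation smooths the signal with a Savitzky–Golay filter
(polynomial order 3, window ≈ one quarter of the movement period as
estimated from the principal frequency, minimum 5 samples) and detects
extrema with prominence ≥ 20% of the interquartile range; a cycle runs
minimum → maximum → minimum, the opening (supination) phase being the
rising half.  Per-phase peak speeds are maxima of |ds/dt| computed by
central differences on the smoothed signal and then smoothed once more with
a 0.7-window Savitzky–Golay pass: the maximum of a noisy derivative is
upward-biased, and the second pass cancels that bias against the slight
peak attenuation — at the default conditions (60 mm, 3 Hz, 1 mm noise,
100 Hz grid) recovered peak speeds stay within ±2.7% of the analytic
`A π f` across 100 seeds.  Amplitude is `s(peak) − (s(start)+s(end))/2`;
maximum opening is `s(peak)` (the two differ by the baseline, which is why
both MO and MA exist).

The principal frequency is the dominant periodogram peak of the detrended
signal in 0.25–8 Hz, zero-padded to ≤ 0.05 Hz bin spacing.  The peak is
accepted only when it rises ≥ 50× above the median band power: quasi-
periodic movement concentrates orders of magnitude more power at its rate
than any noise bin (observed ≥ 115×), while pure noise stays below ~20×.
A spectral-concentration rule was rejected because zero-padding correlates
neighbouring bins and inflates the concentration of pure noise.

Feature vectors per task follow the clinical naming (means and CVs of
maximum opening, amplitude/rotation, per-phase peak speeds, durations, plus
`Freq` for FT and PS).  CVs use the sample standard deviation (n−1);
speeds are derivatives of the scalar task signal (mm/s or deg/s), not 3D
fingertip speeds, so each phase's speed is attributable to that phase.
Amplitude decrement is expressed only through the amplitude mean and CV; no
separate slope feature is added.

## Feature selection

Eq.-style HC normalization divides every parameter by its healthy-control
mean, applied literally even where lower values are worse; the
"worse-is-larger" orientation needed for radar-style reporting is obtained
afterwards by reciprocating only the mean-type parameters and `Freq`
(`orient_worse_is_larger`), and is never fed to the models — the Spearman
filter and the classifiers are invariant or insensitive to such monotone
reorientations, and keeping the model input transform-free avoids silently
changing the regression geometry.

The elastic net minimizes
`1/(2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)` on standardized columns,
α = 0.5 by default (the grouping end matters because kinematic parameters
are mutually correlated by construction).  The λ path is scored by 10-fold
CV and chosen by the one-standard-error rule; the ridge end (α = 0) uses
the closed form `(XᵀX/n + λI)⁻¹Xᵀy/n` directly rather than coordinate
descent.  The Spearman filter keeps parameters with |ρ| > 0.3 at p < 0.01
(t approximation; a vectorized permutation p-value below 20 rows),
intersected with the elastic-net subset; selection runs on the normalized
parameters.  The PCA check reports how many components reach 98% cumulative
variance and whether their top-loading parameters overlap the elastic-net
choice.  Pruning of mutually correlated *selected* parameters is
deliberately out of scope.

## Assessment

Classifiers: polynomial-kernel SVM (primary), Gaussian NB, LDA, multinomial
logistic regression, KNN — all behind a standardization pipeline whose
statistics, like the SVM grid search, are refit inside every training fold
(nested, to avoid optimistic bias).  The default SVM grid is
C ∈ {0.1, 1, 10, 100} × degree ∈ {2, 3} with coef0 = 1 and gamma = 'scale';
the full grid sweeping kernel scale and offset is available as
`FULL_SVM_GRID` for final models, where the extra nested-search cost is
justified.  Both problem framings are supported: binary HC-vs-PD and
five-class (HC as a class of its own ahead of UPDRS 0–3; with synthetic
cohorts the two are genuinely distinct generative classes, which sidesteps
the clinical ambiguity of separating a healthy control from a patient
scored 0).  Evaluation: LOOCV, or repeated stratified 10-fold with
per-repeat reshuffling (500 repeats by default to match the evaluation
protocol the defaults mirror; tests and the acceptance script pass fewer).
Reported: pooled confusion matrix, per-class (macro) accuracy — equal to
overall accuracy exactly when classes are balanced — and the absolute class
error `e_c = |C − C′|` with its mean and maximum.

## Problem sizes used in tests and the acceptance script

Metric oracle: 100 random pairs up to 10⁴ samples.  Kinematic recovery:
one 20-cycle performance plus 100 seeds × 50 cycles for the CV recovery.
Monotonicity: 50 cohorts × 3 tasks × 4 recordings per class.  Selection:
100 runs at n = 200 with 2 informative + 8 noise parameters.  Classifier:
30 recordings per class (150 total), LOOCV, plus a label-permuted control.
Tracking round trip: 10 s of tapping rendered at 30 Hz, 320×240, palm at
400 mm; rhythm variability 0.10 so the duration-CV comparison is not
dominated by single-sample cycle-boundary quantization.  These sizes keep
the whole suite at a few minutes on one CPU while leaving every estimate's
sampling error well inside its tolerance.

## Known limitations

- Preset realism is unvalidated by construction: no public parameterization
  of PD tapping waveforms exists at this granularity, so the severity axes
  are calibrated to clinical descriptions, not measurements.
- The tracker's HSV triplets and CamShift back-projection are tuned for
  rendered scenes; real footage requires per-deployment calibration and may
  break the hue-only assumption under coloured lighting.
- PS rotation is measured from the pinky-projection azimuth, not a fitted
  hand-plane orientation; the two differ under out-of-plane wobble.
- Cross-device temporal alignment assumes a shared clock; the optional
  cross-correlation lag search (± 200 ms, `estimate_time_lag`) is off the
  default comparison path and has been exercised only on synthetic shifts,
  not real co-captures.
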