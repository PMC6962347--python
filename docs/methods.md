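# Methods

This note documents the models, numerical choices and known limitations
of the `plaqueswe` analysis chain. All quantities are SI unless stated;
axis order is (depth, lateral, slow-time) throughout; the velocity sign
convention is positive toward the transducer.

## Synthetic wave fields

The generator emulates a dual-sided acoustic-radiation-force SWE
acquisition: two push beams fire simultaneously on the left and right
flanks of the plaque ROI, launching counter-propagating dispersive
packets. Synthesis is exact in the frequency domain — the source
spectrum `S(f)` is propagated with phase `exp(∓ 2πi (f / c_p(f)) (x −
x_push))`, so the component at frequency `f` travels at exactly the
phase velocity prescribed by the configured dispersion law. This makes
the simulator a ground-truth oracle for both analysis branches: the f–k
ridge lies exactly on `k(f) = f / c_p(f)`, and with a constant law the
envelope translates rigidly at `c0`.

Defaults mirror a clinical carotid protocol: 0.3 mm pixel pitch in both
axes, an 18 ms record, 5 MHz tracking frequency, 400 µs push duration
(applied as a sinc low-pass on the source spectrum). The slow-time
sampling rate is not something a recorded ultrasound image series
reveals unambiguously; 10 kHz (0.1 ms frame interval, 180 frames) is
used as a typical ultrafast tracking rate consistent with the push and
record lengths. The stated "≈0.30 mm²" acquisition resolution is read
as 0.30 mm pixel pitch in each axis; the alternative reading (0.30 mm²
pixel area, ≈0.55 mm pitch) would halve the wavenumber Nyquist but not
change any algorithm.

The source is a Gaussian-windowed tone burst, centre 400 Hz, −6 dB full
bandwidth 500 Hz, so all three analysis bands (200–500 Hz) contain
energy. The field is uniform over depth: depth structure in real data
is the ROI's job, not the wave model's, and a depth-uniform field makes
the depth-averaging stage exactly invertible in tests. Additive white
Gaussian noise is scaled to the clean field's RMS (`snr_db`, default
20 dB — a representative in-vivo value; pass `None` for the noise-free
oracles). Packet speeds below ≈2.8 m/s do not fully cross the default
38 mm aperture inside the 18 ms record; the pipeline's cohort simulation
clips drawn speeds to [2.8, 9.5] m/s for this reason.

What the generator does **not** model: speckle decorrelation, tissue
clutter and motion other than the shear wave, push-beam geometry and
near-field effects, mode conversion at plaque boundaries, attenuation,
and out-of-plane propagation. Passing tests therefore demonstrate
correctness of the estimators under their stated wave model, not
robustness to every in-vivo artefact.

### IQ encoding

`modulate_to_iq` writes the velocity movie into a synthetic speckle
ensemble: per-pixel Rayleigh amplitudes of unit mean with uniform
phases, constant over slow time, whose phase advances by
`4π f0 v Δt / c` per frame. Velocities at or beyond the aliasing limit
`c / (4 f0 Δt)` (0.77 m/s at the defaults) raise an error naming the
limit — tissue particle velocities in SWE are O(1 cm/s), far below it.

## Motion estimation

The 2-D autocorrelation estimator averages the lag-one slow-time
autocorrelation `R1` over a small kernel and converts its angle to
velocity, `v = c·angle(R1)/(4π f0 Δt)`. Averaging the complex `R1`
weights brighter speckle more, which is what stabilises the phase
estimate in noise.

The default kernel is 5 (depth) × 1 (lateral) × 1 (slow-time pairs).
Depth-only averaging preserves the lateral resolution the TTP fit
needs. No slow-time smoothing is applied by default because each
lag-one pair is already a two-frame estimate and any longer window
low-passes the movie: a centred 2-pair window attenuates content by
`0.5 + 0.5·cos(2π f Δt)`, which at the burst's upper band edge
(~650 Hz) is a 4% amplitude loss and measurably breaks the ≤2%
round-trip contract. When a wider time kernel is requested for noisy
data, even extents use a centred window with half-weight endpoints
(e.g. `[¼, ½, ¼]` for 2 pairs) — a plain even-length moving average
would shift the movie by half a frame. No phase unwrapping is
performed; aliasing is prevented upstream in simulation and must be
handled by the acquisition on real data.

## Directional filtering and depth averaging

Per depth row, the (lateral, time) plane is transformed by 2-D FFT and
split by spectral quadrant: with the FFT basis `exp(+2πi(kx + ft))`, a
wave moving toward +x occupies the quadrants where `k·f < 0`. The
zero-frequency lines (`f = 0` or `k = 0`) carry no direction and are
shared half-and-half so the two outputs sum back to the input. A Tukey
window (α = 0.25) tapers both axes before the transform to control
wrap-around leakage on the short records and is divided out after
inversion; because quadrant masking spreads a little energy into the
tapered margins, the divisor is floored at 0.5 (at most a ×2 boost) —
full inverse-window compensation would amplify edge ringing without
bound. Consequences: reconstruction additivity `L + R = input` is exact
in the window's flat interior (the central 75% of each axis) and exact
everywhere with α = 0; the energy inequality `‖L‖² + ‖R‖² ≤ ‖input‖²`
holds exactly in the windowed domain and is asserted untapered.

Depth averaging is an unweighted mean over masked pixels per lateral
column; columns with no masked pixel are dropped and the lateral axis
keeps only included columns. The ROI's lateral extent must be
contiguous. Filtering is applied to the full field before depth
averaging; for depth-uniform fields the two orders commute (asserted in
tests).

## Group velocity

Time-to-peak takes, per lateral position, the time of the maximum map
value (ties broken toward the earliest sample), optionally inside a
crop window — the reproducible replacement for a visual "does the fit
pertain to the main wave" judgement. The line `t = x/v + b` is fitted
with RANSAC: candidate lines through point pairs, inliers within a
0.5 ms time residual, best candidate by inlier count with ties broken
by smaller inlier RMS, and a final ordinary-least-squares refit on the
winning inlier set. The fit is parameterised as `t(x)` because TTP
noise lives in time; velocity is the reciprocal slope. When the number
of distinct pairs does not exceed the iteration budget (200), all pairs
are enumerated, so on small instances the consensus equals exhaustive
search by construction — randomised sampling only engages on maps with
many lateral positions. The RANSAC seed is recorded in the
configuration, making estimates reproducible.

Quality gating: an estimate passes when the inlier ratio exceeds 0.5
and the fitted velocity is finite and positive. A second flag
(`spans_roi`) records whether the inlier span covers at least half the
lateral extent. Leftward maps are mirrored before fitting so both
directions yield positive speeds; the per-acquisition value is the mean
of the passing directional estimates, and an acquisition with no
passing direction is excluded with a logged reason.

## Phase velocity

The dispersion map is the magnitude of the 2-D FFT of the mean-removed,
Tukey-windowed space–time map, zero-padded ×4 per axis (18 ms records
give ≈56 Hz native bins, too coarse for 100 Hz bands; padding
interpolates the spectrum without inventing information). Only `f ≥ 0`
is kept; the wavenumber axis is signed, in cycles per metre, oriented
so `k > 0` means propagation toward +x. Per frequency bin the search is
restricted to wavenumbers of the map's propagation sign with implied
speed `f/|k|` in [0.5, 15] m/s (bracketing all plausible plaque
velocities); the peak wavenumber is refined by 3-point parabolic
interpolation and the phase velocity is `f/|k*|`.

Quality gating replaces the visual discard of noisy or
higher-order-mode-contaminated spectra with two reproducible rules: a
bin is valid when its peak magnitude is at least 3× the mean magnitude
over the search range (peak prominence), and an optional frequency crop
marks bins outside the fundamental-mode interval invalid regardless of
prominence. Band means over [200, 300), [300, 400) and [400, 500] Hz
(half-open except the last) are defined only when at least half of a
band's bins are valid; an undefined band is an expected outcome, not an
error. Prominence threshold, valid fraction, search range and crop are
all configuration-exposed.

## Cohort simulation

The generator reproduces the study conditions of a 27-plaque carotid
cohort: 7/8/8/4 plaques of modified AHA types III/V/VI/VII carried by
~20 subjects, per-group velocity means and SDs for group velocity and
the three phase-velocity bands in both imaging views (the built-in
defaults place type VI well above the other groups, e.g. transverse
group velocity 7.3 ± 2.5 m/s against 3.1–3.6 m/s), 5–15 acquisitions
per plaque and view, and a per-acquisition scatter of 1.5 m/s — the
middle of the 1–2 m/s single-plaque spread typical of such data. Per
plaque, the true velocity is drawn from its group's normal (floored at
0.2 m/s), acquisitions add independent Gaussian noise, and the plaque
record keeps mean, sample SD (n−1; zero for a single acquisition) and
count.

Component covariates use the standard bivariate-normal device: the
component z-score is `R·ẑ + sqrt(1−R²)·ε` against the empirically
standardised realized per-plaque metric mean, hitting the target
Pearson R in expectation. Because the metric margin is standardised
within each cohort, the sample correlation follows the fixed-margin
(regression noncentral-t) distribution rather than the unconditional
bivariate-normal one — slightly tighter, with a flag rate at target
R = 0.6, n = 27 of ≈0.83 rather than the naive Fisher-z 0.76; the
acceptance checks use the conditional prediction. Component scales
(LRNC percent and volume, cap volume and thickness, IPH, calcification,
loose matrix, cap/core ratio) are plausible plaque values with mild
clipping to physical ranges; lipid panels are subject-level, so
subjects contributing two plaques share one draw. Missing values
(components that could not be delineated) are inserted independently at
a configurable rate (default 0.1).

## Statistical evaluation

Per metric (group velocity and the three bands) and view (longitudinal,
transverse), type VI is tested against each other AHA type with a
two-sided Wilcoxon rank-sum test; a metric "differentiates type VI from
all others" when every pairwise p < 0.05 (strict flag at 0.01). P-values
are exact by full enumeration whenever the combined sample size is at
most 12 without ties — which covers the 4–8-plaque groups here and makes
exactness testable against a brute-force oracle — and otherwise use the
normal approximation with tie and continuity corrections; the two
branches agree within 0.02 where both apply.

Correlation screens use pairwise-complete observations (a plaque
missing the covariate is excluded from that analysis only); Pearson
p-values come from the t-distribution with n−2 df and Spearman from the
same t-approximation on the rank correlation with average ranks for
ties. Fewer than three complete pairs make a result undefined and never
flagged. No multiple-testing correction is applied anywhere — matching
the evaluation this chain mirrors — and the report instead records the
number of tests performed.

## Pipeline and reproducibility

One YAML config with a single global seed drives a run; per-stage seeds
derive deterministically, and the manifest (config snapshot, version,
output digests, machine-readable exclusion reasons) reconciles
exclusion counts against output row counts per metric — re-running a
manifest's config reproduces byte-identical outputs. The bundled demo
scale (4 plaques × 3 acquisitions × 2 views on the default grid) keeps
a full run in seconds; statistical calibration checks use 500 null and
200 structured cohort replicates, sizes at which binomial tolerances
are decisive while the suite stays fast.

## Known limitations

* The wave model is 1-D-in-space per direction and depth-uniform; no
  waveguide mode structure beyond the prescribed dispersion law, no
  higher-order modes, so the mode-crop machinery is exercised only via
  its contract, not against genuinely multimodal data.
* The quality thresholds (prominence 3.0, valid fraction 0.5, inlier
  gate 0.5) operationalise visual judgements; their values are design
  choices validated on synthetic data only.
* Lipid correlations treat plaques from the same subject as independent
  observations; within-subject dependence is not modelled.
* Real-system ingestion is limited to the documented HDF5 contract;
  vendor formats need an external converter.
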