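# Methods

This note documents the models implemented in `myowave`, the defaults that
matter, what the synthetic data emulate (and what they do not), and the
design choices made where the problem was genuinely open.

## Measurement model

The measurand is the transverse (deep–superficial) displacement of muscle
aponeuroses relative to a skin-mounted ultrasound probe during the stance
phase of gait. A landmark at image row `y` maps to displacement
`d = −(y − y_standing) · mm_per_px_y`: rows grow with depth, so positive
displacement is motion toward the skin. The quiet-standing reference is
subtracted exactly once, in `spectra.transverse_displacement`.

Geometry: frames are 608 × 512 px for a 60 × 50 mm field of view
(`mm_per_px_x ≈ 0.0987`, `mm_per_px_y ≈ 0.0977`). The true pixel dimensions
of the clinical hardware are not public; 608 × 512 is an assumption recorded
in the configuration, chosen so that 19 landmarks at 32 px spacing span the
image width with a 16 px margin on each side (`x_j = 16 + 32j`).

## Active shape model

**Point distribution model.** Training shapes are stacked as 38-vectors
(x then y) and the covariance eigendecomposed; the smallest set of modes
whose cumulative variance reaches `variance_fraction` (default 0.98) is
retained. *No Procrustes alignment is applied*: absolute position in the
image frame is the quantity analysed downstream, so translation must remain
inside the shape space rather than being factored out as pose. Identical
training shapes give a valid zero-mode model.

**Intensity models.** At each pyramid level (smooth σ=1, downsample ×2) and
landmark, the intensity profile is sampled along the local boundary normal
(perpendicular to the chord joining the neighbouring landmarks; one-sided at
the ends), differentiated by central differences, and normalised by the sum
of absolute values (a zero profile stays zero — no division by zero). Mean
and covariance accumulate over labelled frames; the covariance is
regularised by `ε = 1e-6 × mean(diagonal)` before inversion. Profiles
reaching outside the image are clamped to the edge and the landmark flagged
in the model metadata.

**Search.** Candidates at ±`search_range` (default 4) unit steps along the
normal are scored by Mahalanobis distance to the landmark's profile model;
ties break toward the smallest displacement (stability). The updated points
are projected onto the PDM, each coefficient clamped to ±3√λᵢ, and the
x-coordinates re-pinned to the standard columns. A level converges when
fewer than 10 % of landmarks move more than 1 px; `max_iter` is 20.
Sequence-initial frames are searched over five pyramid levels, subsequent
frames (initialised from the previous solution) over three. Defaults
`k = 6` (profile half-length), `search_range = 4`, `max_iter = 20` were
chosen on synthetic fixtures and are exposed as keyword arguments; the
convergence rule, profile length and retained-variance fraction are not
dictated by the underlying method and are engineering choices. Models are
bound to one image source (per-participant training) and record that source
in their metadata.

**Validated accuracy.** On the standard benchmark (100 frames, speckle,
gait + 8 Hz oscillation, amplitudes ≤ 2 mm, labels every 20th frame) the
held-out mean absolute transverse error is ~0.01–0.02 mm, far inside the
~1 mm bound reported for this class of segmentation; the bound, not the
point value, is the acceptance criterion, since error grows with speckle
contrast and oscillation amplitude.

## Impact input frequency

The rate of force development (RFD) is the central-difference derivative of
the vertical GRF. Within the first 25 % of stance (impact transients occur
in early stance; the late-stance push-off peak must not be picked up),
`t_max_rfd` is the RFD maximum and `t_peak` the first local force maximum
after it (falling back to the window's global maximum). The default
convention is `f = 1/(4Δt)` — the interval spans a quarter oscillation of
the impact signal — which yields the physiological 10–20 Hz magnitudes; the
literal reciprocal `1/Δt` is implemented as `direct_inverse` and the two
differ by exactly ×4. Filtering is zero-phase (forward–backward Butterworth,
60 Hz low-pass default) so timing estimates are not lag-shifted. Stance
detection is by threshold crossing (default 20 N; intervals < 100 ms
discarded); how the impact maximum should be identified in walking traces
without a distinct transient is genuinely underdetermined, and the
first-hump peak is used.

Recovery accuracy is limited by sample quantisation: the central difference
at the force onset shifts the RFD argmax by one sample and peak sampling
adds up to one more, so estimates on the 2 kHz grid carry a two-sample
uncertainty in Δt (≈1.3 Hz at 25 Hz, negligible at 5 Hz).

## Displacement spectra

Spectra are computed on native-rate (~80 Hz) stance segments — never on the
100-point resampled traces, which exist only for reporting displacement
curves on a common stance axis. The high-pass cutoff equals the condition's
stride frequency (protocol values 1.3, 1.8, 2.4, 2.6, 2.7, 2.9, 3.1 Hz).
Power is one-sided `P(f) = 2|X(f)|²/N²` on the unwindowed series, truncated
to 0–40 Hz: under this convention a unit-amplitude sinusoid carries
≈ 0.5 mm², consistent with reporting power in mm². No taper is applied (a
window would change the peak-power units); CF50 uses trapezoidal area with
linear interpolation of the cumulative curve inside the crossing bin.
Per-stance metrics are computed first and then averaged across stances.
Regions follow the 1-based landmark groups 2–6 (distal), 8–12 (mid), 14–18
(proximal), stored 0-based internally; the region metric is the mean over
its five landmarks.

## EMG intensity

The filter bank follows the non-linear scaling `cf_j = (1/scale)(j+q)^r`
with `scale = 0.3, q = 1.45, r = 1.959`, which places the 11 center
frequencies at 6.90 … 395.44 Hz. Each wavelet is defined in the frequency
domain as `W(f) = (f/cf)^(cf·scale) · exp((1 − f/cf)·cf·scale)`, zero at DC,
unit peak gain at `f = cf`. Band intensity is the squared magnitude of the
analytic signal of the band-filtered trace — an envelope-power demodulator
equivalent, for these band widths, to the original Gauss-filtered
instantaneous-power scheme; this is an approximation and is the one place
the implementation deliberately deviates from the cited construction.
Peak-gain normalisation is the default; a `sum` option rescales the bank so
the summed gain is ≈1 across the pass band for users who need approximate
reconstruction from the band sum (that scaling also makes the summed band
intensities track the signal's 6.9–395 Hz power, within ~20 % because the
bands overlap). Wavelet 1 (index 0) is never part of the total intensity
unless explicitly requested. Normalisation across locomotion conditions
divides every series by the single ensemble peak.

## Statistics

Repeated-measures ANOVAs use the classical univariate partition with the
subject-by-factor interaction as each main effect's error term and no
sphericity correction; the two-way design reports the interaction but
significance gating uses the main effects. Post-hoc comparisons are paired
t-tests with `p_adj = min(1, p·m)`. Trend fits are ordinary least-squares
polynomials (degree 1 or 2) with `r² = 1 − SS_res/SS_tot`; the quadratic
can never explain less variance than the linear fit (nested models), which
the tests assert. A zero-variance difference vector in a post-hoc pair is
reported as p = 1 when its mean is also zero and flagged degenerate
otherwise.

## Synthetic data: what it emulates, and what it does not

**Images.** Two bright curvilinear bands (quadratic in the column
coordinate, Gaussian cross-section σ = 3 px) over multiplicative speckle:
Rayleigh noise convolved with a σ = 1.1 px Gaussian kernel, scaled onto a
low-intensity background. Boundary motion is a prescribed sum of sinusoids
(low-frequency gait trajectory + oscillation components), so the landmark
truth is exact by construction. The generator rejects boundaries that leave
the image or approach each other. This defeats naive edge detection and
exercises the full ASM machinery, but it does *not* reproduce real
ultrasound physics: no fascicle striations, no depth-dependent attenuation,
no out-of-plane motion or probe decoupling, and boundary motion is spatially
uniform rather than a travelling wave. Passing the benchmark therefore
validates the algorithmic chain, not clinical-grade robustness.

**Forces.** Running stance = quarter-sine impact rise + rectified decaying
oscillation + a sin² active hump that starts at the impact peak with zero
slope; walking stance = two raised-cosine humps (first hump width
`w = 1/f_impact`) bridged by a sin² arch spanning the two hump peaks with
zero value and slope at both. These constructions make the max-RFD → peak
interval *exactly* a quarter period, which is what lets the estimator be
tested against truth at sample resolution; their overall shapes are only
coarse caricatures of real GRF morphology.

**EMG.** Band-limited Gaussian noise under cosine-tapered burst envelopes,
optional sinusoidal sub-10 Hz artifact, mean-removed.

**Study design.** The default synthetic study is 3 participants × 7
conditions (walking 0.7/1.4/2.0, running 2–5 m s⁻¹) × 4 stance phases, with
stride cutoffs at the protocol values, impact frequencies rising 8 → 20 Hz
and oscillation components rising 5 → 15 Hz / 1.0 → 2.0 mm across
conditions — inside the ranges the measurement context reports (input
frequencies 10–20 Hz, CF50 ~5–15 Hz). Stance durations shorten from 0.70 to
0.40 s with speed (56 → 32 frames at 80 Hz); these frame counts keep the
full pipeline, including per-participant ASM training on every 20th frame of
the two fastest-running conditions, at desk scale. With this construction
the recovered input frequency and CF50 are strictly monotone across
conditions, reproducing the qualitative speed effect; the in vivo F
statistics and fit coefficients themselves are not reproducible because the
original participant data are not redistributable.

## Known limitations

- Longitudinal (proximo-distal) displacement, travelling-wave analysis and
  time-domain velocity/acceleration of landmarks are out of scope.
- Landmarks measure displacement at fixed image columns; a muscle
  translating through the field of view is not tracked materially.
- The ASM search moves landmarks only along boundary normals and re-pins
  x-coordinates; strongly tilted aponeuroses would need a generalised
  landmark grid.
- CF50 of an all-zero (or numerically silent) series is reported as 0 Hz
  with an `all_zero` flag rather than raising.
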