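# Methods

`stridekit` measures spatiotemporal gait parameters from a single 6-axis
inertial sensor on the lateral side of each shoe, the instrumentation used
in clinical studies of Parkinson's disease (PD) gait. This note documents
the measurement model, the synthetic-data generator that serves as its
ground-truth oracle, the numerical choices, and what the validation does
and does not demonstrate about real recordings.

## Coordinate conventions

One fixed sensor frame is used throughout: **x** anterior (direction of
progression at midstance), **y** superior, **z** mediolateral. Sagittal
foot pitch is rotation about z, toes-up positive, so heel-strike (HS)
angles are positive (~19–22°) and toe-off (TO) angles negative (~−55°).
Yaw (heading) is reported clockwise-positive. Acceleration is stored in
m/s² (files may declare `g`; conversion uses exactly 9.81 m/s² per g) and
angular rate in °/s. The sensors saturate at ±6 g and ±500 °/s;
out-of-range values are clipped and counted, never dropped.

## The measurement chain

**Segmentation (subsequence msDTW).** A normalized multi-channel stride
template — by default the sagittal gyroscope plus the anterior and
superior accelerometers, each z-scored — is matched against the
whole-recording z-scored signal with subsequence dynamic time warping
(local cost: Euclidean distance across channels; steps
{match, insert, delete}; the template must be consumed in full, free start
and end on the recording side). Local minima of the end-cost profile below
a per-template-sample threshold become stride candidates; overlaps are
resolved greedily by ascending cost and the accepted boundaries are
snapped to the centre of the nearest windowed gyroscope-energy minimum —
the midstance plateau. The default threshold is calibrated once, on
held-out simulated walks spanning both the PD and control reference
distributions, as the mean + 3 SD of per-stride match costs under
deployment normalization. The sagittal gyroscope alone identifies typical
strides, but subjects with barely lifted heels (heel-strike angles of a
few degrees) lose their gyroscope signature; the accelerometer channels
carry the stance/swing alternation regardless, which is why the
multi-channel default is used.

Turning strides are excluded twice over: pivot-like turn steps do not
resemble the template in the accelerometer channels and are usually never
matched (turns appear as gaps between segments), and any matched segment
whose integrated yaw-rate exceeds 45° net heading change is labelled
`turning` and excluded from parameters. The first two non-turning strides
of each bout (bout starts are recording start, turning runs, and
longer-than-half-a-stride gaps) are labelled `initiation`; summaries can
include or exclude them.

**Event detection.** Within each segment: *midstance* is the centre of
the minimum-energy window (gyroscope magnitude, 0.1 s window) near the
segment start, with plateau-centre tie-breaking; *toe-off* is the most
negative sagittal gyroscope peak before the swing maximum; *heel-strike*
the most negative peak after it. Peak instants are refined to sub-sample
precision by parabolic interpolation through three samples — at 51.2 Hz
one sample is ~20 ms, so this matters for the 9 ms stride-time error
budget. Segments without a quiet stance window (windowed energy above a
30 °/s-RMS equivalent) or without a swing peak (max rate below 20 °/s)
are rejected, not silently measured.

**Orientation.** The sagittal pitch is anchored at midstance from the
accelerometer: the gravity direction is averaged over the contiguous
near-stationary samples around the midstance (gyroscope magnitude below
20 °/s, at most ±0.1 s) — expanding outward rather than using a fixed
window keeps the average off the violent push-off onset when the flat
phase is short. If the averaged magnitude deviates more than 20% from 1 g
the stride is rejected. The pitch course is the anchor plus the
cumulative trapezoidal integral of the sagittal angular rate.

**Trajectory (ZUPT strapdown).** Between the midstance anchors of
consecutive segments, the specific force is rotated to the world frame
with the pitch course (2-D sagittal strapdown; turning strides are
excluded so no heading estimation is needed), gravity subtracted, and
integrated to velocity. A linear drift correction forces the velocity to
exactly zero at both anchors — the zero-velocity update; the foot is
genuinely stationary there, which the flat-foot windows of the simulator
reproduce. A second trapezoidal integration gives position. Stride length
is the horizontal displacement magnitude; toe clearance is the maximum of
the sensor height plus the lever-arm correction
`L · (sin θ − sin θ_midstance)` with `L = 0.10 m`, the declared
toe-to-sensor distance along the foot axis (the simulator uses the same
geometry, making clearance recovery testable; real deployments would
calibrate `L`).

**Parameters.** A gait cycle is timed heel-strike to heel-strike; stance
runs to the following toe-off, swing is the remainder, both reported as
percent of stride time (they sum to 100 by construction). Gait velocity is
stride length over stride time; cadence is strides per minute
(60 / stride time — the convention consistent with published cohort means
of ~55–58 alongside ~1.0–1.1 s stride times). Walk summaries pool both
feet and report mean and coefficient of variation (CV = 100·SD/mean,
sample SD with n−1 — stated explicitly because per-walk stride counts are
small) per parameter, always excluding turning strides and optionally the
initiation strides. Stride length can additionally be normalized to body
height (dimensionless ratio of the mean).

**Cohort statistics.** One value per subject per visit (the walk-summary
mean). Two groups are compared with the classical pooled-variance
independent t-test (Welch by flag); three or more strata with one-way
ANOVA followed by all pairwise t-tests, Bonferroni-multiplied by the
number of pairs and capped at 1 — corrected across pairs within a
parameter, not across parameters. Stratifications: PD vs control, Hoehn &
Yahr stage, UPDRS-III bands (low 1–12, middle 13–22, high ≥ 23), and the
single gait / postural-stability items; controls always form their own
stratum. Longitudinal change classifies each returning patient by the
gait-item delta — lower rating = improved, higher = worsened, unchanged =
stable (the UPDRS convention: higher scores mean more impairment) — and
reports per-parameter percent change from baseline. Significance is fixed
at p < 0.05; group values are presented as mean ± SEM (sample SD/√n).

## The synthetic-gait generator

The simulator is the package's ground-truth oracle: it plans, per stride,
a closed-form twice-continuously-differentiable toe trajectory and pitch
course that satisfy every target quantity *exactly by construction*, then
derives the 6-axis sensor signal by rigid-body kinematics (sensor = toe
− 0.10 m along the foot axis).

One stride runs midstance to midstance over period `T` with stance
fraction `γ`:

* flat-foot windows (±10% of stance time) around each midstance in which
  the foot is exactly stationary and level — the ZUPT anchors;
* the midstance sits 35% into its stance, so most of late stance is
  available for the push-off rotation (consecutive identical strides
  still produce exactly the configured stance fraction, because stance is
  measured HS→TO across the cycle);
* pitch rate built from cos⁴-edged pulses: a broad plateau'd
  plantarflexion approach ending cleanly before a symmetric peak exactly
  at toe-off; a rate-capped swing pulse (plateau grows instead of the
  peak when the rotation budget is large); a symmetric peak exactly at
  heel strike; and a gentle landing pulse returning the foot to flat.
  Pulse areas are solved so pitch equals the requested TO/HS angles at
  the events and returns to zero; peak prominence is pre-compensated for
  the anti-aliasing attenuation so detectors find the events after
  filtering. The heel-strike peak's share of the rotation adapts so it
  stays above the landing plateau even for short strides;
* a 7th-order-smoothstep horizontal toe displacement equal to the stride
  length, and a `sin⁴` clearance bump peaking exactly at the requested
  toe clearance.

**Anti-aliasing front end.** Real IMUs low-pass before sampling; the
simulator does the same (8× oversampling, zero-phase 33-tap FIR at 16 Hz,
decimation to 51.2 Hz), and white sensor noise (defaults 0.05 m/s²,
0.5 °/s — a plausible MEMS noise floor) is added after decimation. This
matters numerically: physiological push-off transients are too fast for
millimetre-accurate trapezoidal integration of pointwise 51.2 Hz samples.
Because the event peaks are locally symmetric with zero pitch curvature
at the event, and the flat windows are wider than the kernel, filtering
preserves event times, event angles, per-stride displacements and peak
clearance essentially exactly; the one visible cost is that the
*interior* of the fastest rate transients is smoothed, so the integrated
pitch can deviate from the pre-filter plan by up to ~1.5° for a few
samples around push-off. Validation therefore asserts pitch accuracy of
0.5° at the events and over the large majority of samples, with a looser
cap inside transients.

**Walks and turns.** A walk is `n_bouts` straight bouts of
`n_strides_per_bout` strides joined by 180° turns executed as pivot steps
(default two per turn, ±90° each), direction alternating clockwise,
counter-clockwise, clockwise. Each foot gets an independent stride
sequence. Quiet standing with a faint deterministic sway pads both ends
(the sway keeps the pad's gyro energy above the flat-foot floor so the
first and last midstance remain identifiable). Optionally the first two
strides of every bout are shortened/slowed (initiation scaling); cohorts
configured from published group means leave this off, because those means
were reported *with* initiation strides included.

**Cohorts.** Between-subject distributions are configured from published
group means ± SEM of large PD (n=190) and control (n=101) cohorts; the
implied between-subject SD is SEM·√n. Within-subject (stride-to-stride)
SDs are free simulator parameters (defaults: 4 cm length, 25 ms time,
0.8% stance, 0.6 cm clearance, 1.2° angles — ordinary stride-to-stride
variability). Per-bout stride counts derive from each subject's stride
length and the 10 m bout distance. Subject means are drawn by
Latin-hypercube (stratified truncated-normal) sampling: the marginals are
unchanged, but a 50-subject cohort represents the configured distribution
with far less cohort-level sampling error than independent draws — a
standard simulation-study variance-reduction choice. Clinical metadata
(H&Y, UPDRS items, height, age) are plausible synthetic values attached
for the stratified statistics, not modelled jointly with gait.

**Sensor-feasibility envelope.** Draws whose planned sagittal rates
exceed the ±500 °/s gyroscope range are rejected and redrawn: a very fast
stride with full clinical angle excursions would saturate the sensor and
carry no usable signal (the real hardware would clip too). This truncates
the joint distribution mainly in the short-stride-time corner; measured
effect on the target parameters (length, clearance, stance fraction) is
below 0.1 SEM, while the mean stride time rises by ~0.03 s.

## Numerical choices

* Trapezoidal integration throughout (pitch, velocity, position):
  deterministic and second-order, matching the analytic test tolerances.
* Gravity constant exactly 9.81 m/s² for bit-exact unit tests.
* Event-detector thresholds (0.1 s energy window, 20 °/s static-rate
  gate, 20% gravity deviation, 0.3 s minimum stride duration) are keyword
  arguments with these defaults.
* DTW ties break toward the diagonal step and earlier starts; candidate
  segments are limited to 0.5–1.9 template lengths.
* The DP kernels are JIT-compiled when `numba` is available, with an
  identical pure-Python fallback.
* Seeded `numpy.random.Generator` everywhere; identical seeds reproduce
  recordings bit-for-bit.

## What the validation shows — and what it does not

Every accuracy number the package reports (stride-time MAE ~0.7 ms,
stride-length MAE ~0.9 cm on the default noisy batch; cohort grand means
recovering the configured group values within a few percent) is measured
against the simulator's exact labels. The simulator reproduces the
*structure* the estimators rely on — quiet midstances, event-locked
rotation peaks, 4×10 m bout/turn layout, realistic amplitudes, sensor
noise, saturation and bandwidth — but not everything about pathological
gait: no freezing or festination episodes, no shuffling with absent
flat-foot phases, no soft-tissue artefacts, no gyroscope bias drift or
temperature effects, and sensor geometry (the 0.10 m lever arm) is known
rather than calibrated. Published validations of this sensor setup
against optical motion capture report 9 ms / 3.9 cm mean absolute errors;
passing those bounds here on synthetic data shows the algorithm chain is
not the limiting factor, not that real-world accuracy would match.

## Known limitations

* Straight-stride sagittal (2-D) reconstruction only; turning strides are
  excluded by design, as in the target protocol.
* Stride-to-stride variability (CV) of the synthetic cohorts comes from
  the configured within-subject SDs, not from a validated model of
  pathological variability; CV-based findings on synthetic data are
  qualitative.
* The clearance estimator's lever-arm geometry is declared, not
  estimated; the published systems compute clearance without shoe-size
  input by a method not fully specified, so this is an explicit,
  documented substitute.
* Very fast strides (roughly, stride time below ~0.9 s at full clinical
  angle excursions) fall outside the sensor-feasible envelope and are not
  generated.
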