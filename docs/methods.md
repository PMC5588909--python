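# Methods

`svopsim` is a software model of a saccadic-vector perimeter: a threshold
visual-field test in which the subject's response is an eye movement toward
the stimulus rather than a button press. The package contains the complete
instrument (geometry, display, gaze classification, thresholding algorithm),
a synthetic patient/eye-tracker that closes the loop, and the statistical
machinery used to evaluate such an instrument against standard automated
perimetry (SAP). This note records the model, its assumptions, the defaults,
and the design choices made where the instrument's public description leaves
the behaviour open.

## Test geometry and the decibel scale

The test pattern is the standard 24-2 grid: 54 points on a 6° lattice offset
3° from both meridians, extended nasally to 27°, with the temporal pair at
(15°, ±3°) flagged as the physiologic blind spot. Coordinates are degrees of
visual angle in a screen-direction frame (+x subject's right, +y superior);
the left-eye pattern is the mirror image, so nasal/temporal structure lands
on the correct side of space for either eye.

Sensitivity is expressed on the SAP attenuation scale:
`increment = L0 · 10^(−dB/10)` with `L0 = 10,000 asb = 10,000/π ≈ 3183.1
cd/m²`. Stimuli are drawn as the increment *added to* the 10 cd/m²
background, so the brightest displayable level (14 dB) corresponds to a
screen luminance of `3183.1·10^−1.4 + 10 ≈ 136.7 cd/m²` — within 0.1% of the
instrument's quoted LCD ceiling, which is why the increment-plus-background
reading of the scale was adopted. The instrument's displayable range is
14–40 dB; sensitivities below 14 dB are *unmeasurable*, and comparison
values from the reference device are truncated up to 14 dB before any
agreement statistic (truncation before correlation, never after).

Stimuli are Goldmann III (4 mm² at the 300 mm reference distance, ≈0.43°
diameter), 200 ms, on a 10 cd/m² background. Goldmann sizes I–V follow the
area-quadrupling progression.

## Gaze-contingent projection

The subject views a flat screen (default 24″ 16:10, 518×324 mm) from a
tracked 3-D eye position (nominal distance 550 mm, no chin rest). Stimulus
placement uses exact trigonometry in a fixation-centred tangent frame: with
`f` the unit vector from eye to fixation point and `r`, `u` the right/up
axes of that frame, a stimulus at angular offset (θx, θy) lies along
`f + tan(θx)·r + tan(θy)·u`, intersected with the screen plane. The inverse
(screen point → angular offset) is algebraically exact, which makes the
compensation contract testable: for any eye translation within ±100 mm
laterally and ±150 mm in depth, re-deriving the angle of a projected
stimulus returns the request to machine precision (measured worst case
~2·10⁻¹⁴ °). Stimuli are drawn as circles; only the diameter is compensated
for viewing distance (no obliquity ellipse), since the instrument's public
description gives no projection math and the angular errors at 24-2
eccentricities are far below the psychophysical tolerances.

The display is a monotone grey-level → luminance look-up table (default: a
1024-entry gamma-2.2 curve whose top entry is exactly the 14 dB stimulus
luminance). Lookup is nearest-neighbour; requests above the table's top
entry raise a gamut error — the physical mechanism behind the 14 dB floor.
At the dim (40 dB) end the quantisation step of the synthetic LUT is
~0.07 cd/m², i.e. delivered levels can be off by a fraction of a dB; the
engine reasons in dB and logs the requested luminance, so this only models
delivery, it does not perturb thresholds.

## Gaze-response classification

A presentation is *seen* when a saccade beginning after stimulus onset lands,
within the response window (default 1 s), on a vector matching the
fixation→stimulus vector in direction (default tolerance 20°) and amplitude
(default ±30% of the required amplitude); *unseen* when the window elapses
with gaze held on fixation (within the fixation tolerance); and *invalid*
otherwise (lost tracking, or a movement on a non-matching vector). Invalid
presentations decide nothing and are re-presented. Saccades are detected at
an inter-sample angular velocity above 100°/s (60 Hz sampling); the landing
point is the componentwise median of the post-movement samples. All angular
quantities are computed through the concurrently tracked eye pose, not in
raw millimetres, because the tolerances are specified in visual angle.

Fixation is verified over a dwell window (200 ms in software v1, 500 ms in
v2) with a 2.0° default tolerance; more than 50% invalid samples in the
window is a tracking-quality failure and the presentation is withheld. The
fixation tolerance can be supplied as a function of the upcoming stimulus
eccentricity (a hook for relaxing the requirement for peripheral targets);
the default is constant. Only the 1-second unseen window is externally
specified; the other tolerances are package defaults chosen at plausible
oculomotor magnitudes and are all configurable. A corrective second saccade
cannot rescue a hypometric first saccade: the decision is single-saccade.

## Thresholding engine

Each location runs a full-threshold 4-2 staircase: 4 dB steps until the
first response reversal, 2 dB after, terminating at the second reversal with
threshold = last seen level (the classic convention; the number of reversals
and the estimator are package choices, as only "4-2 bracketing" is
externally specified). Levels clamp to [14, 40]; two consecutive unseen
responses at 14 dB terminate as unmeasurable (recorded at the floor), two
consecutive seen responses at 40 dB terminate at the ceiling.

Testing begins at four seed locations, one per quadrant (±9°, ±9°), started
at 25 dB. Completed thresholds propagate outward: a location becomes
schedulable once a 4-neighbour has finished, and starts at the rounded mean
of its finished 4-neighbours' thresholds. Unmeasurable (floor-saturated)
results are excluded from propagation — they carry no information about a
neighbour's sensitivity, and including them would bias starting levels near
the blind spot; if no measurable 4-neighbour exists the nearest measurable
finished location is used, and failing that the seed start. Under v2,
starting levels are additionally clamped to ≥18 dB so that no threshold can
rest on a single response; v1 has no clamp. Scheduling is uniform random
among eligible locations (seeded RNG); v2 adds a priority weight (default
0.05 per round waited) favouring locations stuck in the queue, and weight 0
reproduces v1 scheduling exactly. The v1/v2 differences are confined to the
clamp, the dwell, and the priority weight.

Eligibility is gaze-contingent: a location is testable only if its stimulus,
projected from the *current* fixation point and eye pose, falls fully on
screen. A seen stimulus becomes the next fixation target; unseen stimuli do
not move it. When no location is eligible (e.g. fixation has migrated to a
screen edge), the engine presents a synthetic re-centering fixation target
at the screen position that maximises the number of eligible locations —
some recovery rule is required and none is externally specified. Persistent
tracking failure beyond a retry budget (default 25 consecutive failures)
ends the session as *incomplete*, never as an exception. Blind-spot
locations run the same staircase as everywhere else; their floor saturation
and poor repeatability are emergent, not special-cased.

A button-response comparator (`run_sap_like_session`) runs the same 4-2
engine and growth pattern with no gaze layer, standing in for a SAP device
in the analysis; the observer's false-positive rate is carried on the result
for the exclusion rule. It is a comparator of the *thresholding* logic, not
a model of SITA.

### Accuracy of the staircase

A two-reversal 4-2 bracket terminates with a 2 dB gap between the dimmest
seen and brightest unseen level, so two adjacent integer truths can produce
identical response sequences from the same start: *exact* recovery of an
arbitrary truth is impossible in principle, and the guaranteed bound for a
deterministic (step-psychometric) observer is 2 dB (measured worst case over
all truths 15–39 and starts 18–30: 1 dB). Exactness does hold whenever the
starting level equals the truth (start t → seen, unseen, unseen, seen →
threshold t), which is the configuration the noiseless closed-loop test
uses: a flat 25 dB field equal to the seed start, which propagation then
preserves. The same mechanism means a zero-noise observer is not perfectly
repeatable across sessions — the ±1 dB start dependence varies with the
randomised testing order — so "noiseless" cohort correlations are near,
but not exactly, 1.

## The synthetic observer

Frequency of seeing is the standard perimetric model: `p(seen) = fp +
(1 − fp − fn)·Φ((t − level)/σ)` with `t` the true sensitivity and σ the
psychometric slope in dB (default 2 dB; fp = fn = 0.03). At σ = 0 the model
is the deterministic step observer (seen iff level ≤ t). Ground-truth fields
are a hill of vision (peak 31.5 dB, 0.08 dB/° eccentricity slope, 1 dB
between-location noise — a healthy cohort then averages ~28–31 dB) with
optional glaucomatous archetypes: a shallow nasal paracentral cluster
(early), a Bjerrum-region arcuate defect in one hemifield, or advanced loss
(diffuse 10 dB plus deep defects in both arcuate regions, putting ≥20 points
below the 14 dB floor). Blind-spot points have zero sensitivity.

Gaze synthesis runs at 60 Hz. Tracker/fixational error is AR(1)-correlated
angular jitter (lag-1 correlation 0.9) with stationary RMS
`gaze_noise_deg` (default 0.5°, the manufacturer-class error bound): the RMS
magnitude, not the sample-to-sample velocity, is the controlled quantity —
white jitter of that magnitude would exceed the saccade velocity threshold
and masquerade as saccades. Seen decisions inject a saccade at a Gaussian
latency (250 ± 50 ms) landing at the stimulus plus endpoint noise
(`landing_noise_deg`, default 0.5°); samples drop out with probability 0.02;
the head drifts laterally at 2 mm/s in a random direction, exercising the
gaze-contingent compensation. With every noise parameter at zero the
synthesised streams are exactly classifiable: simulator and classifier are
inverses, which is what makes the closed-loop engine tests decisive.

What the simulator does *not* model: image-level eye tracking, smooth
pursuit and microsaccades, corrective second saccades, learning and fatigue
within a session, lid/lens-rim artefacts, and age correction of normal
fields. Passing tests therefore demonstrate the correctness and internal
consistency of the instrument's algorithms under a standard noise model,
not clinical performance on patients.

## Analysis

Exclusions mirror the clinical pipeline: gaze tests are excluded iff
incomplete; button tests iff their false-positive rate exceeds 15%
(artefact grading requires a human and is reported as a non-simulated
category). Agreement is Pearson correlation of per-test mean sensitivity
and, pointwise, of per-location thresholds across test pairs, with the
comparison device truncated at 14 dB *before* correlating (only the
comparison side — the gaze instrument cannot emit values below its floor by
construction). Repeatability is the same pointwise correlation over
same-device repeat pairs, with no truncation; the headline repeatability
figure is the mean per-location r. Summaries are always computed both with
and without the blind-spot pair (52- and 54-point versions), since both
conventions are in clinical use. Correlations use `scipy.stats.pearsonr`;
locations with fewer than 3 complete pairs or zero variance report NaN.
Simulated test durations are bookkeeping from the event-log timestamps
(dwell, stimulus, latency/window) and are reported but not treated as a
validated quantity — real durations are hardware- and patient-dependent.

`cohort_experiment` drives everything end to end: it builds a seeded cohort
(healthy + glaucoma archetype mix), runs the gaze test and the button
comparator twice per repeat subject, applies exclusions, and emits the
mean-threshold scatter, pointwise agreement map, repeatability maps, and
duration summaries. The RNG hierarchy is master seed → per-observer field
seed → per-session substreams, so whole cohorts and individual sessions are
independently reproducible; CLI outputs carry a manifest sufficient to
re-run them byte-identically (no wall-clock timestamps are embedded).

## Problem sizes in the shipped checks

The acceptance script (`scripts/acceptance.py`) measures: the staircase
sweep over all 325 truth×start combinations; one noiseless and twenty noisy
closed-loop sessions; a 2000-point head-translation projection grid; and a
16-observer simulated cohort (8 healthy, 8 glaucoma, two runs per device per
subject). These sizes were chosen to estimate each quantity stably while
keeping a full run in the tens of seconds; the cohort correlations they
print describe this synthetic cohort, whose between-subject variance is
larger and whose noise sources are cleaner than a clinical population's, so
they sit above clinically reported agreement figures.
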