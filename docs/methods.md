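# Methods

This note records the models, conventions, and numerical choices behind
`casakit`, and what the synthetic-data generators do and do not emulate.

## Motility decay and the CatSper-Activity-Index

Dilution of CatSper-competent human sperm in Ca²⁺-free buffer arrests
motility; the motile fraction is modelled as a one-phase decay

    Y(t) = 100 · exp(−t/τ),

with the initial fraction constrained to 100 % (samples are normalized to
their own t = 0 motility). `fit_decay` fits τ by nonlinear least squares
(scipy `curve_fit`, τ bounded positive), seeding τ₀ from the first crossing
of 50 % (τ₀ = t½/ln 2) or, failing that, half the series span. A series
with no net decrease (last value ≥ first) cannot identify τ and is reported
as `τ = inf, converged=False` — the control-buffer behaviour. A
plateau-term variant `Y = P + (100−P)·exp(−t/τ)` is available via
`fit_plateau=True` for series that level off above zero (partial
inhibition); the default has no plateau, matching the constrained form.

The index contrasts motile fractions in control Buffer A and Ca²⁺-free,
progesterone-fortified Buffer B at a 15/30/60-min readout:

    CAI = 100 · (1 − M_B/M_A), clamped to [0, 100].

The published equation exists only as a figure image, so this form is a
documented assumption, isolated in `compute_cai` for easy replacement. It
reproduces the reported behaviour at both ends: Buffer B arrests motility
in donors (M_B → 0, CAI → 100, donor range ≈ 70–100), while inhibited or
defective CatSper preserves M_B ≈ M_A (CAI → 0). The screening threshold
is CAI ≤ 40, inclusive. The index is scale-invariant in (M_A, M_B) and
monotone decreasing in M_B; both are property-tested. Samples with
M_A < 10 % are outside the test's applicability and raise a warning.

`estimate_prevalence` exposes the arithmetic
`100·(n_defective/n_group)/male_factor_share` with the share a parameter
(default 0.5) rather than a hard-coded cohort, since the underlying
stratified counts are not part of this package's inputs.

## CASA kinematics

Tracks are 2-D head positions in µm at uniform frame spacing. Definitions:

* VCL = Σ frame-to-frame distances / duration; VSL = first-to-last
  distance / duration; VAP = arc length of the smoothed (VAP) path /
  duration.
* The VAP path is a centred moving average (default window 5 frames,
  configurable); near the ends the window shrinks symmetrically so it
  stays centred, the endpoints are preserved, and a straight track is
  smoothing-invariant. This also preserves VSL ≤ VAP ≤ VCL ordering.
* The lateral deviation is the signed perpendicular distance of the head
  from the VAP path (sign from the cross product with the local path
  tangent). ALH = 2 × mean |deviation| — the factor 2 approximates the
  peak-to-peak convention and makes the 7 µm gate attainable; it is
  configurable (`alh_factor=1`) because conventions differ between CASA
  implementations. BCF counts every sign change of the deviation per
  second, with no ½ factor; zeros are skipped rather than counted.
* LIN = VSL/VCL, STR = VSL/VAP, WOB = VAP/VCL; LIN and WOB are clamped to
  ≤ 1 against floating-point overshoot. A track with VCL = 0 gets all
  ratios 0 and both flags false.
* Motility is VCL ≥ 10 µm/s (a named constant; the threshold is a design
  choice, not a published definition). Hyperactivation is VCL ≥ 150 µm/s ∧
  LIN ≤ 0.5 ∧ ALH ≥ 7 µm, boundaries inclusive.

Head detection thresholds each frame (Otsu by default, fixed threshold
optional), labels connected components, filters by area, and returns
intensity-weighted centroids; a constant frame yields no detections.
Linking is greedy mutual-nearest-neighbour under a displacement gate —
adequate at the simulated densities; no gap closing, so a missed detection
terminates a track (Hungarian assignment was considered and rejected as
unnecessary at these densities). Image coordinates are 0-based pixels,
origin top-left, y down; tracks are stored in µm.

## Kinetic (time-resolved) CASA

Analysis windows default to [0,15), [15,30), [30,45), [45,60), [60,75),
[105,120), [165,180) seconds. Printed protocols give the interior bounds
as 16, 31, 46, 61 s; the half-open contiguous form avoids unanalyzable 1-s
gaps, and `literal_gap_scheme()` reproduces the printed bounds exactly.
Within each window, three 1-s sub-intervals are placed evenly from the
window start to end−1 s (0, 7, 14 s in the first window); placement is a
convention, not prescribed. A track is clipped to the first sub-interval
it overlaps with ≥ 2 samples and counts once per window (single
assignment); sub-interval groups are pooled and the window value is the
percent of pooled tracks passing the hyperactivation gate. Empty windows
are NaN, not 0.

`baseline_correct` subtracts the buffer-only control timecourse window by
window. With a steady control this already yields ≈ 0 before the stimulus
acts, which is how the corrected curves are anchored at t = 0; an optional
`anchor_first=True` additionally forces the first-window delta to exactly
zero. That literal shift is appropriate only when the first window precedes
the response — applied to a transient confined to the first window it would
null the signal by construction — so the default is plain control
subtraction.

## Tethered-sperm beat analysis

θ(t) is unwrapped (360° period) and zeroed at its first sample. The
decomposition is deliberately two-stage — Ω from the OLS slope, then a sine
fit `A·sin(2πft+φ)` to the detrended residual — because slope and
oscillation are reported as separate quantities and are nearly orthogonal
on these traces. The sine frequency is seeded at the residual periodogram
peak and (A, φ) at the complex demodulate there; because the OLS slope is
slightly biased by the oscillation unless the window holds an integer
number of periods, the fit alternates sine estimation and slope
re-estimation twice, which makes noiseless decompositions exact to ~1e-9.
A joint 4-parameter refinement is available behind `joint_refine=True`.
Degenerate traces (residual numerically zero, e.g. a pure ramp) report
amp = 0 with `converged=False`; a periodogram peak at Nyquist raises an
aliasing warning and marks the fit unconverged. Pre/post deltas are
post − pre, so a frequency decrease is negative.

Beat envelopes take, per arc position, the maximum signed perpendicular
distance above and below the head-midpiece axis across ≥ 3 centerlines;
"above" is the positive cross-product side of the axis direction (recorded
convention). The asymmetry index is

    AI = |↑AUC − ↓AUC| / (↑AUC + ↓AUC),

with AUCs by the trapezoid rule on the stored arc grid (generator default
64 points over a 50 µm flagellum). The published equation is again
figure-only; this normalized-absolute-difference form satisfies both
stated endpoints (0 = symmetric, 1 = one-sided), is invariant to swapping
the sides and to uniform scaling, and lives in one function. Angular beat
amplitude (degrees, from the angle-trace fit) and translational beat
amplitude (µm, from envelopes) are distinct observables; both are
implemented and no conversion between them is assumed.

## Ca²⁺ traces

ΔF/F₀ (%) uses the mean fluorescence before the first event, minus a 1-s
guard band, as F₀ (≥ 3 samples required, F₀ > 0). Response amplitude is
the ΔF/F₀ maximum between stimulus and ionomycin, normalized to the
post-ionomycin maximum; both are invariant under multiplicative gain.
Waveform classification smooths the stimulus segment with a 0.5-s moving
average and finds peaks above 5 % of the ionomycin maximum: two maxima
whose intervening trough drops ≥ 10 % of the lower peak give "biphasic"
(a still-elevated plateau at the segment end counts as the second
maximum), one gives "monophasic", none gives "none". The original
classification was done by eye, so these thresholds are config constants,
not published values.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed) via `numpy.random.default_rng`
and are bit-reproducible; populations derive per-track seeds from a
`SeedSequence`, and class counts use largest-remainder rounding (ties by
mixture order) so compositions are exact.

* **Trajectories** (80 fps, 1 s): a drift of speed v whose heading turns at
  rate v·κ (closed-form circular arc), plus a lateral sinusoid
  perpendicular to the heading, plus isotropic Gaussian jitter. Frozen
  defaults: progressive v = 100 µm/s, 1 µm lateral at 10 Hz, κ = 0
  (LIN ≈ 0.9, ALH ≈ 0.7 µm — fails the gate); hyperactive "star-spin"
  v = 30 µm/s on a ≈ 4.8 µm circle (κ = 0.21 µm⁻¹, one revolution per
  second) with a 9 µm lateral sinusoid at 16 Hz (VCL ≈ 540 µm/s, LIN ≈ 0,
  ALH ≈ 10 µm — passes with margin on 100/100 seeds); immotile: jitter
  only, at 0.03 µm so frame-rate-amplified noise stays below the 10 µm/s
  motility threshold. The 16 Hz beat is chosen so the 5-frame VAP window
  removes the oscillation and ALH captures it; the resulting VCL is above
  the physiological range, which is acceptable here because the gate is
  the only quantitative constraint the source provides for this class —
  these tracks exercise the classifier, they are not hydrodynamic
  simulations. No flagella are rendered in images (head tracking only).
* **Decay series**: binomial sampling of 200 counted cells per time point
  (the observable is a counted fraction; no published noise model exists),
  times 0–60 min in 5-min steps, converging to 100·exp(−t/τ) as n grows.
* **Angle traces** (135 fps, 15 s): ramp + sinusoid + 2° Gaussian noise;
  specs with frame_rate ≤ 2·osc_freq are rejected at construction.
* **Envelopes**: unit half-sine or triangle profiles scaled so trapezoidal
  areas match the spec to 1e-9 relative.
* **Cohorts**: CAI uniform within the stated donor (70–100) and defective
  (≤ 40) ranges — only the ranges are published. Ranges straddling the
  threshold are flagged in metadata.
* **Ca²⁺ traces**: baseline 200 a.u., stimulus waveform scaled to
  `response_amp · iono_amp`, ionomycin as a fast saturating step; the
  biphasic shape is a fast transient plus a delayed sustained component.
* **Kinetic ensembles**: per analysis window, 1-s tracks spread over the
  sub-interval start times with an exact (largest-remainder) hyperactive
  share; randomness enters through trajectories, not composition, so
  recovered fractions are exact up to classification error.

Passing tests on these data shows the *computations* are correct under the
stated models; it does not validate detection/linking against real
dark-field noise, flagellar segmentation (centerlines are consumed, not
extracted), out-of-plane beating, cell collisions, or biological
variability between subjects.

## Problem sizes and tolerances

The test suite and the acceptance script use 9 seeded series for decay and
beat-parameter recovery, 100-seed gate checks, 1,000-track populations for
gate classification, and 5 × 500-track-per-window ensembles for the
kinetic pipeline; the full suite runs in about half a minute and the
acceptance script in under one. Monte-Carlo tolerances (τ̂ within ±10 %,
beat frequency within ±0.2 Hz, Ω within ±5°/s, kinetic delta within the
~2-point binomial CI) were established by simulation at these sizes before
being frozen into tests. Noiseless identities are asserted at 1e-6 or
tighter; envelope-area round trips at 1e-9 relative.
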