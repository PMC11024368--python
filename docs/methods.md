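# Methods

This note documents the models, numerical choices and known limitations of
`gazealter`, in the order data flows through the toolkit.

## Coordinate pipeline

**Conventions.** Eye space is right-handed: +x right, +y up, +z forward
through the display; the screen plane sits at z = 0. A log record stores
the eye's position relative to that plane with the z component as the
*positive* eye-to-screen distance, i.e. the physical eye is at
(GOx, GOy, −GOz). Under this convention the mm conversion
`G_m = GD·(GOz/GDz) + GO` is identical to intersecting the ray
`origin + t·direction` with z = 0, which is what the test suite checks
against. Pixels are 0-based with the origin top-left and y down, so the
pixel conversion flips the sign of y_mm.

**Display defaults.** 2880 × 1600 px across both eyes, 119 mm panel
width, 110° horizontal FOV. The vertical panel height and FOV of the
target headset are not published; we default the height to the width
scaled by the pixel aspect ratio (≈66.1 mm) and the vertical FOV to 90°.
Both are explicit `DisplayModel` fields and can be overridden. An
`flip_x` flag mirrors the horizontal pixel axis for trackers with a
left-handed screen convention.

**Pixel ↔ degree map.** A linear small-angle map
(`deg = (px − TP/2)·FOV/TP`). It is exactly invertible and adequate for
the central ±30° where the analyses operate; it increasingly understates
true eccentricity toward the FOV edge (a tan-map would be exact but would
break the affine composition used throughout the renderer).

**Head-combined gaze.** The eye-in-head direction is rotated by the head
orientation as an intrinsic X→Y→Z Euler composition (degrees). Rays that
are parallel to the screen or point away from it raise a degenerate-ray
error rather than returning the algebraic (behind-the-head) intersection.

## Event classification

Angular speed between consecutive gaze directions
(`arccos` of the dot product over the sample interval, assigned to the
interval midpoint) is smoothed with a Savitzky–Golay filter (window 5,
order 2 at 120 Hz); smoothing never runs across temporal gaps longer than
two sample periods, so blink-induced gaps (validity < 31 samples removed
upstream) isolate trace segments and no event can bridge a blink.

The saccade threshold adapts to the data: `PT ← level + 6·scale` of the
sub-PT samples, iterated from 200 °/s until the change is below 1 °/s
(error after 1000 iterations). By default *level/scale* are the median
and 1.4826·MAD. The textbook mean/sd variant is available
(`threshold_estimator="moments"`) but is not the default for a concrete
reason: on saccade-dense free-viewing traces (2–3 saccades/s, median
amplitudes 6–8°) the in-flight flank samples contaminate the sub-threshold
set enough that the mean+6·sd fixed point lands near 240 °/s — above the
peak velocity of a 6° saccade under the main-sequence law — and medium
saccades are missed wholesale. The robust estimator converges to the
fixation-noise level regardless of saccade density. A floor of 10 °/s
keeps the peak threshold meaningful on noiseless synthetic traces where
the noise estimate collapses to 0.

Saccade seeds (samples above PT) are extended outward to an onset/offset
threshold of `level + 3·scale`, floored at the 2 °/s fixation criterion;
overlapping extensions merge. Saccade amplitude is the great-circle angle
between the gaze directions at onset and offset when directions are
available (the full pipeline), or the time-integral of speed as a
fallback when classifying a bare velocity trace.

**Fixation criterion.** The published criterion — fixation when velocity
is below 2 °/s — cannot be applied to raw sample-to-sample velocity at
120 Hz: isotropic fixational jitter of σ = 0.05° alone produces ~8 °/s of
velocity noise. We therefore apply the 2 °/s criterion to the *drift
velocity* of each inter-saccade interval: the net angular displacement
between its first and last gaze sample divided by its duration. Jitter
has near-zero net drift, so jitter periods classify as fixations (the
behavior the criterion is meant to capture), while steady pursuit-like
drift above 2 °/s falls into the "other" class, which is also where
intervals shorter than 40 ms land. Saccades below 1° are removed
afterwards as putative micro-saccades; the boundary is inclusive (exactly
1.0° is kept) per the "less than 1°" wording of the rule, and both pre-
and post-filter counts are available (rates are computed post-filter).

## Metrics and statistics

Total head rotation sums the Euclidean norms of consecutive Euler-angle
deltas. Each angle series is unwrapped before differencing: a 359°→1°
representation jump contributes 2°, not 358°, since a wrap-around is not
a physical movement. Median-based event summaries report `None` (not 0)
when no event of a kind exists, so aggregation cannot fabricate short
fixations.

The Friedman statistic is computed from within-subject ranks (mean ranks
on ties) with the standard tie correction; it matches
`scipy.stats.friedmanchisquare` to machine precision in the tests, which
also verify the nominal 5% type-I rate by simulation. "Tukey-corrected"
post-hoc comparisons after a Friedman test are implemented as the Nemenyi
studentized-range procedure on rank sums — the standard Tukey analogue
for this design — with the more powerful Conover t-procedure
(Holm-corrected) as an alternative, since the exact procedure behind that
phrase is a matter of interpretation.

## Impairment rendering

No quantitative rendering parameters (scotoma size, blur strength, gray
level, deformation magnitude or period) are published for the conditions
being emulated; every numeric default below is a package convention
chosen to represent an *advanced* stage of the condition, and all are
config fields.

* **Scotoma (B):** radius 10°, gray level 64, smoothstep edge over 2°;
  pixels beyond radius + softness are bit-identical to the input.
* **Metamorphopsia (B):** 8 force-field sources ringed at 0.6 × scotoma
  radius around gaze (seeded angular and amplitude jitter), each pushing
  pixels radially with Gaussian falloff (σ = 30 px, amplitude ≤ 6 px per
  source); offsets scale with `1 + 0.3·sin(2πt / 2 s)`. The offset field
  depends on pixel position only through (pixel − gaze), which makes the
  gaze-contingency shift property exact; the warp samples with bilinear
  interpolation, so a zero field is the exact identity. The maximum
  offset is bounded by n_sources · amplitude · (1 + depth).
* **Tunnel (T):** aperture radius 10° (bit-identical interior),
  smoothstep transition over 2°, periphery blurred up to σ = 8 px and
  dimmed by factor 0.3.
* **Hemianopsia (H):** gaze-tracking vertical boundary (a head-fixed
  boundary can be pinned via `boundary_x_px`), 2° softness band, same
  dark-blur as T; left side by default.
* **Space-variant blur:** a stack of Gaussian-blurred copies at dyadic
  sigmas (0, 1, 2, 4, 8, 16 px) with per-pixel linear interpolation
  between bracketing levels — a multiresolution scale-space realization
  whose uniform-σ output stays within a mean absolute error of 2
  intensity levels of a direct Gaussian filter. Requested σ = 0 returns
  input pixels bit-identically.

Rendering is cyclopean (one image); per-eye stereo rendering is out of
scope without a headset. When rendering arbitrary images the pixel grid
is mapped onto the default FOV via `image_display`.

## Synthetic traces

The generator emulates a 120 Hz binocular tracker log: unit gaze
directions, validity codes, head pose, blink gaps of 200–400 ms with
validity 0 and eye openness 0.

Saccade kinematics follow a main-sequence law — peak velocity
`V_p = 500·(1 − exp(−A/10°)) °/s` — with a raised-cosine velocity profile
along the great circle between endpoints, so flight duration is `2A/V_p`
(≈58 ms for 8°). Fixations carry isotropic Gaussian jitter (default
σ = 0.05°, of the order of the tracker precision being emulated).

The calibration scenario has five symmetric targets
((0,0), (±12°, ±8°)) held 3 s each; the four inter-target jumps all
exceed 4° so they survive the micro-saccade filter. The real task's
target coordinates are only shown graphically in the source material, so
these are placeholders with the same structure.

Free-viewing archetype traces alternate lognormal fixation durations and
lognormal saccade amplitudes (headings resampled to stay within ±30°/±20°
of center); the fixation-duration median is derived from the target
saccade rate so one fixation + saccade cycle averages 1/rate. Head
orientation is a Gaussian-smoothed random walk whose summed rotation is
scaled exactly to the requested mean angular speed. Condition presets are
*directional only* — they encode the qualitative orderings reported for
these conditions (maculopathy: frequent wide saccades and large head
rotation; hemianopsia: wide saccades with a still head; tunnel: small
saccades), not any published magnitudes, because the underlying human
medians come from recordings that are not available:

| condition | rate (ev/s) | amplitude median (°) | head rotation (°/s) |
|---|---|---|---|
| N | 2.0 | 6.0 | 10 |
| B | 3.0 | 8.0 | 25 |
| H | 2.0 | 8.0 | 4 |
| T | 1.5 | 2.5 | 20 |

What passing tests show — and what they do not: the pipeline recovers the
generator's programmed rate, amplitude, fixation duration and head
rotation within 10% and separates the archetypes with omnibus
significance at n = 18. That validates the *machinery* (geometry,
classification, metrics, statistics) against known truth. It does not
validate the behavioral realism of the archetypes themselves: real
low-vision adaptation includes compensatory strategies (regressive
reading saccades, asymmetric scanning toward a blind hemifield,
pursuit-like drift) that the generator deliberately does not model, and
real tracker noise is neither isotropic nor stationary.

## Problem sizes

Cohort-level analyses in the tests and examples use 18 simulated subjects
× 4 conditions × 60 s traces at 120 Hz, matching a typical repeated-
measures design of this kind; the statistical calibration check uses
2,000 null replicates of an 18 × 4 design. Renderer invariants are
checked on 512 × 512 images (unit tests use 128 × 128).

## Known limitations

* Single designated eye per analysis (the eye label is a parameter); no
  ocular-dominance test, binocular fusion or vergence handling.
* No smooth-pursuit event class; pursuit segments fall into "other".
* The linear pixel↔degree map understates eccentricity near the FOV edge.
* No lens-distortion or interpupillary-distance modeling; rendering is
  not real-time and makes no attempt at shader-level performance.
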