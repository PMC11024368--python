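# gazealter

Gaze-contingent low-vision simulation and oculomotor analysis, as a
hardware-free Python toolkit.

Wearable altered-reality simulators let healthy-sighted observers
experience low-vision conditions — central scotomas with metamorphopsia
(advanced maculopathy), homonymous hemianopsia, and tunnel vision — while
an embedded eye tracker records how their oculomotor and head-movement
behavior adapts. `gazealter` re-implements the computational core of such
a system for desk-scale work: it renders the gaze-contingent impairments
on ordinary images, processes gaze/head logs into saccade and fixation
events and per-trial metrics, compares conditions with nonparametric
repeated-measures statistics, and ships a fully seeded synthetic-trace
generator so every stage can be validated against known ground truth
without a headset. It is aimed at vision scientists and rehabilitation
researchers who want to prototype or audit this kind of pipeline.

## The core computations

**Screen-plane projection.** Each tracker sample carries a gaze origin
`GO` (mm; the z component stores the positive eye-to-screen distance) and
a unit gaze direction `GD`. The point of regard on the screen plane in mm
and pixels is

    G_mx = GDx · (GOz / GDz) + GOx                 (same for y)
    G_px = TPx · G_mx / TMx + TPx / 2

with panel resolution `TPx = 2880` px and screen width `TMx = 119` mm by
default, so a centred gaze (0 mm) lands on pixel 1440. Visual angle uses
the small-angle map `deg = (px − TPx/2) · FOV / TPx` (110° horizontal FOV).

**Event classification.** Samples with tracker validity < 31 are removed.
Angular velocity between consecutive gaze directions is Savitzky–Golay
smoothed; an adaptive peak threshold `PT ← level + 6·scale` of the
sub-threshold samples (median/MAD by default) is iterated to convergence;
threshold crossings seed saccades, extended outward to a `level + 3·scale`
onset/offset criterion. Inter-saccade intervals whose net drift velocity
stays below 2 °/s are fixations. Saccades smaller than 1° are discarded
as putative micro-saccades (a 120 Hz tracker cannot resolve fixational
micro-movements). Events never bridge blink gaps.

**Per-trial metrics and statistics.** Saccade rate (count / task
duration), median saccade amplitude (great-circle angle between onset and
offset gaze, degrees), median fixation duration (ms), and total head
rotation

    HR = Σᵢ √( (αᵢ−αᵢ₊₁)² + (βᵢ−βᵢ₊₁)² + (γᵢ−γᵢ₊₁)² )

over unwrapped Euler angles. Conditions (N healthy / B maculopathy / H
hemianopsia / T tunnel) are compared with a Friedman rank ANOVA and
Nemenyi (Tukey-analogue) post-hoc pairwise tests, with Conover as an
option.

**Rendering.** All impairments are anchored to the current gaze point:
B warps the image with a summed radial force-field deformation map
(sinusoidally modulated in time) and overlays a soft-edged dark-gray
scotoma; H blurs and dims one vertical hemifield with the boundary
tracking gaze; T spares a central aperture and progressively dark-blurs
the periphery via a multiresolution Gaussian blur stack. N is the exact
identity.

## Worked example

```python
from gazealter import synthetic_data as synth, pipeline

arrays, truth = synth.simulate_archetype_arrays(
    synth.ARCHETYPE_PRESETS["B"], duration_s=60.0, seed=42)
m = pipeline.trial_metrics(arrays, "B")
print(m.saccade_rate_eps, m.median_saccade_amplitude_deg,
      m.median_fixation_duration_ms, m.total_head_rotation_deg)
```

prints (against the generator's ground truth in parentheses):

```
saccade rate        2.87 events/s   (generator truth 3.00)
median amplitude    7.54 deg        (truth 7.65)
median fixation     267 ms          (truth 267)
total head rotation 1500 deg        (truth 1500)
```

i.e. the full clean → classify → summarize chain recovers the programmed
maculopathy-archetype behavior to within a few percent.

The same workflow from the shell:

```
$ gazealter generate --scenario calibration --seed 1 --out calib.csv
wrote calib.csv (1844 samples)
$ gazealter calibcheck --log calib.csv --out report.json
PASS: 4 saccades, 5 fixations
$ gazealter end-to-end --subjects 18 --duration 60 --seed 0 --outdir run
saccade_rate_eps: chi2=49.58 p=9.83e-11
median_saccade_amplitude_deg: chi2=48.87 p=1.39e-10
median_fixation_duration_ms: chi2=49.02 p=1.29e-10
total_head_rotation_deg: chi2=54.00 p=1.12e-11
```

The calibration check verifies that a five-target scan trace yields
exactly the four programmed gaze jumps; the end-to-end run simulates
18 subjects under all four condition archetypes, reduces each trial to
its metrics, and confirms the conditions separate (omnibus Friedman
p-values shown; pairwise p-values and the tidy metrics table are written
to `run/`).

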