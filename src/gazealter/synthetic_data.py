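"""Seeded synthetic gaze/head traces with known ground truth.

Two families of traces are generated:

* **Scan scenarios** — a sequence of fixation targets with programmed
  holds and saccadic jumps between them, e.g. the five-target calibration
  task (four jumps, 3 s holds).
* **Behavioral archetype cohorts** — free-viewing traces whose saccade
  rate, amplitude distribution, fixation durations and head-rotation rate
  follow per-condition presets, for testing condition-comparison
  statistics against construction.

Saccades use main-sequence kinematics: peak velocity saturates with
amplitude (V_p = V_max * (1 - exp(-A / A_sat)), V_max = 500 deg/s,
A_sat = 10 deg) and the velocity profile is a raised cosine, so flight
duration is 2 A / V_p.  Fixations carry isotropic Gaussian angular jitter.
Blinks are 200-400 ms gaps with validity 0 (below the cleaning threshold).
Head orientation follows a smoothed random walk whose total rotation is
scaled exactly to the requested mean angular speed.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .event_detection import great_circle_deg
from .io_formats import GazeLogRecord, HeadLogRecord

V_MAX_DPS = 500.0      # main-sequence peak-velocity saturation ceiling
A_SAT_DEG = 10.0       # amplitude scale of the saturation law
EYE_SCREEN_MM = 60.0   # nominal eye-to-screen distance stored as gaze-origin z
FOV_LIMIT_DEG = (30.0, 20.0)  # free-viewing excursion bounds (half-extents)


def main_sequence_peak_velocity(amplitude_deg: float) -> float:
    """Saturating amplitude/peak-velocity law, deg/s."""
    return V_MAX_DPS * (1.0 - np.exp(-amplitude_deg / A_SAT_DEG))


def saccade_duration_s(amplitude_deg: float) -> float:
    """Flight time of a raised-cosine saccade: 2 A / V_peak."""
    return 2.0 * amplitude_deg / main_sequence_peak_velocity(amplitude_deg)


@dataclasses.dataclass
class ScanScenario:
    """Programmed fixation targets (visual angle, deg) with hold durations."""

    fixation_targets: list[tuple[float, float]]
    hold_durations_s: list[float]
    sampling_hz: float = 120.0
    noise_sigma_deg: float = 0.05
    blink_schedule: Optional[list[tuple[float, float]]] = None

    def __post_init__(self):
        if not self.fixation_targets:
            raise ValueError("need at least one fixation target")
        if len(self.hold_durations_s) != len(self.fixation_targets):
            raise ValueError("one hold duration per target required")
        if min(self.hold_durations_s) <= 0 or self.sampling_hz <= 0:
            raise ValueError("hold durations and sampling rate must be positive")

    @property
    def n_jumps(self) -> int:
        return len(self.fixation_targets) - 1

    def jump_amplitudes_deg(self) -> np.ndarray:
        """Great-circle amplitude of each programmed jump."""
        dirs = np.array([direction_from_angles(*t) for t in self.fixation_targets])
        return great_circle_deg(dirs[:-1], dirs[1:])


@dataclasses.dataclass(frozen=True)
class ArchetypeParams:
    """Per-condition behavioral preset for cohort simulation.

    The fixation-duration median, when None, is derived from the target
    saccade rate so that one fixation+saccade cycle averages 1/rate.
    """

    condition: str
    saccade_rate_eps: float
    amplitude_median_deg: float
    amplitude_log_sigma: float = 0.25
    fixation_duration_median_ms: Optional[float] = None
    fixation_log_sigma: float = 0.3
    head_rotation_rate_dps: float = 10.0
    noise_sigma_deg: float = 0.05
    blink_rate_per_min: float = 8.0

    def __post_init__(self):
        if self.saccade_rate_eps <= 0 or self.amplitude_median_deg <= 0:
            raise ValueError("rate and amplitude must be positive")


#: Directional presets encoding the qualitative condition signatures:
#: maculopathy (B) — frequent wide saccades and large head rotation;
#: hemianopsia (H) — wide saccades with a comparatively still head;
#: tunnel (T) — small saccades.  Magnitudes are package conventions.
ARCHETYPE_PRESETS: dict[str, ArchetypeParams] = {
    "N": ArchetypeParams("N", saccade_rate_eps=2.0, amplitude_median_deg=6.0,
                         head_rotation_rate_dps=10.0),
    "B": ArchetypeParams("B", saccade_rate_eps=3.0, amplitude_median_deg=8.0,
                         head_rotation_rate_dps=25.0),
    "H": ArchetypeParams("H", saccade_rate_eps=2.0, amplitude_median_deg=8.0,
                         head_rotation_rate_dps=4.0),
    "T": ArchetypeParams("T", saccade_rate_eps=1.5, amplitude_median_deg=2.5,
                         head_rotation_rate_dps=20.0),
}


@dataclasses.dataclass
class TraceArrays:
    """Columnar form of one trial's gaze + head log."""

    time_s: np.ndarray
    directions: np.ndarray       # (n, 3) unit vectors
    validity: np.ndarray         # (n,) int
    head_orientation_deg: np.ndarray  # (n, 3)
    head_position_m: np.ndarray  # (n, 3)
    eye: str = "left"

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def to_records(self) -> list[tuple[GazeLogRecord, HeadLogRecord]]:
        pairs = []
        for i in range(len(self.time_s)):
            v = int(self.validity[i])
            g = GazeLogRecord(
                time_s=float(self.time_s[i]), eye=self.eye, validity=v,
                openness=1.0 if v >= 31 else 0.0, pupil_diameter_mm=3.5,
                pupil_position=(0.5, 0.5),
                gaze_origin_mm=(0.0, 0.0, EYE_SCREEN_MM),
                gaze_direction_norm=tuple(self.directions[i]),
            )
            h = HeadLogRecord(
                time_s=float(self.time_s[i]),
                position_m=tuple(self.head_position_m[i]),
                orientation_deg=tuple(self.head_orientation_deg[i]),
            )
            pairs.append((g, h))
        return pairs


def direction_from_angles(deg_x: float, deg_y: float) -> np.ndarray:
    """Unit gaze direction for horizontal/vertical visual angles (deg)."""
    d = np.array([np.tan(np.radians(deg_x)), np.tan(np.radians(deg_y)), 1.0])
    return d / np.linalg.norm(d)


def _slerp(d0: np.ndarray, d1: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors for fractions f in [0, 1]."""
    dot = float(np.clip(np.dot(d0, d1), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-9:
        return np.tile(d0, (len(f), 1))
    s = np.sin(omega)
    return (np.sin((1 - f) * omega)[:, None] * d0 + np.sin(f * omega)[:, None] * d1) / s


def _raised_cosine_fraction(n: int) -> np.ndarray:
    """Arc-length fraction travelled at each of n in-flight samples."""
    tau = (np.arange(1, n + 1)) / (n + 1)
    return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)


def _jitter(dirs: np.ndarray, sigma_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic Gaussian angular jitter about each direction."""
    if sigma_deg <= 0:
        return dirs
    sig = np.radians(sigma_deg)
    noise = rng.normal(0.0, sig, size=(len(dirs), 2))
    out = dirs.copy()
    out[:, 0] += noise[:, 0]
    out[:, 1] += noise[:, 1]
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def calibration_scenario(noise_sigma_deg: float = 0.05,
                         blink_schedule=None) -> ScanScenario:
    """Five-target calibration scan: four jumps, 3 s holds per target.

    Target coordinates are symmetric placeholders (the real task shows
    them only graphically); every jump exceeds 4 deg so detected saccades
    survive the micro-saccade filter.
    """
    targets = [(0.0, 0.0), (12.0, 8.0), (-12.0, 8.0), (-12.0, -8.0), (12.0, -8.0)]
    return ScanScenario(fixation_targets=targets,
                        hold_durations_s=[3.0] * len(targets),
                        noise_sigma_deg=noise_sigma_deg,
                        blink_schedule=blink_schedule)


def _head_walk(n: int, fs: float, rate_dps: float,
               rng: np.random.Generator) -> np.ndarray:
    """Smooth random-walk Euler orientations with total rotation rate_dps * T."""
    if rate_dps <= 0 or n < 2:
        return np.zeros((n, 3))
    steps = rng.normal(size=(n - 1, 3))
    steps = gaussian_filter1d(steps, sigma=0.1 * fs, axis=0)
    norms = np.linalg.norm(steps, axis=1).sum()
    target_total = rate_dps * (n - 1) / fs
    steps *= target_total / max(norms, 1e-12)
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def _apply_blinks(validity: np.ndarray, time_s: np.ndarray,
                  schedule: Sequence[tuple[float, float]]) -> None:
    for start, end in schedule:
        validity[(time_s >= start) & (time_s < end)] = 0


def simulate_trace(scenario: ScanScenario, seed: int = 0) -> tuple[
        list[tuple[GazeLogRecord, HeadLogRecord]], list[HeadLogRecord]]:
    """Simulate a scan scenario; returns (gaze-head record pairs, head records)."""
    arrays = simulate_scan_arrays(scenario, seed)
    pairs = arrays.to_records()
    return pairs, [h for _, h in pairs]


def simulate_scan_arrays(scenario: ScanScenario, seed: int = 0) -> TraceArrays:
    """Columnar simulation of a scan scenario (fixed targets, programmed jumps)."""
    rng = np.random.default_rng(seed)
    fs = scenario.sampling_hz
    dirs_targets = [direction_from_angles(*t) for t in scenario.fixation_targets]

    chunks: list[np.ndarray] = []
    for k, (d, hold) in enumerate(zip(dirs_targets, scenario.hold_durations_s)):
        n_hold = max(1, round(hold * fs))
        chunks.append(np.tile(d, (n_hold, 1)))
        if k + 1 < len(dirs_targets):
            amp = float(great_circle_deg(d, dirs_targets[k + 1]))
            n_fly = max(2, round(saccade_duration_s(amp) * fs))
            chunks.append(_slerp(d, dirs_targets[k + 1],
                                 _raised_cosine_fraction(n_fly)))
    dirs = np.vstack(chunks)
    n = len(dirs)
    time_s = np.arange(n) / fs
    dirs = _jitter(dirs, scenario.noise_sigma_deg, rng)
    validity = np.full(n, 31, dtype=int)
    if scenario.blink_schedule:
        _apply_blinks(validity, time_s, scenario.blink_schedule)
    head = np.zeros((n, 3))
    pos = np.tile([0.0, 1.4, 0.0], (n, 1))
    return TraceArrays(time_s=time_s, directions=dirs, validity=validity,
                       head_orientation_deg=head, head_position_m=pos)


def simulate_archetype_arrays(params: ArchetypeParams, duration_s: float,
                              seed: int = 0) -> tuple[TraceArrays, dict]:
    """One free-viewing trace following an archetype preset, plus ground truth.

    Ground truth reports both the programmed parameters and the realized
    values (saccade count/rate, median realized amplitude, median realized
    fixation duration, total head rotation).
    """
    rng = np.random.default_rng(seed)
    fs = 120.0
    mean_amp = params.amplitude_median_deg * np.exp(params.amplitude_log_sigma ** 2 / 2)
    mean_sacc_dur = saccade_duration_s(mean_amp)
    if params.fixation_duration_median_ms is None:
        mean_fix = max(1.0 / params.saccade_rate_eps - mean_sacc_dur, 0.08)
        fix_median_s = mean_fix * np.exp(-params.fixation_log_sigma ** 2 / 2)
    else:
        fix_median_s = params.fixation_duration_median_ms / 1000.0

    pos = np.array([0.0, 0.0])
    chunks: list[np.ndarray] = []
    sacc_spans: list[tuple[int, int]] = []   # sample index spans of saccades
    fix_durations: list[float] = []
    amplitudes: list[float] = []
    n_total = 0
    limit = np.array(FOV_LIMIT_DEG)
    n_target = round(duration_s * fs)

    while n_total < n_target:
        fix_s = float(rng.lognormal(np.log(fix_median_s), params.fixation_log_sigma))
        n_fix = max(5, round(fix_s * fs))
        d0 = direction_from_angles(*pos)
        chunks.append(np.tile(d0, (n_fix, 1)))
        n_total += n_fix
        fix_durations.append(n_fix / fs)
        if n_total >= n_target:
            break
        amp = float(rng.lognormal(np.log(params.amplitude_median_deg),
                                  params.amplitude_log_sigma))
        amp = max(amp, 1.5)
        for _ in range(50):  # resample heading until the landing stays in bounds
            theta = rng.uniform(0, 2 * np.pi)
            new_pos = pos + amp * np.array([np.cos(theta), np.sin(theta)])
            if np.all(np.abs(new_pos) <= limit):
                break
        else:
            new_pos = np.clip(new_pos, -limit, limit)
        d1 = direction_from_angles(*new_pos)
        true_amp = float(great_circle_deg(d0, d1))
        n_fly = max(3, round(saccade_duration_s(true_amp) * fs))
        chunks.append(_slerp(d0, d1, _raised_cosine_fraction(n_fly)))
        sacc_spans.append((n_total, n_total + n_fly))
        amplitudes.append(true_amp)
        n_total += n_fly
        pos = new_pos

    dirs = np.vstack(chunks)[:n_target]
    n = len(dirs)
    time_s = np.arange(n) / fs
    dirs = _jitter(dirs, params.noise_sigma_deg, rng)
    validity = np.full(n, 31, dtype=int)

    blink_schedule = []
    if params.blink_rate_per_min > 0:
        n_blinks = rng.poisson(params.blink_rate_per_min * duration_s / 60.0)
        for _ in range(n_blinks):
            start = rng.uniform(0, duration_s)
            blink_schedule.append((start, start + rng.uniform(0.2, 0.4)))
        _apply_blinks(validity, time_s, blink_schedule)

    head = _head_walk(n, fs, params.head_rotation_rate_dps, rng)
    pos_m = np.tile([0.0, 1.4, 0.0], (n, 1))
    arrays = TraceArrays(time_s=time_s, directions=dirs, validity=validity,
                         head_orientation_deg=head, head_position_m=pos_m)

    amplitudes = [a for a, (s, e) in zip(amplitudes, sacc_spans) if e <= n]
    dur = n / fs
    truth = {
        "condition": params.condition,
        "target_rate_eps": params.saccade_rate_eps,
        "n_saccades": len(amplitudes),
        "realized_rate_eps": len(amplitudes) / dur,
        "median_amplitude_deg": float(np.median(amplitudes)) if amplitudes else None,
        "median_fixation_duration_ms": float(np.median(fix_durations)) * 1000.0,
        "total_head_rotation_deg": params.head_rotation_rate_dps * (n - 1) / fs,
        "duration_s": dur,
        "blink_schedule": blink_schedule,
    }
    return arrays, truth


def simulate_cohort(params: ArchetypeParams, n_subjects: int, duration_s: float,
                    seed: int = 0) -> list[tuple[TraceArrays, dict]]:
    """Per-subject archetype traces with ground truth; subject i uses seed (seed, i)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    out = []
    for i in range(n_subjects):
        sub_seed = int(np.random.default_rng([seed, i]).integers(0, 2 ** 31 - 1))
        out.append(simulate_archetype_arrays(params, duration_s, seed=sub_seed))
    return out
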