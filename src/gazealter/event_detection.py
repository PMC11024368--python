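"""Velocity-based saccade/fixation classification.

The classifier follows the adaptive-threshold family of velocity
algorithms: a data-driven peak threshold is found by iterating
``PT <- mean(v | v < PT) + 6 * sd(v | v < PT)`` to convergence, samples
above PT seed saccades, and each seed is extended outward to a lower
onset/offset threshold (noise mean + 3 sd).  Inter-saccade intervals whose
net angular drift stays below a low velocity criterion (default 2 deg/s)
are fixations; everything else is "other".  Saccades below a minimum
amplitude (default 1 deg) are treated as putative micro-saccades and
removed by :func:`filter_microsaccades`.

Blink gaps (samples removed upstream by validity filtering) split the
trace; no event ever bridges a gap longer than two sample periods.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .io_formats import EventTableRow, make_event


class InsufficientDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class VelocityTrace:
    """Angular speed samples at the midpoints of consecutive gaze samples."""

    time_s: np.ndarray          # midpoint times, length n-1
    speed_dps: np.ndarray       # deg/s, >= 0
    sampling_hz: float = 120.0
    dt_s: np.ndarray | None = None  # underlying sample intervals, length n-1

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.speed_dps = np.asarray(self.speed_dps, dtype=float)
        if self.time_s.shape != self.speed_dps.shape:
            raise ValueError("time_s and speed_dps must have the same length")
        if np.any(self.speed_dps < 0):
            raise ValueError("speed_dps must be non-negative")
        if self.dt_s is None:
            self.dt_s = np.full(self.time_s.shape, 1.0 / self.sampling_hz)
        else:
            self.dt_s = np.asarray(self.dt_s, dtype=float)


@dataclasses.dataclass(frozen=True)
class ClassifierSettings:
    """Tunable thresholds of the adaptive classifier.

    ``fixation_velocity_dps`` (2 deg/s) and ``min_saccade_amplitude_deg``
    (1 deg) are the published criteria; the remaining values are standard
    for the adaptive-threshold algorithm family at 120 Hz and are exposed
    because no single canonical setting exists.
    """

    initial_threshold_dps: float = 200.0
    threshold_convergence_dps: float = 1.0
    fixation_velocity_dps: float = 2.0
    min_saccade_amplitude_deg: float = 1.0
    smoothing_window_samples: int = 5
    peak_threshold_floor_dps: float = 10.0
    min_fixation_duration_s: float = 0.040
    max_iterations: int = 1000
    #: "robust" estimates the sub-threshold noise level with median/MAD,
    #: "moments" with mean/sd (the textbook rule).  The moment estimates are
    #: inflated by saccade flank samples on saccade-dense traces, which can
    #: push the fixed point above the peak velocity of medium saccades.
    threshold_estimator: str = "robust"

    def __post_init__(self):
        if min(self.initial_threshold_dps, self.threshold_convergence_dps,
               self.fixation_velocity_dps, self.min_saccade_amplitude_deg,
               self.smoothing_window_samples) <= 0:
            raise ValueError("all classifier settings must be positive")
        if self.smoothing_window_samples % 2 == 0:
            raise ValueError("smoothing window must be odd")
        if self.fixation_velocity_dps >= self.initial_threshold_dps:
            raise ValueError("fixation velocity must be below the initial threshold")


def great_circle_deg(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Great-circle angle between unit vectors, degrees."""
    dot = np.clip(np.sum(np.asarray(a) * np.asarray(b), axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dot))


def saccade_amplitude(onset_dir, offset_dir) -> float:
    """Saccade amplitude: great-circle angle between onset and offset gaze."""
    return float(great_circle_deg(np.asarray(onset_dir, float),
                                  np.asarray(offset_dir, float)))


def angular_velocity(directions, times, *, sampling_hz: float = 120.0,
                     smoothing_window_samples: int = 5) -> VelocityTrace:
    """Angular speed between consecutive gaze directions, deg/s, smoothed.

    speed[i] = angle(d_i, d_{i+1}) / (t_{i+1} - t_i), assigned to the
    interval midpoint, then Savitzky-Golay smoothed (order 2).  Smoothing
    never runs across blink gaps (> 2 sample periods).
    """
    d = np.asarray(directions, dtype=float)
    t = np.asarray(times, dtype=float)
    if d.ndim != 2 or d.shape[0] != t.shape[0]:
        raise ValueError("directions must be (n, 3) matching times")
    if d.shape[0] < 2:
        raise InsufficientDataError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    step = great_circle_deg(d[:-1], d[1:])
    speed = step / dt
    mid = t[:-1] + dt / 2.0

    win = smoothing_window_samples
    if win > 2:
        gap = dt > 2.0 / sampling_hz
        # smooth each contiguous run independently so blinks don't leak
        bounds = np.flatnonzero(gap)
        starts = np.concatenate(([0], bounds + 1))
        ends = np.concatenate((bounds, [len(speed) - 1])) + 1
        out = speed.copy()
        for s, e in zip(starts, ends):
            seg = speed[s:e]
            if len(seg) >= win:
                out[s:e] = savgol_filter(seg, win, polyorder=2)
        speed = np.maximum(out, 0.0)

    return VelocityTrace(time_s=mid, speed_dps=speed,
                         sampling_hz=sampling_hz, dt_s=dt)


def _noise_level_scale(x: np.ndarray, estimator: str) -> tuple[float, float]:
    if estimator == "moments":
        return float(np.mean(x)), float(np.std(x))
    if estimator == "robust":
        med = float(np.median(x))
        return med, 1.4826 * float(np.median(np.abs(x - med)))
    raise ValueError(f"unknown threshold estimator {estimator!r}")


def adaptive_peak_threshold(speed: np.ndarray, settings: ClassifierSettings) -> tuple[float, float]:
    """Iterate the data-driven peak threshold to convergence.

    ``PT <- level + 6 * scale`` of the sub-PT samples, repeated until the
    change falls below the convergence tolerance; (level, scale) are
    median/MAD by default or mean/sd with the "moments" estimator.
    Returns (peak_threshold, onset_threshold); the onset threshold is the
    noise level + 3 * scale, floored at the fixation velocity criterion.
    """
    pt = settings.initial_threshold_dps
    loc = scale = 0.0
    for _ in range(settings.max_iterations):
        below = speed[speed < pt]
        if below.size < 2:
            break
        loc, scale = _noise_level_scale(below, settings.threshold_estimator)
        new_pt = loc + 6.0 * scale
        if abs(new_pt - pt) < settings.threshold_convergence_dps:
            pt = new_pt
            break
        pt = new_pt
    else:
        raise ConvergenceError(
            f"peak threshold did not converge in {settings.max_iterations} iterations"
        )
    pt = max(pt, settings.peak_threshold_floor_dps)
    onset = max(loc + 3.0 * scale, settings.fixation_velocity_dps)
    return pt, onset


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def classify_events(velocity: VelocityTrace, settings: ClassifierSettings | None = None,
                    *, directions=None, sample_times=None) -> list[EventTableRow]:
    """Classify a velocity trace into saccade / fixation / other events.

    Velocity sample i covers the interval between gaze samples i and i+1.
    Saccades are seeded where the (smoothed) speed exceeds the adaptive
    peak threshold and extended outward to the onset/offset threshold.
    An inter-saccade interval is a fixation when its drift velocity is
    below ``fixation_velocity_dps``: with ``directions`` given, drift is
    the net great-circle displacement over the interval divided by its
    duration (robust to fixational jitter); without directions the median
    sample speed is used instead.  Blink gaps split the trace and are not
    covered by events.
    """
    settings = settings or ClassifierSettings()
    v = velocity.speed_dps
    if v.size == 0:
        raise InsufficientDataError("empty velocity trace")
    dt = velocity.dt_s
    t0 = velocity.time_s - dt / 2.0   # start time of each inter-sample interval
    t1 = velocity.time_s + dt / 2.0   # end time

    gap = dt > 2.0 / velocity.sampling_hz
    pt, onset_thr = adaptive_peak_threshold(v[~gap], settings)

    if directions is not None:
        directions = np.asarray(directions, dtype=float)

    events: list[EventTableRow] = []
    bounds = np.flatnonzero(gap)
    seg_starts = np.concatenate(([0], bounds + 1))
    seg_ends = np.concatenate((bounds, [len(v) - 1])) + 1

    def interval_event(i0: int, i1: int) -> EventTableRow | None:
        """Classify non-saccadic samples [i0, i1) as fixation or other."""
        if i1 <= i0:
            return None
        duration = t1[i1 - 1] - t0[i0]
        if directions is not None:
            drift = saccade_amplitude(directions[i0], directions[i1]) / duration
        else:
            drift = float(np.median(v[i0:i1]))
        kind = "fixation" if (drift < settings.fixation_velocity_dps
                              and duration >= settings.min_fixation_duration_s) \
            else "other"
        return make_event(kind, t0[i0], t1[i1 - 1],
                          amplitude_deg=0.0,
                          peak_velocity_dps=float(np.max(v[i0:i1])))

    for s, e in zip(seg_starts, seg_ends):
        seg_v = v[s:e]
        if seg_v.size == 0:
            continue
        # seed saccades above the peak threshold, extend to the onset threshold
        above = seg_v > pt
        sacc: list[tuple[int, int]] = []
        for r0, r1 in _runs(above):
            while r0 > 0 and seg_v[r0 - 1] > onset_thr:
                r0 -= 1
            while r1 < len(seg_v) and seg_v[r1] > onset_thr:
                r1 += 1
            if sacc and r0 <= sacc[-1][1]:
                sacc[-1] = (sacc[-1][0], max(r1, sacc[-1][1]))
            else:
                sacc.append((r0, r1))

        cursor = s
        for r0, r1 in sacc:
            a0, a1 = s + r0, s + r1
            ev = interval_event(cursor, a0)
            if ev:
                events.append(ev)
            if directions is not None:
                amp = saccade_amplitude(directions[a0], directions[a1])
            else:
                amp = float(np.sum(v[a0:a1] * dt[a0:a1]))
            events.append(make_event("saccade", t0[a0], t1[a1 - 1],
                                     amplitude_deg=amp,
                                     peak_velocity_dps=float(np.max(v[a0:a1]))))
            cursor = a1
        ev = interval_event(cursor, e)
        if ev:
            events.append(ev)

    return events


def filter_microsaccades(events: Sequence[EventTableRow],
                         min_amplitude_deg: float = 1.0) -> list[EventTableRow]:
    """Drop saccades with amplitude strictly below ``min_amplitude_deg``.

    Non-saccade events pass through untouched; order is preserved.  A
    saccade of exactly the minimum amplitude is kept.
    """
    return [ev for ev in events
            if ev.event_type != "saccade" or ev.amplitude_deg >= min_amplitude_deg]


def detect_events(directions, times, settings: ClassifierSettings | None = None,
                  *, sampling_hz: float = 120.0,
                  apply_microsaccade_filter: bool = True) -> list[EventTableRow]:
    """Full detection pipeline on one eye's gaze directions.

    Computes the smoothed angular-velocity trace, classifies events with
    direction-based amplitudes, and (by default) removes putative
    micro-saccades below the minimum amplitude.
    """
    settings = settings or ClassifierSettings()
    vel = angular_velocity(directions, times, sampling_hz=sampling_hz,
                           smoothing_window_samples=settings.smoothing_window_samples)
    events = classify_events(vel, settings, directions=directions, sample_times=times)
    if apply_microsaccade_filter:
        events = filter_microsaccades(events, settings.min_saccade_amplitude_deg)
    return events
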