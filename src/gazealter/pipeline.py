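"""End-to-end wiring: raw logs -> cleaning -> detection -> metrics -> stats.

These helpers mirror the analysis chain applied to each trial: keep the
designated eye, drop invalid samples (validity < 31), classify events with
the adaptive velocity algorithm, remove putative micro-saccades (< 1 deg),
and reduce to per-trial summary metrics; cohorts of trials are then
compared across conditions with a Friedman test and post-hoc pairwise
comparisons.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .event_detection import ClassifierSettings, detect_events
from .gaze_geometry import VALIDITY_THRESHOLD, filter_validity
from .io_formats import EventTableRow, GazeLogRecord, HeadLogRecord
from .oculomotor_metrics import (TaskMetrics, friedman_test, metrics_frame,
                                 summarize_trial)
from .synthetic_data import ARCHETYPE_PRESETS, TraceArrays


def records_to_arrays(pairs: Sequence[tuple[GazeLogRecord, HeadLogRecord]],
                      eye: str = "left") -> TraceArrays:
    """Columnar view of one eye's records (no cleaning applied)."""
    sel = [(g, h) for g, h in pairs if g.eye == eye]
    if not sel:
        raise ValueError(f"no records for eye {eye!r}")
    return TraceArrays(
        time_s=np.array([g.time_s for g, _ in sel]),
        directions=np.array([g.gaze_direction_norm for g, _ in sel]),
        validity=np.array([g.validity for g, _ in sel]),
        head_orientation_deg=np.array([h.orientation_deg for _, h in sel]),
        head_position_m=np.array([h.position_m for _, h in sel]),
        eye=eye,
    )


def detect_from_arrays(arrays: TraceArrays,
                       settings: ClassifierSettings | None = None,
                       apply_microsaccade_filter: bool = True) -> list[EventTableRow]:
    """Validity-clean a columnar trace and run the detection pipeline.

    Invalid samples (validity < 31) are dropped before velocity
    computation; the resulting temporal gaps split the trace so no event
    bridges a blink.
    """
    mask = arrays.validity >= VALIDITY_THRESHOLD
    if mask.sum() < 2:
        raise ValueError("fewer than 2 valid samples after cleaning")
    return detect_events(arrays.directions[mask], arrays.time_s[mask],
                         settings, apply_microsaccade_filter=apply_microsaccade_filter)


def detect_from_records(pairs, eye: str = "left",
                        settings: ClassifierSettings | None = None) -> list[EventTableRow]:
    return detect_from_arrays(records_to_arrays(pairs, eye), settings)


def trial_metrics(arrays: TraceArrays, condition: str,
                  settings: ClassifierSettings | None = None) -> TaskMetrics:
    """Full per-trial reduction: clean, detect, filter, summarize."""
    events = detect_from_arrays(arrays, settings)
    return summarize_trial(events, arrays.head_orientation_deg, condition,
                           task_duration_s=arrays.duration_s)


def calibration_check(pairs_or_arrays, expected_jumps: int = 4,
                      settings: ClassifierSettings | None = None,
                      eye: str = "left") -> dict:
    """Scan-path verification: does the cleaned trace show the programmed jumps?

    Returns a report with the detected saccade/fixation counts and a
    pass/fail flag (pass when the saccade count equals ``expected_jumps``
    and the trace holds at least ``expected_jumps + 1`` fixations).
    """
    if isinstance(pairs_or_arrays, TraceArrays):
        arrays = pairs_or_arrays
    else:
        arrays = records_to_arrays(pairs_or_arrays, eye)
    events = detect_from_arrays(arrays, settings)
    n_sacc = sum(e.event_type == "saccade" for e in events)
    n_fix = sum(e.event_type == "fixation" for e in events)
    passed = (n_sacc == expected_jumps) and (n_fix >= expected_jumps + 1)
    return {
        "pass": bool(passed),
        "expected_jumps": int(expected_jumps),
        "detected_saccades": int(n_sacc),
        "detected_fixations": int(n_fix),
        "eye": arrays.eye,
    }


@dataclasses.dataclass
class CohortResult:
    """Tidy per-subject metrics plus condition comparisons per measure."""

    metrics: pd.DataFrame
    comparisons: dict
    truths: dict


MEASURES = {
    "saccade_rate_eps": "saccade rate (events/s)",
    "median_saccade_amplitude_deg": "median saccade amplitude (deg)",
    "median_fixation_duration_ms": "median fixation duration (ms)",
    "total_head_rotation_deg": "total head rotation (deg)",
}


def run_cohort_comparison(n_subjects: int = 18, duration_s: float = 60.0,
                          seed: int = 0,
                          conditions: Sequence[str] = ("N", "B", "H", "T"),
                          settings: ClassifierSettings | None = None,
                          posthoc: str = "nemenyi") -> CohortResult:
    """Simulate archetype cohorts, run the analysis chain, compare conditions.

    Each condition's cohort is generated from its preset with a
    condition-specific seed stream; the same subject index shares no
    randomness across conditions (independent repeated measures under the
    null of the generator presets being equal).
    """
    rows: list[TaskMetrics] = []
    subject_ids: list[int] = []
    truths: dict[str, list[dict]] = {}
    for c_idx, cond in enumerate(conditions):
        preset = ARCHETYPE_PRESETS[cond]
        cohort = synth.simulate_cohort(preset, n_subjects, duration_s,
                                       seed=seed * 131 + c_idx)
        truths[cond] = [t for _, t in cohort]
        for s_idx, (arrays, _) in enumerate(cohort):
            rows.append(trial_metrics(arrays, cond, settings))
            subject_ids.append(s_idx)

    frame = metrics_frame(rows)
    frame.insert(0, "subject", subject_ids)

    comparisons = {}
    for measure in MEASURES:
        wide = frame.pivot(index="subject", columns="condition", values=measure)
        wide = wide[list(conditions)]
        if wide.isna().any().any():
            continue
        comp = friedman_test(wide.to_numpy(), conditions=tuple(conditions),
                             posthoc=posthoc)
        comparisons[measure] = {
            "statistic": comp.statistic,
            "p_value": comp.p_value,
            "conditions": list(comp.conditions),
            "pairwise_p": comp.pairwise.tolist(),
        }
    return CohortResult(metrics=frame, comparisons=comparisons, truths=truths)
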