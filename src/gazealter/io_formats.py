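"""On-disk formats for gaze/head logs, event tables, and impairment configs.

The toolkit stores one trial per CSV file, in long format: one row per
(timestamp, eye) pair, with the head pose repeated on each row.  Event
tables are TSV.  Impairment configs are JSON.  All text is UTF-8 with "."
as the decimal separator; times are float seconds since trial start.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required column order of the gaze-head log CSV dialect.
GAZE_LOG_COLUMNS = [
    "time_s", "eye", "validity", "openness", "pupil_diameter_mm",
    "pupil_x", "pupil_y",
    "gox_mm", "goy_mm", "goz_mm",
    "gdx", "gdy", "gdz",
    "head_x_m", "head_y_m", "head_z_m",
    "head_alpha_deg", "head_beta_deg", "head_gamma_deg",
]

EVENT_TABLE_COLUMNS = [
    "event_type", "onset_s", "offset_s", "amplitude_deg",
    "peak_velocity_dps", "duration_ms",
]

#: Direction vectors may deviate from unit norm by this much before erroring.
DIRECTION_NORM_TOL = 1e-3


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class OrderingError(FormatError):
    """Timestamps in a log file are not non-decreasing."""


class InvariantError(ValueError):
    """A record violates a domain-type invariant."""


@dataclasses.dataclass(frozen=True)
class GazeLogRecord:
    """One per-eye eye-tracker sample.

    ``gaze_origin_mm`` is the eye position relative to the screen plane:
    x/y in the plane, z the positive eye-to-screen distance (the eye sits
    at z = -goz with +z pointing through the screen).
    ``gaze_direction_norm`` is a unit vector (re-normalized on load).
    """

    time_s: float
    eye: str
    validity: int
    openness: float
    pupil_diameter_mm: float
    pupil_position: tuple[float, float]
    gaze_origin_mm: tuple[float, float, float]
    gaze_direction_norm: tuple[float, float, float]


@dataclasses.dataclass(frozen=True)
class HeadLogRecord:
    """Head pose: position in metres, intrinsic X-Y-Z Euler angles in degrees."""

    time_s: float
    position_m: tuple[float, float, float]
    orientation_deg: tuple[float, float, float]


@dataclasses.dataclass(frozen=True)
class EventTableRow:
    """One classified oculomotor event (saccade, fixation, or other)."""

    event_type: str
    onset_s: float
    offset_s: float
    amplitude_deg: float
    peak_velocity_dps: float
    duration_ms: float

    def validate(self) -> None:
        if self.event_type not in ("saccade", "fixation", "other"):
            raise InvariantError(f"unknown event_type {self.event_type!r}")
        if not self.offset_s > self.onset_s:
            raise InvariantError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )
        if abs(self.duration_ms - (self.offset_s - self.onset_s) * 1000.0) > 0.5:
            raise InvariantError("duration_ms inconsistent with onset/offset")
        if self.amplitude_deg < 0:
            raise InvariantError("amplitude_deg must be >= 0")


def make_event(event_type: str, onset_s: float, offset_s: float,
               amplitude_deg: float = 0.0,
               peak_velocity_dps: float = 0.0) -> EventTableRow:
    """Build an EventTableRow with duration derived from onset/offset."""
    row = EventTableRow(
        event_type=event_type, onset_s=float(onset_s), offset_s=float(offset_s),
        amplitude_deg=float(amplitude_deg),
        peak_velocity_dps=float(peak_velocity_dps),
        duration_ms=(float(offset_s) - float(onset_s)) * 1000.0,
    )
    row.validate()
    return row


def _row_to_records(row: pd.Series) -> tuple[GazeLogRecord, HeadLogRecord]:
    d = np.array([row["gdx"], row["gdy"], row["gdz"]], dtype=float)
    norm = float(np.linalg.norm(d))
    if not np.isfinite(norm) or abs(norm - 1.0) > DIRECTION_NORM_TOL:
        raise InvariantError(
            f"gaze direction norm {norm:.6f} deviates from 1 by more than "
            f"{DIRECTION_NORM_TOL}"
        )
    d = d / norm
    gaze = GazeLogRecord(
        time_s=float(row["time_s"]),
        eye=str(row["eye"]),
        validity=int(row["validity"]),
        openness=float(row["openness"]),
        pupil_diameter_mm=float(row["pupil_diameter_mm"]),
        pupil_position=(float(row["pupil_x"]), float(row["pupil_y"])),
        gaze_origin_mm=(float(row["gox_mm"]), float(row["goy_mm"]),
                        float(row["goz_mm"])),
        gaze_direction_norm=(float(d[0]), float(d[1]), float(d[2])),
    )
    head = HeadLogRecord(
        time_s=float(row["time_s"]),
        position_m=(float(row["head_x_m"]), float(row["head_y_m"]),
                    float(row["head_z_m"])),
        orientation_deg=(float(row["head_alpha_deg"]), float(row["head_beta_deg"]),
                         float(row["head_gamma_deg"])),
    )
    if not (0.0 <= gaze.openness <= 1.0):
        raise InvariantError(f"openness {gaze.openness} outside [0, 1]")
    return gaze, head


def read_gaze_log(path, *, return_bad_rows: bool = False):
    """Read a gaze-head log CSV.

    Returns a list of ``(GazeLogRecord, HeadLogRecord)`` pairs in file
    order.  Structural problems (missing columns, non-monotone time) raise;
    individually malformed data rows are skipped, logged with their
    1-based physical line number, and returned when ``return_bad_rows``.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"eye": str})
    missing = [c for c in GAZE_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    pairs: list[tuple[GazeLogRecord, HeadLogRecord]] = []
    bad: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is physical line 1
        try:
            pairs.append(_row_to_records(row))
        except (InvariantError, ValueError, TypeError) as exc:
            logger.warning("%s line %d: %s", path, line_no, exc)
            bad.append((line_no, str(exc)))

    times = [g.time_s for g, _ in pairs]
    if any(b < a for a, b in zip(times, times[1:])):
        raise OrderingError(f"{path}: time_s is not non-decreasing")
    if return_bad_rows:
        return pairs, bad
    return pairs


def write_gaze_log(pairs: Sequence[tuple[GazeLogRecord, HeadLogRecord]], path) -> None:
    """Write ``(gaze, head)`` pairs to the CSV dialect read by read_gaze_log."""
    rows = []
    for g, h in pairs:
        rows.append({
            "time_s": g.time_s, "eye": g.eye, "validity": g.validity,
            "openness": g.openness, "pupil_diameter_mm": g.pupil_diameter_mm,
            "pupil_x": g.pupil_position[0], "pupil_y": g.pupil_position[1],
            "gox_mm": g.gaze_origin_mm[0], "goy_mm": g.gaze_origin_mm[1],
            "goz_mm": g.gaze_origin_mm[2],
            "gdx": g.gaze_direction_norm[0], "gdy": g.gaze_direction_norm[1],
            "gdz": g.gaze_direction_norm[2],
            "head_x_m": h.position_m[0], "head_y_m": h.position_m[1],
            "head_z_m": h.position_m[2],
            "head_alpha_deg": h.orientation_deg[0],
            "head_beta_deg": h.orientation_deg[1],
            "head_gamma_deg": h.orientation_deg[2],
        })
    frame = pd.DataFrame(rows, columns=GAZE_LOG_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.9g")


def write_event_table(events: Sequence[EventTableRow], path) -> None:
    """Write events as a TSV table; rows are validated before anything is written."""
    for ev in events:
        ev.validate()
    frame = pd.DataFrame(
        [dataclasses.asdict(ev) for ev in events], columns=EVENT_TABLE_COLUMNS
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_event_table(path) -> list[EventTableRow]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    events = []
    for _, row in frame.iterrows():
        ev = EventTableRow(
            event_type=str(row["event_type"]),
            onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
            amplitude_deg=float(row["amplitude_deg"]),
            peak_velocity_dps=float(row["peak_velocity_dps"]),
            duration_ms=float(row["duration_ms"]),
        )
        ev.validate()
        events.append(ev)
    return events


def load_condition_config(path):
    """Load an impairment-condition JSON config into a ConditionConfig.

    The document must carry a ``condition`` tag in {N, B, H, T}; all other
    fields are optional and take documented defaults.
    """
    from .lowvision_render import ConditionConfig

    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return ConditionConfig.model_validate(doc)


def save_condition_config(config, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(config.model_dump_json(indent=2))
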