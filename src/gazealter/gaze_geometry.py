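"""Coordinate pipeline: validity cleaning, gaze ray -> screen mm -> pixels
-> visual angle, and the combined eye+head gaze-contingent vector.

Conventions (used everywhere in the toolkit):

* Eye space: +x right, +y up, +z forward through the screen.
* The screen plane sits at z = 0; a record's gaze origin stores the
  positive eye-to-screen distance in its z component, i.e. the eye is at
  (GOx, GOy, -GOz).  With that convention the mm conversion

      G_mx = GDx * (GOz / GDz) + GOx

  is exactly the ray-plane intersection of origin + t * direction with z=0.
* Pixels are 0-based, origin top-left, y down; so the pixel conversion
  flips the sign of y_mm.
* Head rotation is an intrinsic X->Y->Z Euler composition in degrees.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import GazeLogRecord, HeadLogRecord

logger = logging.getLogger(__name__)

#: Validity codes below this are discarded, following the tracker convention
#: that 31 (all five validity bits set) marks a fully valid sample.
VALIDITY_THRESHOLD = 31


class DegenerateRayError(ValueError):
    """Gaze ray is (numerically) parallel to the screen plane."""


@dataclasses.dataclass(frozen=True)
class DisplayModel:
    """Headset display geometry.

    Defaults describe the HTC Vive Pro Eye panel: 2880 x 1600 px across
    both eyes, 119 mm wide, 110 deg horizontal FOV.  The vertical screen
    size and FOV are not published for this headset; the defaults below
    (height scaled by the pixel aspect ratio, 90 deg vertical FOV) are
    documented assumptions.
    """

    resolution_px: tuple[int, int] = (2880, 1600)
    screen_size_mm: tuple[float, float] = (119.0, 119.0 * 1600 / 2880)
    fov_deg: tuple[float, float] = (110.0, 90.0)

    def __post_init__(self):
        if min(self.resolution_px) <= 0 or min(self.screen_size_mm) <= 0 \
                or min(self.fov_deg) <= 0:
            raise ValueError("display parameters must be strictly positive")

    @property
    def center_px(self) -> tuple[float, float]:
        return self.resolution_px[0] / 2.0, self.resolution_px[1] / 2.0


@dataclasses.dataclass(frozen=True)
class MmGazePoint:
    """Gaze position on the screen plane in millimetres (0 = screen center)."""

    x_mm: float
    y_mm: float


@dataclasses.dataclass(frozen=True)
class PixelGazePoint:
    """Gaze position in pixels; may lie outside the panel when gaze leaves it."""

    x_px: float
    y_px: float

    def on_screen(self, display: DisplayModel) -> bool:
        return (0 <= self.x_px < display.resolution_px[0]
                and 0 <= self.y_px < display.resolution_px[1])


def filter_validity(records: Sequence[GazeLogRecord],
                    threshold: int = VALIDITY_THRESHOLD) -> list[GazeLogRecord]:
    """Drop samples whose validity code is below ``threshold`` (default 31).

    Order is preserved; the number of removed samples is logged.
    """
    kept = [r for r in records if r.validity >= threshold]
    removed = len(records) - len(kept)
    if removed:
        logger.info("validity filter removed %d of %d samples", removed, len(records))
    return kept


def gaze_to_mm(record: GazeLogRecord) -> MmGazePoint:
    """Project the gaze ray onto the screen plane, in millimetres.

    x_mm = GDx * (GOz / GDz) + GOx, and the same with y components.
    Raises DegenerateRayError when the ray is parallel to the screen
    (|GDz| <= 1e-6).
    """
    gdx, gdy, gdz = record.gaze_direction_norm
    gox, goy, goz = record.gaze_origin_mm
    if abs(gdz) <= 1e-6:
        raise DegenerateRayError(
            f"gaze direction z-component {gdz} too small: ray parallel to screen"
        )
    scale = goz / gdz
    return MmGazePoint(x_mm=gdx * scale + gox, y_mm=gdy * scale + goy)


def mm_to_pixels(point: MmGazePoint, display: DisplayModel | None = None,
                 *, flip_x: bool = False) -> PixelGazePoint:
    """Convert screen-plane millimetres to pixels.

    x_px = TPx * x_mm / TMx + TPx/2: mm 0 maps to the horizontal midpoint
    and the physical edges +-TMx/2 map to pixels TPx / 0.  The y axis flips
    sign (pixel y grows downward, mm y grows upward).  ``flip_x`` mirrors
    the x axis for trackers with a left-handed screen convention.
    """
    display = display or DisplayModel()
    tpx, tpy = display.resolution_px
    tmx, tmy = display.screen_size_mm
    x_mm = -point.x_mm if flip_x else point.x_mm
    return PixelGazePoint(
        x_px=tpx * x_mm / tmx + tpx / 2.0,
        y_px=tpy * (-point.y_mm) / tmy + tpy / 2.0,
    )


def pixels_to_mm(point: PixelGazePoint, display: DisplayModel | None = None) -> MmGazePoint:
    display = display or DisplayModel()
    tpx, tpy = display.resolution_px
    tmx, tmy = display.screen_size_mm
    return MmGazePoint(
        x_mm=(point.x_px - tpx / 2.0) * tmx / tpx,
        y_mm=-(point.y_px - tpy / 2.0) * tmy / tpy,
    )


def pixels_to_degrees(point: PixelGazePoint,
                      display: DisplayModel | None = None) -> tuple[float, float]:
    """Small-angle linear map from pixels to visual angle in degrees.

    deg = (px - TP/2) * (fov / TP) per axis; the screen center is (0, 0)
    and a full half-panel is half the FOV.  Positive deg_y points down,
    matching the pixel convention.
    """
    display = display or DisplayModel()
    tpx, tpy = display.resolution_px
    fx, fy = display.fov_deg
    return ((point.x_px - tpx / 2.0) * fx / tpx,
            (point.y_px - tpy / 2.0) * fy / tpy)


def degrees_to_pixels(deg: tuple[float, float],
                      display: DisplayModel | None = None) -> PixelGazePoint:
    """Inverse of :func:`pixels_to_degrees` (exact up to float rounding)."""
    display = display or DisplayModel()
    tpx, tpy = display.resolution_px
    fx, fy = display.fov_deg
    return PixelGazePoint(x_px=deg[0] * tpx / fx + tpx / 2.0,
                          y_px=deg[1] * tpy / fy + tpy / 2.0)


def head_rotation_matrix(orientation_deg: tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix for intrinsic X->Y->Z Euler angles in degrees."""
    return Rotation.from_euler("XYZ", orientation_deg, degrees=True).as_matrix()


def contingent_gaze_point(record: GazeLogRecord, head: HeadLogRecord,
                          display: DisplayModel | None = None) -> PixelGazePoint:
    """Gaze-contingent screen point from the combined eye+head vector.

    The eye-in-head gaze direction is rotated by the head orientation and
    the rotated ray is pushed through the mm and pixel conversions.  With
    zero head rotation this equals the eye-only pipeline.  Points that
    leave the panel are returned unclamped (check ``on_screen``).
    """
    display = display or DisplayModel()
    rot = head_rotation_matrix(head.orientation_deg)
    d = rot @ np.asarray(record.gaze_direction_norm, dtype=float)
    if d[2] <= 1e-6:
        # parallel to or pointing away from the screen: no forward intersection
        raise DegenerateRayError(
            f"rotated gaze ray (z component {d[2]:.3g}) does not hit the screen ahead"
        )
    rotated = dataclasses.replace(record, gaze_direction_norm=tuple(d))
    return mm_to_pixels(gaze_to_mm(rotated), display)
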