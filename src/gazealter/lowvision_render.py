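"""Gaze-contingent low-vision impairment rendering on raster images.

Three impairments are simulated, each anchored to the current gaze point:

* **B — binocular maculopathy**: a soft-edged dark-gray central scotoma
  over the fovea, preceded by a metamorphopsia warp (straight lines appear
  wavy) driven by a gaze-contingent deformation field built by summing
  radial Gaussian force-field sources, with sinusoidal temporal modulation.
* **H — homonymous hemianopsia**: one vertical hemifield (default left)
  blurred and dimmed, with the boundary tracking the gaze x-coordinate.
* **T — tubular (tunnel) vision**: a clear central aperture around gaze,
  periphery progressively blurred (multiresolution blur stack) and dimmed
  toward black with eccentricity.
* **N — healthy sight**: exact identity.

All masks are computed in visual-angle units via the small-angle
pixel<->degree map, so radii are specified in degrees.  Rendering is fully
deterministic given (image, gaze, config, t, seed).  No quantitative
rendering parameters are published for the conditions being emulated; all
numeric defaults here are documented package conventions.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy import ndimage

from .gaze_geometry import DisplayModel, PixelGazePoint


class DeformationParams(BaseModel):
    """Force-field deformation (metamorphopsia) parameters."""

    n_sources: int = Field(default=8, ge=0)
    source_amplitude_px: float = Field(default=6.0, ge=0)
    source_sigma_px: float = Field(default=30.0, gt=0)
    #: ring on which sources sit; None derives 0.6 * scotoma radius at render time
    ring_radius_px: Optional[float] = Field(default=None, ge=0)
    modulation_depth: float = Field(default=0.3, ge=0, le=1)
    modulation_period_s: float = Field(default=2.0, gt=0)

    @property
    def max_offset_px(self) -> float:
        """Analytic bound on the offset magnitude anywhere in the field."""
        return self.n_sources * self.source_amplitude_px * (1 + self.modulation_depth)


class ConditionConfig(BaseModel):
    """Parameters of one simulated impairment condition.

    ``condition`` is N (healthy), B (maculopathy), H (hemianopsia) or
    T (tunnel vision); only the fields relevant to the chosen condition
    are used.
    """

    condition: Literal["N", "B", "H", "T"]
    scotoma_radius_deg: float = Field(default=10.0, ge=0)
    scotoma_gray_level: int = Field(default=64, ge=0, le=255)
    scotoma_softness_deg: float = Field(default=2.0, ge=0)
    deformation: DeformationParams = Field(default_factory=DeformationParams)
    hemifield_side: Literal["left", "right"] = "left"
    boundary_softness_deg: float = Field(default=2.0, ge=0)
    aperture_radius_deg: float = Field(default=10.0, ge=0)
    aperture_softness_deg: float = Field(default=2.0, ge=0)
    blur_max_sigma_px: float = Field(default=8.0, ge=0)
    dim_factor: float = Field(default=0.3, ge=0, le=1)

    @field_validator("condition", mode="before")
    @classmethod
    def _upper(cls, v):
        return v.upper() if isinstance(v, str) else v


def image_display(shape, fov_deg: tuple[float, float] = (110.0, 90.0)) -> DisplayModel:
    """DisplayModel whose pixel grid is the given image, spanning ``fov_deg``.

    Used when rendering on arbitrary images rather than the native HMD
    panel: the image width maps to the horizontal FOV.
    """
    h, w = shape[:2]
    return DisplayModel(resolution_px=(w, h),
                        screen_size_mm=(119.0, 119.0 * h / w),
                        fov_deg=fov_deg)


def _as_float(image: np.ndarray) -> tuple[np.ndarray, np.dtype]:
    img = np.asarray(image)
    return img.astype(np.float64), img.dtype


def _restore(img: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(np.rint(img), info.min, info.max).astype(dtype)
    return img.astype(dtype)


def _deg_per_px(display: DisplayModel) -> tuple[float, float]:
    return (display.fov_deg[0] / display.resolution_px[0],
            display.fov_deg[1] / display.resolution_px[1])


def _eccentricity_deg(shape, gaze: PixelGazePoint, display: DisplayModel) -> np.ndarray:
    """Per-pixel angular distance (deg) from the gaze point."""
    h, w = shape[:2]
    sx, sy = _deg_per_px(display)
    ys, xs = np.mgrid[0:h, 0:w]
    return np.hypot((xs - gaze.x_px) * sx, (ys - gaze.y_px) * sy)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 ramp 0->1 on [0, 1]; exactly 0/1 outside."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def build_deformation_field(shape, gaze: PixelGazePoint, params: DeformationParams,
                            t: float = 0.0, seed: int = 0) -> np.ndarray:
    """Sum-of-force-field pixel offset map, shape (h, w, 2) as (dy, dx).

    Sources are ringed around the gaze point (seeded angular jitter and
    per-source amplitude jitter), each pushing pixels radially away from
    itself with Gaussian falloff.  All offsets are scaled by the periodic
    factor ``1 + depth * sin(2 pi t / period)``.  The field depends on
    pixel position only through (pixel - gaze), so translating the gaze
    translates the field.
    """
    h, w = shape[:2]
    field = np.zeros((h, w, 2), dtype=np.float64)
    if params.n_sources == 0 or params.source_amplitude_px == 0:
        return field
    rng = np.random.default_rng(seed)
    n = params.n_sources
    ring = 40.0 if params.ring_radius_px is None else params.ring_radius_px
    angles = (np.arange(n) * 2 * np.pi / n
              + rng.uniform(-np.pi / n, np.pi / n, size=n))
    amps = params.source_amplitude_px * rng.uniform(0.5, 1.0, size=n)

    ys, xs = np.mgrid[0:h, 0:w]
    rel_x = xs - gaze.x_px
    rel_y = ys - gaze.y_px
    sig2 = 2.0 * params.source_sigma_px ** 2
    for ang, amp in zip(angles, amps):
        src_x = ring * np.cos(ang)
        src_y = ring * np.sin(ang)
        dx = rel_x - src_x
        dy = rel_y - src_y
        r = np.hypot(dx, dy)
        mag = amp * np.exp(-(r ** 2) / sig2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r > 0, dx / r, 0.0)
            uy = np.where(r > 0, dy / r, 0.0)
        field[..., 1] += mag * ux
        field[..., 0] += mag * uy

    field *= 1.0 + params.modulation_depth * np.sin(2 * np.pi * t / params.modulation_period_s)
    return field


def apply_metamorphopsia(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Warp the image: output pixel p samples input at p + offset(p), bilinear."""
    img, dtype = _as_float(image)
    if field.shape[:2] != img.shape[:2]:
        raise ValueError("deformation field extent does not match image")
    h, w = img.shape[:2]
    ys, xs = np.mgrid[0:h, 0:w]
    sy = ys + field[..., 0]
    sx = xs + field[..., 1]
    if img.ndim == 2:
        out = ndimage.map_coordinates(img, [sy, sx], order=1, mode="nearest")
    else:
        out = np.stack([
            ndimage.map_coordinates(img[..., c], [sy, sx], order=1, mode="nearest")
            for c in range(img.shape[2])
        ], axis=-1)
    return _restore(out, dtype)


def apply_scotoma(image: np.ndarray, gaze: PixelGazePoint, config: ConditionConfig,
                  display: DisplayModel | None = None) -> np.ndarray:
    """Soft-edged dark-gray disc over the central visual field around gaze."""
    display = display or image_display(image.shape)
    img, dtype = _as_float(image)
    ecc = _eccentricity_deg(img.shape, gaze, display)
    soft = max(config.scotoma_softness_deg, 1e-9)
    # weight 1 inside the radius, smooth fall to exactly 0 at radius+softness
    wgt = 1.0 - _smoothstep((ecc - config.scotoma_radius_deg) / soft)
    if img.ndim == 3:
        wgt = wgt[..., None]
    out = np.where(wgt > 0, (1.0 - wgt) * img + wgt * config.scotoma_gray_level, img)
    return _restore(out, dtype)


def pyramid_blur(image: np.ndarray, sigma_map: np.ndarray,
                 level_sigmas: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
                 ) -> np.ndarray:
    """Space-variant blur via a multiresolution Gaussian blur stack.

    A stack of progressively blurred copies of the image is built at the
    dyadic sigma levels; each output pixel linearly interpolates between
    the two levels bracketing its requested sigma.  A sigma map of zeros
    returns the input exactly; sigmas beyond the top level saturate.
    """
    img, dtype = _as_float(image)
    sig = np.asarray(sigma_map, dtype=np.float64)
    if sig.shape != img.shape[:2]:
        raise ValueError("sigma_map extent does not match image")
    if np.any(sig < 0):
        raise ValueError("sigma_map must be non-negative")
    if not np.any(sig > 0):
        return _restore(img, dtype)

    if img.ndim == 3:
        out = np.stack([_pyramid_blur_gray(img[..., c], sig, level_sigmas)
                        for c in range(img.shape[2])], axis=-1)
    else:
        out = _pyramid_blur_gray(img, sig, level_sigmas)
    return _restore(out, dtype)


def _pyramid_blur_gray(img: np.ndarray, sig: np.ndarray,
                       level_sigmas: tuple[float, ...]) -> np.ndarray:
    sigmas = np.asarray(level_sigmas, dtype=float)
    stack = np.stack([img] + [ndimage.gaussian_filter(img, s) for s in sigmas[1:]])
    sig_c = np.clip(sig, sigmas[0], sigmas[-1])
    idx = np.clip(np.searchsorted(sigmas, sig_c, side="right") - 1, 0, len(sigmas) - 2)
    lo, hi = sigmas[idx], sigmas[idx + 1]
    frac = (sig_c - lo) / (hi - lo)
    h, w = img.shape
    ys, xs = np.mgrid[0:h, 0:w]
    out = stack[idx, ys, xs] * (1.0 - frac) + stack[idx + 1, ys, xs] * frac
    zero = sig == 0  # requested sigma 0 must stay bit-identical
    out[zero] = img[zero]
    return out


def _dark_blur(img: np.ndarray, wgt: np.ndarray, config: ConditionConfig) -> np.ndarray:
    """Blend toward a blurred + dimmed copy with per-pixel weight in [0, 1]."""
    sigma_map = wgt * config.blur_max_sigma_px
    blurred = pyramid_blur(img, sigma_map).astype(np.float64)
    dim = 1.0 - wgt * (1.0 - config.dim_factor)
    w3 = wgt[..., None] if img.ndim == 3 else wgt
    d3 = dim[..., None] if img.ndim == 3 else dim
    return np.where(w3 > 0, (1.0 - w3) * img + w3 * d3 * blurred, img)


def apply_tunnel(image: np.ndarray, gaze: PixelGazePoint, config: ConditionConfig,
                 display: DisplayModel | None = None) -> np.ndarray:
    """Clear central aperture around gaze; periphery dark-blurred."""
    display = display or image_display(image.shape)
    img, dtype = _as_float(image)
    ecc = _eccentricity_deg(img.shape, gaze, display)
    soft = max(config.aperture_softness_deg, 1e-9)
    wgt = _smoothstep((ecc - config.aperture_radius_deg) / soft)
    return _restore(_dark_blur(img, wgt, config), dtype)


def apply_hemianopsia(image: np.ndarray, gaze: PixelGazePoint, config: ConditionConfig,
                      display: DisplayModel | None = None,
                      boundary_x_px: Optional[float] = None) -> np.ndarray:
    """Blur + dim one vertical hemifield; boundary tracks the gaze x.

    ``boundary_x_px`` overrides the gaze-fixed boundary for a head-fixed
    variant.  The intact hemifield (beyond the softness band) is returned
    bit-identical.
    """
    display = display or image_display(image.shape)
    img, dtype = _as_float(image)
    bx = gaze.x_px if boundary_x_px is None else boundary_x_px
    sx, _ = _deg_per_px(display)
    band_px = max(config.boundary_softness_deg / sx, 1e-9)
    h, w = img.shape[:2]
    xs = np.arange(w, dtype=np.float64)
    if config.hemifield_side == "left":
        ramp = _smoothstep((bx + band_px / 2.0 - xs) / band_px)
    else:
        ramp = _smoothstep((xs - bx + band_px / 2.0) / band_px)
    wgt = np.broadcast_to(ramp[None, :], (h, w)).copy()
    return _restore(_dark_blur(img, wgt, config), dtype)


def render_condition(image: np.ndarray, gaze: PixelGazePoint, config: ConditionConfig,
                     display: DisplayModel | None = None, t: float = 0.0,
                     seed: int = 0) -> np.ndarray:
    """Dispatch to the condition's operator chain.

    N: identity.  B: metamorphopsia warp then scotoma.  H: hemifield
    dark-blur.  T: tunnel aperture.  Deterministic given all arguments.
    """
    display = display or image_display(image.shape)
    cond = config.condition
    if cond == "N":
        return np.asarray(image).copy()
    if cond == "B":
        sx, _ = _deg_per_px(display)
        params = config.deformation
        if params.ring_radius_px is None:
            params = params.model_copy(
                update={"ring_radius_px": 0.6 * config.scotoma_radius_deg / sx})
        field = build_deformation_field(image.shape, gaze, params, t=t, seed=seed)
        warped = apply_metamorphopsia(image, field)
        return apply_scotoma(warped, gaze, config, display)
    if cond == "H":
        return apply_hemianopsia(image, gaze, config, display)
    if cond == "T":
        return apply_tunnel(image, gaze, config, display)
    raise ValueError(f"unknown condition {cond!r}")
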