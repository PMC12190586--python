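"""Rendering of expert gaze into dense attention maps.

An eye tracker reports fixations in screen-pixel coordinates while a lesion
image is displayed centered on the screen. Each fixation is spread into a
Gaussian "gaze area" whose width sigma models the effective field of view
plus tracker error; summing the per-fixation Gaussians and max-normalizing
yields the human attention map A_human in [0, 1] that supervises the
network's class-activation attention.

The Gaussian width can either be preset (default 30 px, appropriate for
full-resolution endoscopy frames) or derived from viewing geometry: an
angular error of theta degrees at eye-screen distance R subtends an arc of
pi*R*theta/360 on the screen, which converts to display pixels through the
pixel density sqrt((Hp*Wp)/(H*W)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

logger = logging.getLogger(__name__)

__all__ = [
    "GazePoint",
    "FixationSequence",
    "ViewingGeometry",
    "GazeAttentionMap",
    "point_spread",
    "effective_sigma",
    "render_gaze_map",
    "overlay_heatmap",
    "gaussian_kernel_1d",
]


@dataclass(frozen=True)
class GazePoint:
    """One fixation: 0-based pixel coordinates, origin top-left."""

    x_px: float
    y_px: float
    timestamp_ms: float = 0.0
    duration_ms: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.x_px) and np.isfinite(self.y_px)):
            raise ValueError("gaze coordinates must be finite")
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be >= 0")


@dataclass
class FixationSequence:
    """Ordered fixations recorded while one image was read."""

    image_id: str
    points: list[GazePoint]
    screen_w_px: int = 1920
    screen_h_px: int = 1080

    def __post_init__(self):
        if self.screen_w_px <= 0 or self.screen_h_px <= 0:
            raise ValueError("screen dimensions must be positive")
        self.points = sorted(self.points, key=lambda p: p.timestamp_ms)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ViewingGeometry:
    """Display and viewing parameters for the angular-error sigma model.

    Physical extents and the eye distance share one length unit (cm by
    convention). Defaults: 27-inch 1920x1080 display (64x48 cm), eyes at
    65 cm, 1 degree of angular error.
    """

    screen_w_px: float = 1920.0
    screen_h_px: float = 1080.0
    screen_w_phys: float = 64.0
    screen_h_phys: float = 48.0
    eye_distance: float = 65.0
    perspective_error_deg: float = 1.0

    def __post_init__(self):
        for name in ("screen_w_px", "screen_h_px", "screen_w_phys",
                     "screen_h_phys", "eye_distance", "perspective_error_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.perspective_error_deg < 90.0:
            raise ValueError("perspective_error_deg must be in (0, 90)")


@dataclass
class GazeAttentionMap:
    """Dense human-attention map over image pixels, values in [0, 1]."""

    values: np.ndarray
    image_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def point_spread(x: float, y: float, center: GazePoint, sigma: float) -> float:
    """Gaussian spread of a single fixation evaluated at pixel (x, y).

    Returns (1/(sqrt(2*pi)*sigma)) * exp(-((x-xc)^2 + (y-yc)^2)/(2*sigma^2)).
    The leading constant uses the one-dimensional normalizer; because maps
    are max-normalized downstream, any constant factor is immaterial.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    d2 = (x - center.x_px) ** 2 + (y - center.y_px) ** 2
    return float(np.exp(-d2 / (2.0 * sigma ** 2)) / (np.sqrt(2.0 * np.pi) * sigma))


def effective_sigma(geom: ViewingGeometry) -> float:
    """Gaussian width in display pixels implied by the viewing geometry.

    sigma = (theta/360) * pi * R * sqrt((Hp*Wp)/(H*W)): the arc length
    subtended by theta degrees at distance R, converted from physical units
    to pixels via the display's mean pixel density. Linear in both R and
    theta. Provided as a calibration helper; the rendering default stays at
    the preset sigma unless a caller wires this value in.
    """
    arc = (geom.perspective_error_deg / 360.0) * np.pi * geom.eye_distance
    density = np.sqrt((geom.screen_h_px * geom.screen_w_px)
                      / (geom.screen_h_phys * geom.screen_w_phys))
    return float(arc * density)


def gaussian_kernel_1d(sigma: float, taps: int) -> np.ndarray:
    """Sampled 1-D Gaussian of `taps` taps centered on the middle tap."""
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if taps < 1 or taps % 2 == 0:
        raise ValueError("taps must be a positive odd integer")
    off = np.arange(taps) - taps // 2
    return np.exp(-off ** 2 / (2.0 * sigma ** 2)) / (np.sqrt(2.0 * np.pi) * sigma)


def screen_to_image(fix: FixationSequence, img_w: int, img_h: int,
                    offset: tuple[float, float] | None = None) -> np.ndarray:
    """Map screen-pixel fixations to integer image pixels.

    The image is assumed displayed at native size centered on the screen, so
    image_xy = screen_xy - (screen_dim - image_dim)/2, rounded to the nearest
    pixel. `offset` overrides the centered placement (x_offset, y_offset).
    Returns an (n, 3) array of (x, y, weight=duration); off-image fixations
    are NOT removed here.
    """
    if offset is None:
        off_x = (fix.screen_w_px - img_w) / 2.0
        off_y = (fix.screen_h_px - img_h) / 2.0
    else:
        off_x, off_y = offset
    out = np.array([[round(p.x_px - off_x), round(p.y_px - off_y), p.duration_ms]
                    for p in fix.points], dtype=float)
    return out.reshape(-1, 3)


def render_gaze_map(fix: FixationSequence, img_w: int, img_h: int,
                    sigma: float = 30.0, kernel_taps: int = 199,
                    weight_by_duration: bool = False,
                    border: str = "zero",
                    normalize: bool = True,
                    offset: tuple[float, float] | None = None) -> GazeAttentionMap:
    """Render a fixation sequence into a gaze-attention map.

    Pipeline: map fixations from screen to image coordinates; drop fixations
    that fall outside the image (clamping would pile spurious mass on the
    borders); accumulate an impulse image (weight 1 per fixation, or the
    fixation duration when `weight_by_duration`); convolve with a separable
    discrete Gaussian (`kernel_taps` taps, std `sigma`, zero-padded borders
    by default); rescale so the maximum equals 1. An empty or fully
    off-image sequence yields an all-zero map with a logged warning.
    """
    if img_w <= 0 or img_h <= 0:
        raise ValueError("image dimensions must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if kernel_taps % 2 == 0 or kernel_taps < 1:
        raise ValueError("kernel_taps must be a positive odd integer")
    if border not in ("zero", "reflect"):
        raise ValueError("border must be 'zero' or 'reflect'")

    impulse = np.zeros((img_h, img_w))
    pts = screen_to_image(fix, img_w, img_h, offset=offset)
    n_inside = 0
    for x, y, dur in pts:
        xi, yi = int(x), int(y)
        if 0 <= xi < img_w and 0 <= yi < img_h:
            impulse[yi, xi] += dur if weight_by_duration else 1.0
            n_inside += 1
    if n_inside == 0:
        logger.warning("no in-image fixations for %r; returning all-zero map",
                       fix.image_id)
        return GazeAttentionMap(values=impulse, image_id=fix.image_id)

    kern = gaussian_kernel_1d(sigma, kernel_taps)
    mode = "constant" if border == "zero" else "reflect"
    blurred = convolve1d(impulse, kern, axis=0, mode=mode, cval=0.0)
    blurred = convolve1d(blurred, kern, axis=1, mode=mode, cval=0.0)
    if normalize:
        peak = blurred.max()
        if peak > 0:
            blurred = blurred / peak
        blurred = np.clip(blurred, 0.0, 1.0)
    return GazeAttentionMap(values=blurred, image_id=fix.image_id)


def overlay_heatmap(image: np.ndarray, gaze_map, alpha: float = 0.5,
                    cmap: str = "jet") -> np.ndarray:
    """Blend a color-mapped attention map onto an RGB image.

    `image` is (H, W, 3) with values either in [0, 1] floats or uint8;
    output matches the input dtype and range. alpha=0 returns the image
    unchanged, alpha=1 the pure colormap rendering.
    """
    from matplotlib import colormaps

    values = gaze_map.values if hasattr(gaze_map, "values") else np.asarray(gaze_map)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    if image.shape[:2] != values.shape:
        raise ValueError(
            f"map shape {values.shape} does not match image {image.shape[:2]}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")

    is_uint8 = image.dtype == np.uint8
    img = image.astype(float) / 255.0 if is_uint8 else image.astype(float)
    colored = colormaps[cmap](np.clip(values, 0.0, 1.0))[..., :3]
    out = (1.0 - alpha) * img + alpha * colored
    if is_uint8:
        return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    return np.clip(out, 0.0, 1.0)
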