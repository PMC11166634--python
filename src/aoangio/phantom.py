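"""Synthetic retinal capillary phantoms and AO-SLO-like frame sequences.

The phantom emulates the scene an adaptive-optics scanning laser
ophthalmoscope sees over a ~300 µm patch of inner retina: a static,
weakly textured background, a sparse plexus of capillaries a few
micrometers in caliber, early diabetic lesion morphologies (loops,
s-shaped inflections, dilations, microaneurysms with bright granular
content), and a configurable fraction of non-perfused "ghost" segments —
capillaries that remain visible structurally but carry no flow.

Flow is modelled as an i.i.d.-per-frame multiplicative modulation of the
perfused lumen intensity (erythrocytes passing through the lumen change
backscatter frame to frame); ghost segments and background are static up
to eye motion and sensor noise.  Eye motion is a per-frame rigid jitter
plus one smooth low-frequency warp per frame; both are recorded exactly
as applied so registration accuracy can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import interpolate, ndimage

__all__ = [
    "PhantomSpec",
    "VesselSegmentTruth",
    "Phantom",
    "MotionModel",
    "FrameSequence",
    "InfeasiblePhantomError",
    "generate_phantom",
    "render_frames",
    "render_structural",
    "invert_warp",
]

LESION_TAGS = ("normal", "loop", "s_inflection", "dilation", "microaneurysm")


class InfeasiblePhantomError(ValueError):
    """Requested vessel geometry cannot fit in the phantom field."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic capillary phantom.

    Defaults correspond to the imaging regime emulated throughout the
    package: 1.5 µm/px sampling, capillary calibers of 4–8 µm, and one
    fifth of vessel segments non-perfused.
    """

    field_width_px: int = 192
    field_height_px: int = 192
    pixel_pitch_um: float = 1.5
    n_vessels: int = 8
    caliber_range_um: tuple[float, float] = (4.0, 8.0)
    n_loops: int = 1
    n_s_inflections: int = 1
    n_dilations: int = 1
    n_microaneurysms: int = 1
    ghost_fraction: float = 0.2
    background_level: float = 0.30
    vessel_contrast: float = 0.50
    ghost_contrast: float = 0.35
    texture_amplitude: float = 0.06
    flow_modulation: float = 0.5
    ghost_caliber_factor: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        lo, hi = self.caliber_range_um
        if not (0 < lo <= hi):
            raise ValueError("caliber_range_um must satisfy 0 < lo <= hi")
        if not (0.0 <= self.ghost_fraction <= 1.0):
            raise ValueError("ghost_fraction must lie in [0, 1]")
        for name in ("n_vessels", "n_loops", "n_s_inflections", "n_dilations",
                     "n_microaneurysms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("background_level", "vessel_contrast", "ghost_contrast",
                     "texture_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_width_px * self.pixel_pitch_um,
                self.field_height_px * self.pixel_pitch_um)


@dataclass
class VesselSegmentTruth:
    """Ground truth for one vessel segment.

    ``centerline`` is an ordered (K, 2) array of (x_um, y_um) points;
    microaneurysms additionally carry a bulb (center + radius, µm).
    """

    centerline: np.ndarray
    caliber_um: float
    lesion_tag: str
    perfused: bool
    bulb_center_um: Optional[tuple[float, float]] = None
    bulb_radius_um: float = 0.0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs >= 2 (x, y) points")
        if self.caliber_um <= 0:
            raise ValueError("caliber_um must be positive")
        if self.lesion_tag not in LESION_TAGS:
            raise ValueError(f"unknown lesion tag {self.lesion_tag!r}")


@dataclass
class Phantom:
    spec: PhantomSpec
    segments: list[VesselSegmentTruth]
    vessel_mask: np.ndarray
    perfused_mask: np.ndarray
    ghost_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return (self.spec.field_height_px, self.spec.field_width_px)


@dataclass(frozen=True)
class MotionModel:
    """Inter-frame eye motion: rigid jitter plus a smooth random warp.

    Amplitudes are bounds (µm) on the per-frame rigid translation and on
    the maximum displacement of the smooth low-frequency deformation.
    """

    jitter_amplitude_um: float = 3.0
    deformation_amplitude_um: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.jitter_amplitude_um < 0 or self.deformation_amplitude_um < 0:
            raise ValueError("motion amplitudes must be nonnegative")


@dataclass
class FrameSequence:
    """A stack of co-located grayscale frames.

    ``true_warps`` holds the sampling displacement actually applied when
    rendering each frame, in pixels, shape (N, H, W, 2) ordered (dy, dx):
    frame_n(y, x) was sampled from the scene at (y + dy, x + dx).
    """

    frames: np.ndarray
    pixel_pitch_um: float
    true_warps: Optional[np.ndarray] = None
    validity_mask: Optional[np.ndarray] = None
    registered: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (N, H, W) stack")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# geometry helpers

def _smooth_curve(points: np.ndarray, n_samples: int = 200) -> np.ndarray:
    """Cubic spline through waypoints; returns densely sampled (K, 2) µm."""
    points = np.asarray(points, dtype=float)
    k = min(3, len(points) - 1)
    tck, _ = interpolate.splprep([points[:, 0], points[:, 1]], s=0.0, k=k)
    u = np.linspace(0.0, 1.0, n_samples)
    x, y = interpolate.splev(u, tck)
    return np.column_stack([x, y])


def _random_crossing_curve(rng: np.random.Generator, w_um: float, h_um: float
                           ) -> np.ndarray:
    """A smooth curve entering and leaving the field at random borders."""
    # opposite borders with jittered waypoints in between
    if rng.random() < 0.5:  # left -> right
        p0 = np.array([0.0, rng.uniform(0.1, 0.9) * h_um])
        p1 = np.array([w_um, rng.uniform(0.1, 0.9) * h_um])
    else:  # top -> bottom
        p0 = np.array([rng.uniform(0.1, 0.9) * w_um, 0.0])
        p1 = np.array([rng.uniform(0.1, 0.9) * w_um, h_um])
    n_way = 4
    t = np.linspace(0.0, 1.0, n_way + 2)[:, None]
    base = p0 * (1 - t) + p1 * t
    jitter_scale = 0.12 * min(w_um, h_um)
    base[1:-1] += rng.normal(0.0, jitter_scale, size=(n_way, 2))
    base[:, 0] = np.clip(base[:, 0], 0.0, w_um)
    base[:, 1] = np.clip(base[:, 1], 0.0, h_um)
    return _smooth_curve(base)


def _loop_curve(rng: np.random.Generator, center: np.ndarray, radius: float
                ) -> np.ndarray:
    """Closed, slightly eccentric loop (distended capillary loop)."""
    theta = np.linspace(0.0, 2.0 * np.pi, 120)
    ecc = rng.uniform(0.7, 1.0)
    phi = rng.uniform(0.0, np.pi)
    x = radius * np.cos(theta)
    y = ecc * radius * np.sin(theta)
    xr = x * np.cos(phi) - y * np.sin(phi) + center[0]
    yr = x * np.sin(phi) + y * np.cos(phi) + center[1]
    return np.column_stack([xr, yr])


def _s_curve(rng: np.random.Generator, center: np.ndarray, length: float,
             amplitude: float) -> np.ndarray:
    """Short segment with two curvature reversals (s-shaped inflection)."""
    t = np.linspace(-0.5, 0.5, 100)
    x = t * length
    y = amplitude * np.sin(2.0 * np.pi * t)
    phi = rng.uniform(0.0, np.pi)
    xr = x * np.cos(phi) - y * np.sin(phi) + center[0]
    yr = x * np.sin(phi) + y * np.cos(phi) + center[1]
    return np.column_stack([xr, yr])


def _short_curve(rng: np.random.Generator, center: np.ndarray, length: float
                 ) -> np.ndarray:
    """Gently curved short segment (used for dilations and MA stalks)."""
    t = np.linspace(-0.5, 0.5, 60)
    x = t * length
    y = rng.uniform(-0.1, 0.1) * length * np.sin(np.pi * t)
    phi = rng.uniform(0.0, np.pi)
    xr = x * np.cos(phi) - y * np.sin(phi) + center[0]
    yr = x * np.sin(phi) + y * np.cos(phi) + center[1]
    return np.column_stack([xr, yr])


def _clip_to_field(curve: np.ndarray, w_um: float, h_um: float) -> np.ndarray:
    out = curve.copy()
    out[:, 0] = np.clip(out[:, 0], 0.0, w_um)
    out[:, 1] = np.clip(out[:, 1], 0.0, h_um)
    return out


def _rasterize_segment(seg: VesselSegmentTruth, shape: tuple[int, int],
                       pitch: float, caliber_scale: float = 1.0) -> np.ndarray:
    """Binary tube mask: pixels within caliber/2 of the centerline."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    pts = seg.centerline / pitch  # pixel coords (x, y)
    # resample densely so consecutive points are < 0.5 px apart
    d = np.r_[0.0, np.cumsum(np.hypot(*np.diff(pts, axis=0).T))]
    if d[-1] > 0:
        n = max(int(d[-1] / 0.4) + 1, 2)
        s = np.linspace(0.0, d[-1], n)
        pts = np.column_stack([np.interp(s, d, pts[:, 0]),
                               np.interp(s, d, pts[:, 1])])
    r_px = 0.5 * seg.caliber_um * caliber_scale / pitch
    _paint_disks(mask, pts, np.full(len(pts), r_px))
    if seg.bulb_center_um is not None and seg.bulb_radius_um > 0:
        c = np.asarray(seg.bulb_center_um) / pitch
        _paint_disks(mask, c[None, :], np.array([seg.bulb_radius_um / pitch]))
    return mask


def _paint_disks(mask: np.ndarray, centers_px: np.ndarray,
                 radii_px: np.ndarray) -> None:
    h, w = mask.shape
    r_max = float(radii_px.max()) if len(radii_px) else 0.0
    half = max(int(np.ceil(r_max)), 1)
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    for (cx, cy), r in zip(centers_px, radii_px):
        ix, iy = int(round(cx)), int(round(cy))
        stamp = (xx + ix - cx) ** 2 + (yy + iy - cy) ** 2 <= max(r, 0.5) ** 2
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        mask[y0:y1, x0:x1] |= stamp[y0 - (iy - half):y1 - (iy - half),
                                    x0 - (ix - half):x1 - (ix - half)]


# ---------------------------------------------------------------------------
# phantom generation

def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a capillary phantom with the requested lesion census.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`InfeasiblePhantomError` when the requested calibers or lesion
    geometries cannot fit inside the field.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w_um, h_um = spec.field_um
    lo, hi = spec.caliber_range_um
    max_bulb_um = 30.0

    any_structure = (spec.n_vessels + spec.n_loops + spec.n_s_inflections
                     + spec.n_dilations + spec.n_microaneurysms) > 0
    if any_structure and min(w_um, h_um) < max(6.0 * hi, 4.0 * max_bulb_um if
                                               spec.n_microaneurysms else 0.0):
        raise InfeasiblePhantomError(
            f"field {w_um:.0f}x{h_um:.0f} um too small for calibers up to "
            f"{hi} um / requested lesions")

    segments: list[VesselSegmentTruth] = []
    margin = 0.18 * min(w_um, h_um)

    def interior_point() -> np.ndarray:
        return np.array([rng.uniform(margin, w_um - margin),
                         rng.uniform(margin, h_um - margin)])

    for _ in range(spec.n_vessels):
        curve = _random_crossing_curve(rng, w_um, h_um)
        segments.append(VesselSegmentTruth(
            centerline=_clip_to_field(curve, w_um, h_um),
            caliber_um=rng.uniform(lo, hi), lesion_tag="normal",
            perfused=True))
    for _ in range(spec.n_loops):
        curve = _loop_curve(rng, interior_point(), rng.uniform(12.0, 25.0))
        segments.append(VesselSegmentTruth(
            centerline=_clip_to_field(curve, w_um, h_um),
            caliber_um=rng.uniform(lo, hi), lesion_tag="loop", perfused=True))
    for _ in range(spec.n_s_inflections):
        curve = _s_curve(rng, interior_point(), rng.uniform(50.0, 80.0),
                         rng.uniform(8.0, 14.0))
        segments.append(VesselSegmentTruth(
            centerline=_clip_to_field(curve, w_um, h_um),
            caliber_um=rng.uniform(lo, hi), lesion_tag="s_inflection",
            perfused=True))
    for _ in range(spec.n_dilations):
        curve = _short_curve(rng, interior_point(), rng.uniform(40.0, 70.0))
        segments.append(VesselSegmentTruth(
            centerline=_clip_to_field(curve, w_um, h_um),
            caliber_um=hi * rng.uniform(1.5, 2.0), lesion_tag="dilation",
            perfused=True))
    for _ in range(spec.n_microaneurysms):
        center = interior_point()
        curve = _short_curve(rng, center, rng.uniform(25.0, 40.0))
        bulb_r = rng.uniform(10.0, max_bulb_um) / 2.0 + 5.0  # radius, µm
        segments.append(VesselSegmentTruth(
            centerline=_clip_to_field(curve, w_um, h_um),
            caliber_um=rng.uniform(lo, hi), lesion_tag="microaneurysm",
            perfused=True, bulb_center_um=tuple(curve[-1]),
            bulb_radius_um=bulb_r))

    # flag the ghost subset at the requested fraction
    n_ghost = int(round(spec.ghost_fraction * len(segments)))
    ghost_idx = rng.choice(len(segments), size=n_ghost, replace=False) \
        if n_ghost else np.array([], dtype=int)
    for i in ghost_idx:
        segments[i].perfused = False

    shape = (spec.field_height_px, spec.field_width_px)
    perfused_mask = np.zeros(shape, dtype=bool)
    ghost_raw = np.zeros(shape, dtype=bool)
    for seg in segments:
        if seg.perfused:
            perfused_mask |= _rasterize_segment(seg, shape,
                                                spec.pixel_pitch_um)
        else:
            ghost_raw |= _rasterize_segment(seg, shape, spec.pixel_pitch_um,
                                            spec.ghost_caliber_factor)
    # flow wins at crossings: a pixel inside a perfused lumen is perfused
    ghost_mask = ghost_raw & ~perfused_mask
    vessel_mask = perfused_mask | ghost_mask
    return Phantom(spec=spec, segments=segments, vessel_mask=vessel_mask,
                   perfused_mask=perfused_mask, ghost_mask=ghost_mask)


# ---------------------------------------------------------------------------
# rendering

def _background_texture(spec: PhantomSpec) -> np.ndarray:
    """Static smooth texture (retinal mosaic stand-in), from spec.seed."""
    shape = (spec.field_height_px, spec.field_width_px)
    rng = np.random.default_rng(spec.seed + 17)
    noise = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(noise, sigma=2.5)
    sd = tex.std()
    if sd > 0:
        tex *= spec.texture_amplitude / sd
    return tex


def _base_scene(phantom: Phantom) -> np.ndarray:
    """Time-averaged scene: background + texture + vessel contrasts."""
    spec = phantom.spec
    img = np.full(phantom.shape, spec.background_level, dtype=float)
    img += _background_texture(spec)
    img[phantom.perfused_mask] = spec.background_level + spec.vessel_contrast
    img[phantom.ghost_mask] = spec.background_level + spec.ghost_contrast
    return np.clip(img, 0.0, None)


def render_structural(phantom: Phantom) -> np.ndarray:
    """Structural *en face* image: all vessels bright, ghosts as narrow
    strings of reduced contrast.  Deterministic (no sensor noise)."""
    img = ndimage.gaussian_filter(_base_scene(phantom), sigma=0.6)
    return np.clip(img, 0.0, None)


def render_frames(phantom: Phantom, n_frames: int, motion: MotionModel,
                  noise_sd: float, flow_on: bool, seed: int) -> FrameSequence:
    """Render an AO-SLO-like frame sequence from a phantom.

    Per frame: perfused lumen pixels get an i.i.d. multiplicative flow
    modulation (when ``flow_on``), the scene is resampled under the
    frame's motion warp, and additive Gaussian sensor noise is applied,
    clipping at zero.  The applied warps are recorded exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    motion.validate()
    spec = phantom.spec
    h, w = phantom.shape
    if h == 0 or w == 0:
        raise ValueError("phantom rasters are empty")

    base = _base_scene(phantom)
    rng_render = np.random.default_rng(seed)
    rng_motion = np.random.default_rng(motion.seed)
    jit_px = motion.jitter_amplitude_um / spec.pixel_pitch_um
    def_px = motion.deformation_amplitude_um / spec.pixel_pitch_um

    perf_idx = np.flatnonzero(phantom.perfused_mask.ravel())
    m = spec.flow_modulation
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    frames = np.empty((n_frames, h, w), dtype=float)
    warps = np.zeros((n_frames, h, w, 2), dtype=np.float32)
    for n in range(n_frames):
        scene = base.copy()
        if flow_on and perf_idx.size:
            mod = 1.0 + m * (2.0 * rng_render.random(perf_idx.size) - 1.0)
            flat = scene.ravel()
            flat[perf_idx] = np.clip(flat[perf_idx] * mod, 0.02, None)
        # motion draws happen every frame so sequences with different
        # amplitudes but equal seeds stay frame-wise comparable
        t = rng_motion.uniform(-1.0, 1.0, size=2)
        coarse = rng_motion.standard_normal((2, 4, 4))
        if jit_px > 0 or def_px > 0:
            wy = np.full((h, w), t[0] * jit_px)
            wx = np.full((h, w), t[1] * jit_px)
            if def_px > 0:
                for comp, arr in enumerate((wy, wx)):
                    fieldc = ndimage.zoom(coarse[comp], (h / 4.0, w / 4.0),
                                          order=3, mode="nearest",
                                          grid_mode=True)
                    peak = np.abs(fieldc).max()
                    if peak > 0:
                        arr += fieldc * (def_px * rng_motion.uniform(0.5, 1.0)
                                         / peak)
            frame = ndimage.map_coordinates(scene, [yy + wy, xx + wx],
                                            order=3, mode="nearest")
            warps[n, :, :, 0] = wy
            warps[n, :, :, 1] = wx
        else:
            frame = scene
        if noise_sd > 0:
            frame = frame + noise_sd * rng_render.standard_normal((h, w))
        frames[n] = np.clip(frame, 0.0, None)

    return FrameSequence(frames=frames, pixel_pitch_um=spec.pixel_pitch_um,
                         true_warps=warps)


def invert_warp(warp: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Numerically invert a dense displacement field.

    ``warp`` has shape (H, W, 2) ordered (dy, dx) in pixels, defining the
    sampling map x -> x + w(x).  Returns v with (x + v(x)) + w(x + v(x))
    = x, by fixed-point iteration v <- -w(x + v).
    """
    h, w = warp.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    v = np.zeros_like(warp, dtype=float)
    for _ in range(n_iter):
        cy = yy + v[..., 0]
        cx = xx + v[..., 1]
        wy = ndimage.map_coordinates(warp[..., 0].astype(float), [cy, cx],
                                     order=1, mode="nearest")
        wx = ndimage.map_coordinates(warp[..., 1].astype(float), [cy, cx],
                                     order=1, mode="nearest")
        v[..., 0] = -wy
        v[..., 1] = -wx
    return v
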