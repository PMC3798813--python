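"""Synthetic scene generators for the validation pipeline.

Every input the analysis chain consumes can be generated here with exact
ground truth and seeded randomness:

* a B-mode-like sequence of an oscillating spring imaged in water,
* a gastrocnemius-like scene twitching under 1-pps stimulation,
* trigger-locked multichannel M-wave recordings on an electrode grid,
* voltage/current sinusoid pairs for electrode-interface impedance sweeps.

Rendering model
---------------
Frames are rendered from a fixed cloud of sub-resolution scatterers held in
material (frame-0) coordinates. Each frame the cloud is advected by the
scene's continuous displacement field, splatted onto the pixel grid with
bilinear weights, convolved with a separable Gaussian point-spread function,
and log-compressed to 8 bits. Because motion is applied to continuous
scatterer coordinates before rasterisation, sub-pixel displacements are
rendered faithfully — frames are never produced by integer-pixel shifting.
Bright anatomical structures (spring edges and end caps, aponeuroses, skin
line) are polylines densely sampled into high-reflectivity scatterers with a
frozen multiplicative texture so that correlation windows see stable,
feature-rich speckle.

All randomness flows from the explicit ``seed`` through one
``numpy.random.Generator``; identical parameters and seed reproduce
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import (
    EMGRecording,
    GridGeometry,
    GroundTruth,
    ImageSequence,
    Segmentation,
    default_channel_map,
)
from .errors import ValidationError

__all__ = [
    "ScattererField",
    "SpringSceneParams",
    "TwitchSceneParams",
    "MWaveGridParams",
    "InterfaceCircuit",
    "simulate_spring_sequence",
    "simulate_twitch_sequence",
    "simulate_mwave_grid",
    "simulate_interface_signals",
    "twitch_pulse",
    "render_frames",
]

SeedLike = Union[int, np.random.SeedSequence]


def _make_rng(seed: SeedLike) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Scatterer field and renderer
# ---------------------------------------------------------------------------


@dataclass
class ScattererField:
    """Point scatterers plus bright structure polylines, all in scene mm.

    ``positions`` are ``(N, 2)`` ``(axial_mm, lateral_mm)`` coordinates in the
    frame-0 (material) configuration; ``reflectivity`` is one non-negative
    amplitude per scatterer. ``bright_structures`` holds the polylines
    (vertex arrays in mm) from which the high-reflectivity samples were
    drawn, for inspection; their sampled points are already part of
    ``positions``/``reflectivity``.
    """

    positions: np.ndarray
    reflectivity: np.ndarray
    bright_structures: list = field(default_factory=list)
    bounds_mm: tuple[float, float] = (0.0, 0.0)  # (axial extent, lateral extent)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must be (N, 2) (axial, lateral) mm")
        if self.reflectivity.shape != (self.positions.shape[0],):
            raise ValidationError("one reflectivity per scatterer required")
        if np.any(self.reflectivity < 0):
            raise ValidationError("reflectivities must be non-negative")

    @property
    def n_scatterers(self) -> int:
        return int(self.positions.shape[0])


def _sample_polyline(
    polyline: np.ndarray,
    rng: np.random.Generator,
    step_mm: float = 0.025,
    texture_scale_mm: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Densely sample a polyline into points with frozen multiplicative texture.

    The texture is piecewise-constant over ``texture_scale_mm`` arclength
    chunks, coarser than the PSF, so it survives envelope smoothing and gives
    correlation windows something to lock onto.
    """
    poly = np.asarray(polyline, dtype=float)
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    n = max(int(math.ceil(total / step_mm)), 2)
    s = np.linspace(0.0, total, n)
    ax = np.interp(s, arclen, poly[:, 0])
    lat = np.interp(s, arclen, poly[:, 1])
    chunks = (s / texture_scale_mm).astype(int)
    gains = 0.55 + 0.9 * rng.random(chunks.max() + 1)
    return np.column_stack([ax, lat]), gains[chunks]


def _splat_bilinear(
    rows: np.ndarray, cols: np.ndarray, amp: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Accumulate point amplitudes onto a grid with bilinear weights."""
    h, w = shape
    acc = np.zeros(h * w)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        if np.any(ok):
            acc += np.bincount(
                rr[ok] * w + cc[ok], weights=(amp * wt)[ok], minlength=h * w
            )
    return acc.reshape(h, w)


def render_frames(
    positions_mm: np.ndarray,
    reflectivity: np.ndarray,
    displacement,
    n_frames: int,
    shape_px: tuple[int, int],
    calib_mm_per_px: tuple[float, float],
    psf_sigma_mm: tuple[float, float] = (0.1, 0.2),
    log_dynamic: float = 60.0,
) -> np.ndarray:
    """Render a scatterer cloud into an 8-bit frame stack.

    ``displacement(frame, positions_mm) -> (N, 2) mm`` supplies the motion of
    each scatterer from its material position. Intensity is normalised by the
    frame-0 envelope peak, so a motionless scene renders identical frames.
    """
    calib_ax, calib_lat = calib_mm_per_px
    sigma_px = (psf_sigma_mm[0] / calib_ax, psf_sigma_mm[1] / calib_lat)
    frames = np.empty((n_frames,) + shape_px, dtype=np.uint8)
    ref = None
    denom = math.log1p(log_dynamic)
    for f in range(n_frames):
        pts = positions_mm + displacement(f, positions_mm)
        env = _splat_bilinear(
            pts[:, 0] / calib_ax, pts[:, 1] / calib_lat, reflectivity, shape_px
        )
        env = gaussian_filter(env, sigma_px, mode="constant")
        np.maximum(env, 0.0, out=env)
        if ref is None:
            ref = float(env.max())
            if ref <= 0:
                ref = 1.0
        img = 255.0 * np.log1p(log_dynamic * env / ref) / denom
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return frames


# ---------------------------------------------------------------------------
# Spring scene
# ---------------------------------------------------------------------------


@dataclass
class SpringSceneParams:
    """Oscillating spring imaged in water.

    The spring axis lies along the image axial (row) direction. One end is
    fixed (deep, at the beaker base); the other is driven sinusoidally so the
    spring length is ``rest + (D/2) sin(2 pi f t)`` with peak-to-peak ``D``.
    """

    rest_length_mm: float = 10.0
    peak_to_peak_mm: float = 1.0
    frequency_hz: float = 1.0
    duration_s: float = 30.0
    frame_rate_hz: float = 80.0
    calib_mm_per_px: tuple[float, float] = (0.05, 0.05)
    scatterer_density_per_mm2: float = 30.0
    psf_sigma_mm: tuple[float, float] = (0.1, 0.2)
    axial_margin_mm: float = 2.5
    lateral_width_mm: float = 6.0
    spring_radius_mm: float = 1.5
    seed: SeedLike = 0

    def __post_init__(self) -> None:
        if self.peak_to_peak_mm < 0:
            raise ValidationError("peak_to_peak_mm must be non-negative")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if not self.frame_rate_hz > 0:
            raise ValidationError("frame_rate_hz must be positive")
        if not (0 < self.frequency_hz < self.frame_rate_hz / 2):
            raise ValidationError(
                f"frequency_hz={self.frequency_hz} must lie strictly below the "
                f"Nyquist rate {self.frame_rate_hz / 2} Hz"
            )
        if self.calib_mm_per_px[0] <= 0 or self.calib_mm_per_px[1] <= 0:
            raise ValidationError("calibration must be positive along both axes")
        if self.rest_length_mm <= self.peak_to_peak_mm:
            raise ValidationError("rest length must exceed the oscillation amplitude")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def _spring_field(params: SpringSceneParams, rng: np.random.Generator) -> ScattererField:
    h_mm = params.rest_length_mm + 2 * params.axial_margin_mm
    w_mm = params.lateral_width_mm
    cx = w_mm / 2
    y_top = params.axial_margin_mm
    y_bot = y_top + params.rest_length_mm
    r = params.spring_radius_mm

    n_bg = int(round(params.scatterer_density_per_mm2 * h_mm * w_mm))
    pos = rng.random((n_bg, 2)) * np.array([h_mm, w_mm])
    refl = 0.08 * rng.rayleigh(1.0, n_bg)

    structures = []
    # End caps (lateral segments) and short near-vertical edge segments at
    # each spring end, plus faint full-length body edges.
    for y_end, tag in ((y_top, "top"), (y_bot, "bottom")):
        cap = np.array([[y_end, cx - r], [y_end, cx + r]])
        structures.append((cap, 8.0, f"{tag}_cap"))
        for x_edge in (cx - r, cx + r):
            edge = np.array([[y_end - 0.6, x_edge], [y_end + 0.6, x_edge]])
            structures.append((edge, 8.0, f"{tag}_edge"))
    for x_edge in (cx - r, cx + r):
        body = np.array([[y_top, x_edge], [y_bot, x_edge]])
        structures.append((body, 2.0, "body_edge"))

    all_pos = [pos]
    all_refl = [refl]
    for poly, boost, _tag in structures:
        p, gain = _sample_polyline(poly, rng)
        all_pos.append(p)
        all_refl.append(boost * gain)
    return ScattererField(
        positions=np.vstack(all_pos),
        reflectivity=np.concatenate(all_refl),
        bright_structures=[(poly, boost) for poly, boost, _ in structures],
        bounds_mm=(h_mm, w_mm),
    )


def _spring_displacement(params: SpringSceneParams):
    """Affine axial stretch about the fixed (deep) end of the spring."""
    y_bot = params.axial_margin_mm + params.rest_length_mm
    amp = params.peak_to_peak_mm / 2
    omega = 2 * math.pi * params.frequency_hz
    dt = 1.0 / params.frame_rate_hz
    rest = params.rest_length_mm

    def displacement(frame: int, pts_mm: np.ndarray) -> np.ndarray:
        s = amp * math.sin(omega * frame * dt)
        disp = np.zeros_like(pts_mm)
        disp[:, 0] = -s * (y_bot - pts_mm[:, 0]) / rest
        return disp

    return displacement


def simulate_spring_sequence(
    params: SpringSceneParams,
) -> tuple[ImageSequence, GroundTruth]:
    """Render the oscillating-spring scene and its exact length ground truth."""
    rng = _make_rng(params.seed)
    field_ = _spring_field(params, rng)
    disp = _spring_displacement(params)
    calib_ax, calib_lat = params.calib_mm_per_px
    shape = (
        int(round(field_.bounds_mm[0] / calib_ax)),
        int(round(field_.bounds_mm[1] / calib_lat)),
    )
    frames = render_frames(
        field_.positions,
        field_.reflectivity,
        disp,
        params.n_frames,
        shape,
        params.calib_mm_per_px,
        params.psf_sigma_mm,
    )
    t = np.arange(params.n_frames) / params.frame_rate_hz
    length = params.rest_length_mm + (params.peak_to_peak_mm / 2) * np.sin(
        2 * math.pi * params.frequency_hz * t
    )
    cx = params.lateral_width_mm / 2
    meta = {
        "scene": "spring",
        "end_axial_px": [
            params.axial_margin_mm / calib_ax,
            (params.axial_margin_mm + params.rest_length_mm) / calib_ax,
        ],
        "center_lateral_px": cx / calib_lat,
        "edge_lateral_px": [
            (cx - params.spring_radius_mm) / calib_lat,
            (cx + params.spring_radius_mm) / calib_lat,
        ],
        "peak_to_peak_mm": params.peak_to_peak_mm,
        "frequency_hz": params.frequency_hz,
    }
    seq = ImageSequence(frames, params.frame_rate_hz, params.calib_mm_per_px, meta)
    gt = GroundTruth(time_s=t, length_mm=length, displacement=disp)
    return seq, gt


def spring_structure_centroids(
    params: SpringSceneParams, frames: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Axial centroids (mm) of the two end structures on the noiseless layer.

    Renders only the bright end structures (no speckle) and returns a
    ``(len(frames), 2)`` array of intensity-weighted axial centroids
    (top end, bottom end) — the geometric surface against which the emitted
    ground truth can be audited.
    """
    rng = _make_rng(params.seed)
    field_ = _spring_field(params, rng)
    disp = _spring_displacement(params)
    calib_ax, calib_lat = params.calib_mm_per_px
    shape = (
        int(round(field_.bounds_mm[0] / calib_ax)),
        int(round(field_.bounds_mm[1] / calib_lat)),
    )
    if frames is None:
        frames = range(params.n_frames)
    y_mid = params.axial_margin_mm + params.rest_length_mm / 2

    # Re-sample only the end structures (first 6 polylines: 2 x (cap + 2 edges)).
    pts, refl = [], []
    rng2 = _make_rng(params.seed)
    for poly, boost in field_.bright_structures[:6]:
        p, gain = _sample_polyline(poly, rng2)
        pts.append(p)
        refl.append(boost * gain)
    pts = np.vstack(pts)
    refl = np.concatenate(refl)

    out = np.empty((len(list(frames)), 2))
    for i, f in enumerate(frames):
        moved = pts + disp(f, pts)
        env = _splat_bilinear(
            moved[:, 0] / calib_ax, moved[:, 1] / calib_lat, refl, shape
        )
        env = gaussian_filter(env, (0.1 / calib_ax, 0.2 / calib_lat), mode="constant")
        rows_mm = np.arange(shape[0]) * calib_ax
        prof = env.sum(axis=1)
        top = rows_mm < y_mid
        out[i, 0] = np.average(rows_mm[top], weights=prof[top])
        out[i, 1] = np.average(rows_mm[~top], weights=prof[~top])
    return out


# ---------------------------------------------------------------------------
# Twitch scene
# ---------------------------------------------------------------------------


def twitch_pulse(
    t: np.ndarray,
    onsets_s: np.ndarray,
    tau_rise_s: float,
    tau_decay_s: float,
) -> np.ndarray:
    """Unit-peak twitch waveform: difference of two exponentials per stimulus.

    ``a (exp(-t/tau_decay) - exp(-t/tau_rise))`` normalised so each pulse
    peaks at 1; pulses from successive stimuli superpose linearly.
    """
    if not tau_rise_s < tau_decay_s:
        raise ValidationError("tau_rise must be smaller than tau_decay")
    t = np.asarray(t, dtype=float)
    # analytic peak of the difference-of-exponentials
    tp = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)) * math.log(
        tau_decay_s / tau_rise_s
    )
    peak = math.exp(-tp / tau_decay_s) - math.exp(-tp / tau_rise_s)
    out = np.zeros_like(t)
    for t0 in np.atleast_1d(onsets_s):
        dt = t - t0
        m = dt > 0
        out[m] += (np.exp(-dt[m] / tau_decay_s) - np.exp(-dt[m] / tau_rise_s)) / peak
    return out


@dataclass
class TwitchSceneParams:
    """Gastrocnemius-like scene: two aponeuroses bounding a speckled fascicle
    region, deforming under a stimulus-locked twitch.

    ``resting_muscle_length_mm`` is the resting deep-to-superficial fascicle
    span measured by the probe grid (the inner fascicle band); shortening
    reduces it by ``shortening_mm`` at the twitch peak while the
    inter-aponeurosis thickness grows by ``thickening_mm``.
    """

    resting_muscle_length_mm: float = 10.0
    resting_thickness_mm: float = 14.0
    shortening_mm: float = 1.0
    thickening_mm: float = 0.5
    tau_rise_s: float = 0.025
    tau_decay_s: float = 0.09
    stim_rate_pps: float = 1.0
    stim_latency_s: float = 0.025
    duration_s: float = 20.0
    frame_rate_hz: float = 80.0
    calib_mm_per_px: tuple[float, float] = (0.05, 0.05)
    lateral_width_mm: float = 24.0
    superficial_depth_mm: float = 3.0
    apo_slope: float = 0.04  # mm depth per mm lateral
    scatterer_density_per_mm2: float = 30.0
    psf_sigma_mm: tuple[float, float] = (0.1, 0.2)
    seed: SeedLike = 0

    def __post_init__(self) -> None:
        if self.shortening_mm < 0 or self.thickening_mm < -self.resting_thickness_mm:
            raise ValidationError(
                "shortening must be non-negative and thickening may not "
                "collapse the aponeuroses"
            )
        if not self.tau_rise_s < self.tau_decay_s:
            raise ValidationError("tau_rise must be smaller than tau_decay")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValidationError("duration and frame rate must be positive")
        if self.stim_rate_pps <= 0:
            raise ValidationError("stimulus rate must be positive")
        band = 5 * self.resting_thickness_mm / 7
        if self.shortening_mm >= band:
            raise ValidationError(
                "shortening amplitude would fold the inner fascicle band"
            )
        margin = self.resting_thickness_mm / 7
        if (self.thickening_mm + self.shortening_mm) / 2 <= -margin:
            raise ValidationError(
                "thickening/shortening combination would cross the aponeuroses"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def stimulus_onsets_s(self) -> np.ndarray:
        n = int(math.floor((self.duration_s - 1e-9) * self.stim_rate_pps)) + 1
        return np.arange(n) / self.stim_rate_pps + self.stim_latency_s


def _twitch_displacement(params: TwitchSceneParams, pulse: np.ndarray):
    """Axial accordion field: knots at the aponeuroses and at the outer
    fascicle probe rows (1/7 and 6/7 of the gap).

    The superficial aponeurosis is fixed, the deep one moves deeper by the
    thickening, and the inner band (between the 1/7 and 6/7 knots — exactly
    the span measured by the probe grid) contracts by the shortening, the
    slack being absorbed symmetrically by the two margin layers.
    """
    h0 = params.resting_thickness_mm
    cx = params.lateral_width_mm / 2
    y_s0 = params.superficial_depth_mm
    slope = params.apo_slope
    a_th = params.thickening_mm
    a_sh = params.shortening_mm

    # plateaus around the aponeuroses and the measurement rows keep the field
    # locally uniform there, so piecewise-linear interpolation of tracked
    # features is unbiased exactly where the series are read off; the strain
    # is concentrated in the short ramps between plateaus
    d_apo = h0 / 35
    d_knot = h0 / 14
    k1, k2 = h0 / 7, 6 * h0 / 7
    knots_rel = np.array(
        [d_apo, k1 - d_knot, k1 + d_knot, k2 - d_knot, k2 + d_knot, h0 - d_apo]
    )

    def displacement(frame: int, pts_mm: np.ndarray) -> np.ndarray:
        p = float(pulse[frame])
        w1 = (a_th + a_sh) * p / 2
        w2 = (a_th - a_sh) * p / 2
        w_knots = np.array([0.0, w1, w1, w2, w2, a_th * p])
        y_s = y_s0 + slope * (pts_mm[:, 1] - cx)
        rel = pts_mm[:, 0] - y_s
        disp = np.zeros_like(pts_mm)
        disp[:, 0] = np.interp(rel, knots_rel, w_knots)
        return disp

    return displacement


def simulate_twitch_sequence(
    params: TwitchSceneParams,
) -> tuple[ImageSequence, GroundTruth, Segmentation]:
    """Render the twitching-muscle scene, its ground truth, and the true
    aponeurosis segmentation (frame-0 pixel coordinates)."""
    rng = _make_rng(params.seed)
    calib_ax, calib_lat = params.calib_mm_per_px
    h0 = params.resting_thickness_mm
    w_mm = params.lateral_width_mm
    cx = w_mm / 2
    y_s0 = params.superficial_depth_mm
    depth_mm = y_s0 + h0 + max(params.thickening_mm, 0.0) + 2.5

    n_bg = int(round(params.scatterer_density_per_mm2 * depth_mm * w_mm))
    pos = rng.random((n_bg, 2)) * np.array([depth_mm, w_mm])
    y_s_at = y_s0 + params.apo_slope * (pos[:, 1] - cx)
    rel = pos[:, 0] - y_s_at
    level = np.where(rel < 0, 0.25, np.where(rel < h0, 0.5, 0.2))
    refl = level * rng.rayleigh(1.0, n_bg)

    xs = np.linspace(0.3, w_mm - 0.3, 25)
    sup_poly = np.column_stack([y_s0 + params.apo_slope * (xs - cx), xs])
    deep_poly = np.column_stack([y_s0 + h0 + params.apo_slope * (xs - cx), xs])
    skin_poly = np.column_stack([np.full_like(xs, 1.0), xs])
    structures = [(sup_poly, 6.0), (deep_poly, 6.0), (skin_poly, 4.0)]

    all_pos = [pos]
    all_refl = [refl]
    for poly, boost in structures:
        p, gain = _sample_polyline(poly, rng)
        all_pos.append(p)
        all_refl.append(boost * gain)

    t = np.arange(params.n_frames) / params.frame_rate_hz
    pulse = twitch_pulse(
        t, params.stimulus_onsets_s, params.tau_rise_s, params.tau_decay_s
    )
    disp = _twitch_displacement(params, pulse)
    shape = (int(round(depth_mm / calib_ax)), int(round(w_mm / calib_lat)))
    frames = render_frames(
        np.vstack(all_pos),
        np.concatenate(all_refl),
        disp,
        params.n_frames,
        shape,
        params.calib_mm_per_px,
        params.psf_sigma_mm,
    )
    gt = GroundTruth(
        time_s=t,
        length_mm=params.resting_muscle_length_mm - params.shortening_mm * pulse,
        thickness_mm=h0 + params.thickening_mm * pulse,
        displacement=disp,
    )
    seg = Segmentation(
        superficial=np.column_stack([sup_poly[:, 0] / calib_ax, sup_poly[:, 1] / calib_lat]),
        deep=np.column_stack([deep_poly[:, 0] / calib_ax, deep_poly[:, 1] / calib_lat]),
    )
    meta = {
        "scene": "twitch",
        "stimulus_onsets_s": params.stimulus_onsets_s.tolist(),
        "resting_thickness_mm": h0,
    }
    seq = ImageSequence(frames, params.frame_rate_hz, params.calib_mm_per_px, meta)
    return seq, gt, seg


# ---------------------------------------------------------------------------
# M-wave grid
# ---------------------------------------------------------------------------


@dataclass
class MWaveGridParams:
    """Trigger-locked M-wave trains over an electrode grid.

    The per-channel M-wave is a biphasic template (first derivative of a
    Gaussian, 15 ms) scaled by a 2-D Gaussian spatial profile centred between
    the two middle electrode columns, delayed per row to mimic propagation,
    plus white noise, optional powerline interference, and injectable
    bad-channel failure modes.
    """

    grid: GridGeometry = field(default_factory=GridGeometry)
    fs_hz: float = 2048.0
    stim_rate_pps: float = 1.0
    duration_s: float = 20.0
    first_stim_s: float = 0.5
    template_duration_ms: float = 15.0
    template_peak_mV: float = 1.0
    template_latency_ms: float = 5.0
    profile_center: Optional[tuple[float, float]] = None  # (row, col), electrode units
    profile_sigma: tuple[float, float] = (3.0, 1.8)
    prop_delay_ms_per_row: float = 0.5
    noise_rms_uV: float = 10.0
    powerline_uV: float = 0.0
    powerline_hz: float = 50.0
    open_contact_noise_factor: float = 50.0
    bad_channels: dict = field(default_factory=dict)
    seed: SeedLike = 0

    def __post_init__(self) -> None:
        if self.stim_rate_pps * self.duration_s < 1:
            raise ValidationError("duration too short for a single stimulus")
        if self.duration_s <= self.first_stim_s:
            raise ValidationError("duration too short for a single stimulus")
        if self.noise_rms_uV < 0:
            raise ValidationError("noise RMS must be non-negative")
        for ch, mode in self.bad_channels.items():
            if not (0 <= int(ch) < self.grid.n_channels):
                raise ValidationError(f"bad channel index {ch} outside the grid")
            if mode not in {"open_contact", "short_circuit_pair", "artifact_burst"}:
                raise ValidationError(f"unknown failure mode {mode!r}")

    @property
    def trigger_samples(self) -> np.ndarray:
        spacing = int(round(self.fs_hz / self.stim_rate_pps))
        start = int(round(self.first_stim_s * self.fs_hz))
        n_total = int(round(self.duration_s * self.fs_hz))
        trig = start + spacing * np.arange(
            int((self.duration_s - self.first_stim_s) * self.stim_rate_pps) + 1
        )
        return trig[trig < n_total]

    def template_waveform(self, fs_hz: Optional[float] = None) -> np.ndarray:
        """The nominal (unit-profile) template sampled at ``fs_hz``, in uV."""
        fs = fs_hz or self.fs_hz
        n = int(round(self.template_duration_ms / 1000 * fs))
        tt = (np.arange(n) / fs) * 1000.0  # ms
        return _gauss_deriv(tt, self.template_duration_ms) * self.template_peak_mV * 1000.0


def _gauss_deriv(t_ms: np.ndarray, duration_ms: float) -> np.ndarray:
    """Biphasic pulse: first derivative of a Gaussian, unit peak, support
    ``[0, duration_ms]`` (clipped to ~0 outside)."""
    t0 = duration_ms / 2
    sigma = duration_ms / 7
    x = (np.asarray(t_ms, dtype=float) - t0) / sigma
    w = -x * np.exp(-0.5 * x**2)
    w[(t_ms < 0) | (t_ms > duration_ms)] = 0.0
    return w / math.exp(-0.5)  # peak of |x e^{-x^2/2}| is at |x|=1


def simulate_mwave_grid(params: MWaveGridParams) -> EMGRecording:
    """Simulate the monopolar grid recording with trigger-locked M-waves."""
    rng = _make_rng(params.seed)
    grid = params.grid
    fs = params.fs_hz
    n = int(round(params.duration_s * fs))
    trig = params.trigger_samples
    if trig.size < 1:
        raise ValidationError("duration too short for a single stimulus")
    chan_map = default_channel_map(grid)
    center = params.profile_center or ((grid.rows - 1) / 2, (grid.cols - 1) / 2)
    sr, sc = params.profile_sigma

    samples = np.zeros((grid.n_channels, n))
    n_tpl = int(round(params.template_duration_ms / 1000 * fs)) + 4
    for ch in range(grid.n_channels):
        row, col = chan_map[ch]
        amp = math.exp(
            -((row - center[0]) ** 2) / (2 * sr**2)
            - ((col - center[1]) ** 2) / (2 * sc**2)
        )
        delay_ms = params.template_latency_ms + params.prop_delay_ms_per_row * abs(
            row - center[0]
        )
        k = np.arange(n_tpl)
        t_ms = k / fs * 1000.0 - delay_ms
        wave = amp * params.template_peak_mV * 1000.0 * _gauss_deriv(
            t_ms, params.template_duration_ms
        )
        for t0 in trig:
            hi = min(t0 + n_tpl, n)
            samples[ch, t0:hi] += wave[: hi - t0]
    if params.noise_rms_uV > 0:
        samples += rng.normal(0.0, params.noise_rms_uV, samples.shape)
    if params.powerline_uV > 0:
        tt = np.arange(n) / fs
        phase = rng.uniform(0, 2 * math.pi)
        line = np.sin(2 * math.pi * params.powerline_hz * tt + phase)
        gains = params.powerline_uV * (0.8 + 0.4 * rng.random(grid.n_channels))
        samples += gains[:, None] * line[None, :]

    # Failure modes are applied after clean construction so that a shorted
    # channel copies its neighbour's *final* trace.
    for ch, mode in sorted(params.bad_channels.items()):
        ch = int(ch)
        if mode == "open_contact":
            nominal = params.noise_rms_uV if params.noise_rms_uV > 0 else 1.0
            samples[ch] = rng.normal(
                0.0, params.open_contact_noise_factor * nominal, n
            )
        elif mode == "short_circuit_pair":
            row, col = chan_map[ch]
            partner = ch + 1 if (ch + 1 in chan_map and chan_map[ch + 1][1] == col) else ch - 1
            samples[ch] = samples[partner]
        elif mode == "artifact_burst":
            nominal = params.noise_rms_uV if params.noise_rms_uV > 0 else 1.0
            burst_len = int(0.1 * fs)
            for _ in range(3):
                t0 = rng.integers(0, n - burst_len)
                burst = rng.normal(0.0, 20 * nominal, burst_len) * np.hanning(burst_len)
                samples[ch, t0 : t0 + burst_len] += burst

    return EMGRecording(
        samples=samples,
        fs_hz=fs,
        grid=grid,
        trigger_samples=trig,
        channel_map=chan_map,
    )


# ---------------------------------------------------------------------------
# Electrode-interface test signals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceCircuit:
    """Lumped electrode-skin model: R_series + (R_parallel || C_parallel).

    A two-electrode measurement sees two interfaces plus tissue in series;
    the lumped values represent that series total.
    """

    R_series_ohm: float = 1e3
    R_parallel_ohm: float = 1e6
    C_parallel_F: float = 4.7e-9

    def __post_init__(self) -> None:
        if self.R_series_ohm < 0 or self.C_parallel_F < 0:
            raise ValidationError("circuit values must be non-negative")
        if self.R_parallel_ohm < 0:
            raise ValidationError("circuit values must be non-negative")

    def impedance(self, freq_hz) -> np.ndarray:
        """Complex impedance Z(f) = R_s + R_p / (1 + j 2 pi f R_p C_p)."""
        f = np.asarray(freq_hz, dtype=float)
        jw = 2j * math.pi * f
        if np.isinf(self.R_parallel_ohm):
            if self.C_parallel_F == 0:
                raise ValidationError("open parallel branch has no finite impedance")
            par = 1.0 / (jw * self.C_parallel_F)
        else:
            par = self.R_parallel_ohm / (1.0 + jw * self.R_parallel_ohm * self.C_parallel_F)
        return self.R_series_ohm + par


DEFAULT_SWEEP_HZ = (10.0, 20.0, 50.0, 100.0, 159.0, 200.0, 350.0, 500.0, 700.0, 1000.0)


def simulate_interface_signals(
    circuit: InterfaceCircuit,
    freqs_hz: Sequence[float] = DEFAULT_SWEEP_HZ,
    current_pp_A: float = 200e-9,
    fs_hz: float = 10000.0,
    noise_rms_V: float = 0.0,
    duration_s: float = 2.0,
    seed: SeedLike = 0,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Per-frequency (voltage, current) sinusoid pairs through the circuit.

    The injected current is ``(I_pp/2) sin(2 pi f t)``; the voltage is the
    current scaled and phase-shifted by the complex impedance, plus additive
    white noise on the voltage channel. Records are long enough for at least
    ten full cycles at every frequency.
    """
    rng = _make_rng(seed)
    out: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for f in freqs_hz:
        if not (0 < f < fs_hz / 2):
            raise ValidationError(f"frequency {f} Hz outside (0, fs/2)")
        dur = max(duration_s, 10.0 / f)
        nsamp = int(math.ceil(dur * fs_hz))
        t = np.arange(nsamp) / fs_hz
        amp_i = current_pp_A / 2
        i_tr = amp_i * np.sin(2 * math.pi * f * t)
        z = complex(circuit.impedance(f))
        v_tr = amp_i * abs(z) * np.sin(2 * math.pi * f * t + math.atan2(z.imag, z.real))
        if noise_rms_V > 0:
            v_tr = v_tr + rng.normal(0.0, noise_rms_V, nsamp)
        out[float(f)] = (v_tr, i_tr)
    return out
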