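"""Synthetic two-channel capillary movies with known ground truth.

Real acquisitions of the rat retinal microvasculature are two-channel
confocal time series: a plasma-dye channel showing the vessel lumen and a
labelled-RBC channel showing sparse bright cells advected through the
network.  This module renders such movies from an explicit scene model so
that every downstream stage (registration, kymograph velocimetry, spot
counting, diametry) can be validated against exact ground truth:

* vessels are polyline centrelines dressed with a Gaussian-blurred
  top-hat cross-section of known diameter;
* labelled cells are Gaussian blobs of fixed physical FWHM (default
  6.5 µm, the diameter of a rat RBC) advected along the centreline at a
  prescribed, optionally sinusoidally modulated, speed;
* frames can be corrupted by Poisson shot noise, Gaussian read noise and
  small whole-frame translational jitter.

Spot positions are evaluated at real-valued (sub-pixel) coordinates and
integrated over pixel areas, so trajectories carry no rasterisation bias
and total flux is conserved.  Jitter is applied analytically (the scene
is translated before rendering), so a jittered frame equals the
jitter-free frame resampled at shifted coordinates, exactly.

Default calibrations mirror the two acquisition modes of the study this
package targets: ~4.93 µm/px at ~58.25 fps for the two-channel speed
series and ~1.23 µm/px at 15.23 fps for single-channel diameter series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import erf

from .core_io import ImageSeries, VesselPath

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------


@dataclass
class VesselSpec:
    """One vessel of the synthetic network."""

    path: VesselPath
    diameter_um: float = 8.0
    mean_speed_um_s: float = 1000.0
    modulation_amplitude: float = 0.0  # fraction a of v(t) = v̄(1 + a sin 2πt/T)
    modulation_period_s: float = 10.0
    spot_rate_per_s: float = 5.0

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if not self.mean_speed_um_s > 0:
            raise ValueError("mean_speed_um_s must be positive")
        if not 0.0 <= self.modulation_amplitude <= 0.5:
            raise ValueError("modulation_amplitude must be in [0, 0.5]")

    # -- exact kinematics ---------------------------------------------------

    def speed_um_s(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous speed v(t) = v̄ (1 + a sin(2π t / T))."""
        if self.modulation_amplitude == 0.0:
            return self.mean_speed_um_s * np.ones_like(np.asarray(t_s, dtype=float))
        w = 2.0 * math.pi / self.modulation_period_s
        return self.mean_speed_um_s * (
            1.0 + self.modulation_amplitude * np.sin(w * np.asarray(t_s, dtype=float))
        )

    def arc_travel_um(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Closed-form distance travelled since t=0: ∫₀ᵗ v(τ) dτ."""
        t = np.asarray(t_s, dtype=float)
        if self.modulation_amplitude == 0.0:
            return self.mean_speed_um_s * t
        w = 2.0 * math.pi / self.modulation_period_s
        return self.mean_speed_um_s * (
            t + self.modulation_amplitude / w * (1.0 - np.cos(w * t))
        )

    def mean_speed_in_window(self, t0_s: float, t1_s: float) -> float:
        """Exact mean speed over [t0, t1), from the closed-form integral."""
        return float(
            (self.arc_travel_um(t1_s) - self.arc_travel_um(t0_s)) / (t1_s - t0_s)
        )


@dataclass
class SynthSpec:
    """Full specification of a synthetic acquisition."""

    image_size: tuple[int, int] = (64, 192)  # (H, W)
    pixel_size_um: float = 4.93
    frame_rate_fps: float = 58.25
    duration_s: float = 3.0
    vessels: list[VesselSpec] = field(default_factory=list)
    spot_diameter_um: float = 6.5
    psf_sigma_um: float = 0.0
    background_level: float = 10.0
    plasma_amplitude: float = 60.0
    rbc_amplitude: float = 120.0
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0  # 0 disables shot noise
    jitter_max_px: float = 0.0
    jitter_sd_px: float = 0.0
    jitter_integer: bool = False  # round drawn jitter to whole pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.spot_diameter_um > 0:
            raise ValueError("spot_diameter_um must be positive")
        if self.duration_s * self.frame_rate_fps < 2:
            raise ValueError("need at least 2 frames (duration_s * fps >= 2)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_fps))

    def spot_sigma_px(self) -> float:
        """Effective Gaussian sigma of a rendered cell, in pixels."""
        s_cell = (self.spot_diameter_um / self.pixel_size_um) / FWHM_PER_SIGMA
        s_psf = self.psf_sigma_um / self.pixel_size_um
        return math.hypot(s_cell, s_psf)

    def approx_spot_snr(self) -> float:
        """Peak-pixel spot amplitude over background noise SD.

        SNR ≈ P / sqrt(B / poisson_scale + gaussian_sd²) where P is the
        brightest pixel of a centred spot and B the background level.
        Infinite when all noise is off.
        """
        s = self.spot_sigma_px()
        frac = erf(0.5 / (s * math.sqrt(2.0)))
        peak = self.rbc_amplitude * 2.0 * math.pi * s * s * (frac / (s * math.sqrt(2.0 * math.pi))) ** 2
        var = self.gaussian_sd**2
        if self.poisson_scale > 0:
            var += self.background_level / self.poisson_scale
        if var == 0:
            return math.inf
        return float(peak / math.sqrt(var))


@dataclass
class GroundTruth:
    """Everything the renderer knows that an analysis must recover.

    Attributes
    ----------
    trajectories
        DataFrame with columns frame, spot_id, vessel_id, x, y, arc_px —
        exact sub-pixel spot centres per frame.
    speeds
        DataFrame with columns frame, vessel_id, speed_um_s — the exact
        instantaneous speed at each frame's start time.
    counts
        DataFrame with columns frame, vessel_id, count — number of spots
        of that vessel inside the image on that frame.
    jitter
        (T, 2) array of applied per-frame (dx, dy) scene shifts.
    diameters_um
        True diameter per vessel_id.
    vessels
        The generating :class:`VesselSpec` objects (exact kinematics).
    """

    trajectories: pd.DataFrame
    speeds: pd.DataFrame
    counts: pd.DataFrame
    jitter: np.ndarray
    diameters_um: dict[str, float]
    vessels: dict[str, VesselSpec]

    def mean_speed_in_window(self, vessel_id: str, t0_s: float, t1_s: float) -> float:
        return self.vessels[vessel_id].mean_speed_in_window(t0_s, t1_s)


# ---------------------------------------------------------------------------
# Polyline geometry
# ---------------------------------------------------------------------------


class _ArcPath:
    """Arc-length parameterisation of a polyline, in pixel units."""

    def __init__(self, path: VesselPath):
        v = path.as_array()
        seg = np.diff(v, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        self.cum = np.concatenate([[0.0], np.cumsum(seglen)])
        self.length = float(self.cum[-1])
        self.verts = v

    def point_at(self, s_px: np.ndarray) -> np.ndarray:
        """(N, 2) array of (x, y) at arc positions s (clipped to path)."""
        s = np.clip(np.asarray(s_px, dtype=float), 0.0, self.length)
        x = np.interp(s, self.cum, self.verts[:, 0])
        y = np.interp(s, self.cum, self.verts[:, 1])
        return np.stack([x, y], axis=-1)


def _segment_distance(
    px: np.ndarray, py: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distance from grid points (px, py) to segment a→b."""
    ab = b - a
    denom = float(ab @ ab)
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))


def distance_to_path(path: VesselPath, image_size: tuple[int, int],
                     shift: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Per-pixel distance (px) to a polyline translated by ``shift``."""
    h, w = image_size
    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.astype(float) - shift[0]
    ys = ys.astype(float) - shift[1]
    v = path.as_array()
    d = np.full((h, w), np.inf)
    for a, b in zip(v[:-1], v[1:]):
        np.minimum(d, _segment_distance(xs, ys, a, b), out=d)
    return d


def tube_profile(distance_px: np.ndarray, radius_px: float, sigma_px: float) -> np.ndarray:
    """Cross-section intensity of a blurred top-hat tube, in [0, 1].

    The 1-D convolution of a unit top-hat of half-width R with a Gaussian
    of width sigma: 0.5 (erf((R−d)/σ√2) + erf((R+d)/σ√2)); a hard edge in
    the sigma → 0 limit.
    """
    if sigma_px <= 1e-9:
        return (distance_px <= radius_px).astype(float)
    s = sigma_px * math.sqrt(2.0)
    return 0.5 * (erf((radius_px - distance_px) / s) + erf((radius_px + distance_px) / s))


def _render_spots(
    canvas: np.ndarray, centres: np.ndarray, amplitude: float, sigma_px: float
) -> None:
    """Add pixel-integrated Gaussian blobs at real-valued centres (in place)."""
    h, w = canvas.shape
    half = int(math.ceil(4.0 * sigma_px + 2.0))
    s2 = sigma_px * math.sqrt(2.0)
    norm = amplitude * 2.0 * math.pi * sigma_px**2
    for cx, cy in centres:
        x0, x1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
        y0, y1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c, dtype=float)
        ys = np.arange(y0c, y1c, dtype=float)
        ix = 0.5 * (erf((xs + 0.5 - cx) / s2) - erf((xs - 0.5 - cx) / s2))
        iy = 0.5 * (erf((ys + 0.5 - cy) / s2) - erf((ys - 0.5 - cy) / s2))
        canvas[y0c:y1c, x0c:x1c] += norm * np.outer(iy, ix)


def spot_flux(spec: SynthSpec) -> float:
    """Total integrated intensity of one rendered spot."""
    return float(spec.rbc_amplitude * 2.0 * math.pi * spec.spot_sigma_px() ** 2)


# ---------------------------------------------------------------------------
# Network templates
# ---------------------------------------------------------------------------


def make_network(
    template: Literal["simple", "branching"],
    image_size: tuple[int, int],
    pixel_size_um: float,
    seed: int = 0,
) -> list[VesselSpec]:
    """Build a small vessel network for synthesis.

    ``simple`` is a single straight horizontal capillary spanning 80% of
    the image width.  ``branching`` adds an arteriole trunk with child
    capillaries leaving from trunk vertices and a draining venule; child
    geometry is randomised by ``seed`` but every child's first vertex
    coincides with a vertex of its parent.  Diameters are drawn in the
    5–20 µm range typical of the retinal plexus.
    """
    h, w = image_size
    rng = np.random.default_rng(seed)
    if template == "simple":
        if w < 20 or h < 8:
            raise ValueError(f"image {h}x{w} too small for the simple template")
        x0, x1 = 0.1 * (w - 1), 0.9 * (w - 1)
        y = (h - 1) / 2.0
        path = VesselPath("v0", "SL", "C", ((x0, y), (x1, y)))
        return [VesselSpec(path=path, diameter_um=min(8.0, 0.45 * h * pixel_size_um))]
    if template != "branching":
        raise ValueError(f"unknown template {template!r}")
    if w < 48 or h < 32:
        raise ValueError(f"image {h}x{w} too small for the branching template")
    y_mid = (h - 1) / 2.0
    xs = np.linspace(0.08 * (w - 1), 0.92 * (w - 1), 5)
    trunk_verts = tuple((float(x), y_mid) for x in xs)
    trunk = VesselPath("A", "SL", "A3", trunk_verts)
    specs = [
        VesselSpec(
            path=trunk,
            diameter_um=float(rng.uniform(10.0, 20.0)),
            mean_speed_um_s=float(rng.uniform(1500.0, 4000.0)),
        )
    ]
    for i, sign in enumerate((-1.0, 1.0)):
        origin = trunk_verts[i + 1]
        dx = float(rng.uniform(0.15, 0.3)) * (w - 1)
        dy = sign * float(rng.uniform(0.25, 0.4)) * (h - 1)
        end = (
            min(max(origin[0] + dx, 0.0), w - 1.0),
            min(max(origin[1] + dy, 0.0), h - 1.0),
        )
        child = VesselPath(f"C{i}", "SL" if i == 0 else "DL", "C", (origin, end))
        specs.append(
            VesselSpec(
                path=child,
                diameter_um=float(rng.uniform(5.0, 9.0)),
                mean_speed_um_s=float(rng.uniform(300.0, 1200.0)),
            )
        )
    vend = trunk_verts[-1]
    vein = VesselPath(
        "V", "SL", "V3", (vend, (vend[0], min(vend[1] + 0.35 * h, h - 1.0)))
    )
    specs.append(
        VesselSpec(
            path=vein,
            diameter_um=float(rng.uniform(10.0, 18.0)),
            mean_speed_um_s=float(rng.uniform(800.0, 2000.0)),
        )
    )
    return specs


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _initial_spots(spec: SynthSpec, vessel: VesselSpec, arc: _ArcPath,
                   rng: np.random.Generator) -> np.ndarray:
    """Initial arc positions (px).  The steady-state spot count is
    spot_rate × transit time; spots recirculate (respawn at the path
    origin on exit), keeping the per-frame count stationary.  Spots are
    spread at near-equal arc spacing (random phase, ±30% per-spot
    perturbation) so the mean spacing implied by the rate is also the
    minimum spacing, up to that perturbation; because all spots of a
    vessel share one speed profile, spacing is preserved over time."""
    transit_s = arc.length * spec.pixel_size_um / vessel.mean_speed_um_s
    n = max(1, int(round(vessel.spot_rate_per_s * transit_s)))
    pitch = arc.length / n
    phase = rng.uniform(0.0, pitch)
    perturb = rng.uniform(-0.3, 0.3, size=n) * pitch
    return np.mod(np.arange(n) * pitch + phase + perturb, arc.length)


def render_movie(spec: SynthSpec) -> tuple[ImageSeries, GroundTruth]:
    """Render a two-channel movie (plasma + rbc) with ground truth.

    The plasma channel is a static tube rendering of all vessels plus
    background; the rbc channel contains the advected spots.  The same
    per-frame jitter shift is applied to both channels; noise (Poisson
    then Gaussian) is applied last, independently per channel and frame.
    """
    return _render(spec, two_channel=True)


def render_diameter_series(spec: SynthSpec) -> tuple[ImageSeries, GroundTruth]:
    """Render a single-channel (plasma only) diameter series.

    Defaults for this acquisition mode are ~1.23 µm/px at 15.23 fps; the
    vessel cross-section is a Gaussian-blurred top-hat of known true
    diameter, so FWHM estimates can be validated analytically.
    """
    return _render(spec, two_channel=False)


def _render(spec: SynthSpec, two_channel: bool) -> tuple[ImageSeries, GroundTruth]:
    h, w = spec.image_size
    p = spec.pixel_size_um
    f = spec.frame_rate_fps
    n_frames = spec.n_frames
    # independent streams per purpose: spot layout is identical whether or
    # not jitter/noise are enabled, so paired clean/corrupted renders of
    # one seed share the same scene
    rng_spots = np.random.default_rng([spec.seed, 0])
    rng_jitter = np.random.default_rng([spec.seed, 1])
    rng_noise = np.random.default_rng([spec.seed, 2])
    arcs = {v.path.vessel_id: _ArcPath(v.path) for v in spec.vessels}

    for v in spec.vessels:
        arc = arcs[v.path.vessel_id]
        v_max = v.mean_speed_um_s * (1.0 + v.modulation_amplitude)
        if v_max / (p * f) > arc.length:
            raise ValueError(
                f"{v.path.vessel_id}: per-frame displacement "
                f"{v_max / (p * f):.1f} px exceeds path length {arc.length:.1f} px; "
                "increase the frame rate or use a longer vessel"
            )

    # jitter: frame 0 is the reference (0, 0)
    jitter = np.zeros((n_frames, 2))
    if spec.jitter_sd_px > 0:
        jitter[1:] = rng_jitter.normal(0.0, spec.jitter_sd_px, size=(n_frames - 1, 2))
        if spec.jitter_max_px > 0:
            np.clip(jitter, -spec.jitter_max_px, spec.jitter_max_px, out=jitter)
        if spec.jitter_integer:
            np.round(jitter, out=jitter)

    # initial spot arc positions (before advection)
    spot_origin: dict[str, np.ndarray] = {
        v.path.vessel_id: _initial_spots(spec, v, arcs[v.path.vessel_id], rng_spots)
        for v in spec.vessels
    }

    psf_sigma_px = spec.psf_sigma_um / p
    plasma_static: np.ndarray | None = None

    def plasma_frame(shift: tuple[float, float]) -> np.ndarray:
        img = np.full((h, w), float(spec.background_level))
        for v in spec.vessels:
            d = distance_to_path(v.path, (h, w), shift=shift)
            r_px = (v.diameter_um / 2.0) / p
            img += spec.plasma_amplitude * tube_profile(d, r_px, psf_sigma_px)
        return img

    times = np.arange(n_frames) / f
    spot_sigma = spec.spot_sigma_px()
    traj_rows: list[tuple] = []
    count_rows: list[tuple] = []
    n_channels = 2 if two_channel else 1
    frames = np.zeros((n_frames, h, w, n_channels), dtype=np.float32)

    for k in range(n_frames):
        dx, dy = jitter[k]
        if plasma_static is None or (dx, dy) != (0.0, 0.0):
            plasma = plasma_frame((dx, dy)) if (dx, dy) != (0.0, 0.0) else None
            if plasma is None:
                plasma_static = plasma_frame((0.0, 0.0))
                plasma = plasma_static
        else:
            plasma = plasma_static
        frames[k, :, :, 0] = plasma

        if two_channel:
            rbc = np.full((h, w), float(spec.background_level))
            for v in spec.vessels:
                vid = v.path.vessel_id
                arc = arcs[vid]
                travel_px = float(np.asarray(v.arc_travel_um(times[k]))) / p
                s = np.mod(spot_origin[vid] + travel_px, arc.length)
                pts = arc.point_at(s)
                centres = pts + np.array([dx, dy])
                _render_spots(rbc, centres, spec.rbc_amplitude, spot_sigma)
                inside = (
                    (centres[:, 0] >= 0)
                    & (centres[:, 0] <= w - 1)
                    & (centres[:, 1] >= 0)
                    & (centres[:, 1] <= h - 1)
                )
                count_rows.append((k, vid, int(inside.sum())))
                for j, ((x, y), si) in enumerate(zip(centres, s)):
                    traj_rows.append((k, j, vid, float(x), float(y), float(si)))
            frames[k, :, :, 1] = rbc

    # noise, per channel per frame, after scene composition
    if spec.poisson_scale > 0:
        lam = np.clip(frames.astype(np.float64), 0.0, None) * spec.poisson_scale
        frames = (rng_noise.poisson(lam) / spec.poisson_scale).astype(np.float32)
    if spec.gaussian_sd > 0:
        frames = frames + rng_noise.normal(
            0.0, spec.gaussian_sd, size=frames.shape
        ).astype(np.float32)

    channel_names = ["plasma", "rbc"] if two_channel else ["plasma"]
    series = ImageSeries(
        frames=frames, channel_names=channel_names, pixel_size_um=p, frame_rate_fps=f
    )

    speeds = pd.DataFrame(
        [
            (k, v.path.vessel_id, float(np.asarray(v.speed_um_s(times[k]))))
            for k in range(n_frames)
            for v in spec.vessels
        ],
        columns=["frame", "vessel_id", "speed_um_s"],
    )
    truth = GroundTruth(
        trajectories=pd.DataFrame(
            traj_rows, columns=["frame", "spot_id", "vessel_id", "x", "y", "arc_px"]
        ),
        speeds=speeds,
        counts=pd.DataFrame(count_rows, columns=["frame", "vessel_id", "count"]),
        jitter=jitter,
        diameters_um={v.path.vessel_id: v.diameter_um for v in spec.vessels},
        vessels={v.path.vessel_id: v for v in spec.vessels},
    )
    return series, truth
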