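"""Vessel diametry: FWHM of intensity profiles across line probes.

The operational vessel diameter is the full width at half maximum of the
plasma-channel intensity profile along a short line drawn perpendicular
to the vessel axis.  For in vivo series every 100th frame of a 30 s
sequence is measured (plus the temporal average frame, used for probe
placement); histology mode measures a single projection image.

The FWHM rule: background is the mean of the outer 10% of samples at
each end of the profile; the half level sits midway between background
and peak; the two half-level crossings are located by linear
interpolation on each side of the peak and their distance, in µm, is the
width.  Profiles without a crossing on either side are flagged and
excluded from output tables.  The rule is invariant to affine intensity
transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import ImageSeries, LineProbe, logger, make_table
import pandas as pd


@dataclass
class Profile:
    """Sampled intensity profile across one probe."""

    positions_um: np.ndarray
    intensities: np.ndarray
    background: float = float("nan")
    peak: float = float("nan")
    fwhm_um: float | None = None
    flagged: bool = False


def extract_frames(
    series: ImageSeries, every_n: int = 100, span_s: float = 30.0,
    channel: int | str = 0,
) -> tuple[list[int], list[np.ndarray], np.ndarray]:
    """Frames 0, n, 2n, … within a span, plus the span-average frame.

    Returns (frame indices, frames, averaged frame).  A 30 s sequence at
    15.23 fps holds 456 frames, so every-100th sampling yields frames
    {0, 100, 200, 300, 400} — one measurement every ~6.6 s.
    """
    if every_n < 1:
        raise ValueError("every_n must be >= 1")
    # allow a span that misses the duration by less than one frame period
    # (e.g. "30 s" of a 456-frame acquisition at 15.23 fps = 29.94 s)
    if span_s > series.duration_s + 1.0 / series.frame_rate_fps:
        raise ValueError(
            f"span {span_s} s exceeds series duration {series.duration_s:.2f} s"
        )
    n_span = min(int(round(span_s * series.frame_rate_fps)), series.n_frames)
    stack = series.channel(channel)
    indices = list(range(0, n_span, every_n))
    frames = [stack[k] for k in indices]
    averaged = stack[:n_span].astype(np.float64).mean(axis=0)
    return indices, frames, averaged


def sample_profile(
    frame: np.ndarray,
    probe: LineProbe,
    pixel_size_um: float,
    spacing_px: float = 0.25,
) -> Profile:
    """Bilinearly sample the frame along the probe at 0.25 px spacing."""
    (x0, y0), (x1, y1) = probe.endpoints
    length_px = probe.length_px()
    n = int(np.floor(length_px / spacing_px)) + 1
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    vals = ndimage.map_coordinates(
        np.asarray(frame, dtype=np.float64), np.stack([ys, xs]), order=1, mode="nearest"
    )
    return Profile(positions_um=t * length_px * pixel_size_um, intensities=vals)


def fwhm(profile: Profile, tail_fraction: float = 0.1) -> Profile:
    """Fill in background, peak and FWHM of a profile (in place).

    The peak is the maximum of a 3-sample moving mean (guards against
    single-sample noise spikes); it must be an interior sample above
    background, and a half-level crossing must exist on both sides,
    otherwise the profile is flagged.
    """
    y = profile.intensities
    x = profile.positions_um
    if len(y) < 3:
        raise ValueError("profile needs at least 3 samples")
    n_tail = max(1, int(round(tail_fraction * len(y))))
    background = float(np.mean(np.concatenate([y[:n_tail], y[-n_tail:]])))
    smooth = np.convolve(y, np.ones(3) / 3.0, mode="same")
    smooth[0] = smooth[-1] = -np.inf  # peak must be interior
    peak_idx = int(np.argmax(smooth))
    peak = float(y[peak_idx])
    profile.background = background
    profile.peak = peak
    if peak <= background:
        profile.flagged = True
        return profile
    half = background + (peak - background) / 2.0

    # walk outward from the peak on each side to the nearest crossing
    left = None
    for i in range(peak_idx - 1, -1, -1):
        if (y[i] - half) * (y[i + 1] - half) <= 0 and y[i] != y[i + 1]:
            frac = (half - y[i]) / (y[i + 1] - y[i])
            left = float(x[i] + frac * (x[i + 1] - x[i]))
            break
    right = None
    for i in range(peak_idx, len(y) - 1):
        if (y[i] - half) * (y[i + 1] - half) <= 0 and y[i] != y[i + 1]:
            frac = (half - y[i]) / (y[i + 1] - y[i])
            right = float(x[i] + frac * (x[i + 1] - x[i]))
            break
    if left is None or right is None:
        profile.flagged = True
        return profile
    profile.fwhm_um = right - left
    return profile


def measure_diameters(
    source: ImageSeries | np.ndarray,
    probes: list[LineProbe],
    mode: str = "invivo",
    rat_id: str = "rat1",
    every_n: int = 100,
    span_s: float = 30.0,
    channel: int | str = 0,
    pixel_size_um: float | None = None,
    include_aggregate: bool = True,
) -> pd.DataFrame:
    """Measure all probes and return a long-format measurement table.

    ``invivo`` mode expects an :class:`ImageSeries` and measures every
    ``every_n``-th frame within ``span_s`` (window_index = frame index),
    optionally adding a per-probe mean row with window_index = -1.
    ``histology`` mode expects a single 2-D projection image (with
    ``pixel_size_um``) and yields one row per probe.  Flagged profiles
    are logged and skipped.
    """
    rows: list[dict] = []
    if mode == "invivo":
        if not isinstance(source, ImageSeries):
            raise TypeError("invivo mode needs an ImageSeries")
        indices, frames, _avg = extract_frames(source, every_n, span_s, channel)
        p = source.pixel_size_um
        for probe in probes:
            widths = []
            for k, frame in zip(indices, frames):
                prof = fwhm(sample_profile(frame, probe, p))
                if prof.flagged:
                    logger.warning(
                        "%s frame %d: no half-maximum crossing; skipped",
                        probe.vessel_id, k,
                    )
                    continue
                widths.append(prof.fwhm_um)
                rows.append(_row(probe, rat_id, k, prof.fwhm_um, "invivo"))
            if include_aggregate and widths:
                rows.append(_row(probe, rat_id, -1, float(np.mean(widths)), "invivo"))
    elif mode == "histology":
        img = np.asarray(source)
        if img.ndim != 2:
            raise TypeError("histology mode needs a single 2-D image")
        if pixel_size_um is None:
            raise ValueError("histology mode needs pixel_size_um")
        for probe in probes:
            prof = fwhm(sample_profile(img, probe, pixel_size_um))
            if prof.flagged:
                logger.warning("%s: no half-maximum crossing; skipped", probe.vessel_id)
                continue
            rows.append(_row(probe, rat_id, 0, prof.fwhm_um, "histology"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return make_table(rows)


def _row(probe: LineProbe, rat_id: str, window: int, value: float, method: str) -> dict:
    return {
        "rat_id": rat_id,
        "layer": probe.layer,
        "vessel_type": probe.vessel_type,
        "vessel_id": probe.vessel_id,
        "window_index": window,
        "value": value,
        "value_kind": "diameter_um",
        "method": method,
    }
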