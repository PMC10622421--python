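"""Labelled-RBC spot detection and counting (haematocrit proxy).

Each frame of the rbc channel is filtered with a Laplacian of Gaussian
matched to the diameter of a rat RBC (~6.5 µm), candidate centres are
local maxima of the filtered frame passing a prominence threshold and a
mean-raw-intensity threshold (the two knobs used to suppress cells from
out-of-focus layers), and the per-frame count of centres inside a vessel
mask is the proxy measure of haematocrit.  Count maps accumulate the
detection centres pixel-wise over a time interval.

The two thresholds are chosen once (e.g. from the first frame) and then
applied unchanged to all frames, so count series are comparable across
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import ImageSeries, VesselPath
from .velocimetry import sample_path_positions

#: sigma of the LoG for a blob of given diameter: at sigma = d / (2*sqrt(2))
#: the (negated, scale-normalised) LoG response of a matching Gaussian blob
#: is maximal at the blob centre.
LOG_SIGMA_PER_DIAMETER = 1.0 / (2.0 * math.sqrt(2.0))


@dataclass
class SpotParams:
    """Detection parameters, fixed for a whole series."""

    log_size_um: float = 6.5
    prominence: float = 10.0
    min_mean_intensity: float = 0.0
    dilation_radius_um: float = 3.25

    def __post_init__(self) -> None:
        if not self.log_size_um > 0:
            raise ValueError("log_size_um must be positive")
        if not self.prominence > 0:
            raise ValueError("prominence must be positive")
        if self.dilation_radius_um < 0:
            raise ValueError("dilation_radius_um must be >= 0")


@dataclass
class SpotDetections:
    """Per-frame candidate centres for one series."""

    centres: list[np.ndarray]  # per frame: (N, 2) of (x, y)
    image_size: tuple[int, int]
    pixel_size_um: float
    frame_rate_fps: float
    params: SpotParams = field(default_factory=SpotParams)

    @property
    def n_frames(self) -> int:
        return len(self.centres)

    def point_stack(self) -> np.ndarray:
        """Binary (T, H, W) stack with a 1 at each detection centre."""
        h, w = self.image_size
        out = np.zeros((self.n_frames, h, w), dtype=np.uint8)
        for k, c in enumerate(self.centres):
            if len(c):
                xs = np.clip(np.round(c[:, 0]).astype(int), 0, w - 1)
                ys = np.clip(np.round(c[:, 1]).astype(int), 0, h - 1)
                out[k, ys, xs] = 1
        return out

    def dilated_stack(self) -> np.ndarray:
        """Point stack dilated to the approximate size of a rat RBC."""
        r_px = self.params.dilation_radius_um / self.pixel_size_um
        stack = self.point_stack()
        if r_px <= 0:
            return stack
        footprint = _disc(r_px)
        return np.stack([ndimage.binary_dilation(f, footprint) for f in stack]).astype(
            np.uint8
        )


@dataclass
class CountSeries:
    """Per-frame RBC counts in a vessel mask, with a moving average."""

    counts: np.ndarray
    moving_average: np.ndarray
    frame_rate_fps: float
    ma_window_frames: int


def _disc(radius_px: float) -> np.ndarray:
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2) <= radius_px**2


# ---------------------------------------------------------------------------
# Filtering and detection
# ---------------------------------------------------------------------------


def log_filter(
    frame: np.ndarray, size_um: float, pixel_size_um: float, warn: bool = True
) -> np.ndarray:
    """Blob-enhancing filter: negated, scale-normalised Laplacian of Gaussian.

    ``size_um`` is the target blob diameter; sigma = (size/p)/(2·√2) so a
    Gaussian blob of that diameter responds maximally at its centre.
    The response is positive at bright-blob centres and suppresses both
    flat background and much larger structures.
    """
    from .core_io import logger

    sigma = (size_um / pixel_size_um) * LOG_SIGMA_PER_DIAMETER
    if size_um / pixel_size_um < 1.0:
        raise ValueError("blob size below one pixel; cannot filter")
    if warn and sigma < 0.5:
        logger.warning(
            "LoG sigma %.2f px < 0.5 px: blob diameter %.2f um is undersampled "
            "at %.2f um/px", sigma, size_um, pixel_size_um,
        )
    arr = np.asarray(frame, dtype=np.float64)
    raw = ndimage.gaussian_laplace(arr, sigma=sigma)
    # the sampled-Gaussian derivative kernel does not sum to zero at small
    # sigma, so a constant frame would leak through; subtract that bias
    # (linear in the input) so flat regions map exactly to zero
    kernel_sum = float(ndimage.gaussian_laplace(np.ones((1, 1)), sigma=sigma)[0, 0])
    return -(sigma**2) * (raw - kernel_sum * arr)


def _local_prominence(filtered: np.ndarray, radius_px: float) -> np.ndarray:
    """Height of each pixel above the minimum of its neighbourhood.

    A deterministic surrogate for interactive prominence selection: the
    prominence of a candidate maximum is its filtered value minus the
    minimum filtered value within a disc of ``radius_px``.  Raising the
    threshold can only remove detections, never add them.
    """
    footprint = _disc(radius_px)
    return filtered - ndimage.minimum_filter(filtered, footprint=footprint)


def detect_spots(
    filtered: np.ndarray,
    params: SpotParams,
    pixel_size_um: float,
    raw_frame: np.ndarray | None = None,
) -> np.ndarray:
    """Candidate centres on one filtered frame, as an (N, 2) (x, y) array.

    Centres are strict local maxima of the filtered frame whose local
    prominence within a blob-sized neighbourhood reaches
    ``params.prominence`` and whose mean *raw* intensity in a disc of
    radius log_size/2 reaches ``params.min_mean_intensity``.  Maxima
    closer than log_size/2 are merged into the brighter one.
    """
    size_px = params.log_size_um / pixel_size_um
    half = size_px / 2.0
    footprint = _disc(max(half, 1.0))
    is_max = (filtered == ndimage.maximum_filter(filtered, footprint=footprint)) & (
        filtered > 0
    )
    prom = _local_prominence(filtered, max(size_px, 1.0))
    cand = is_max & (prom >= params.prominence)
    ys, xs = np.nonzero(cand)
    if len(xs) == 0:
        return np.empty((0, 2))

    values = filtered[ys, xs]
    order = np.argsort(values)[::-1]  # brightest first
    kept: list[tuple[float, float]] = []
    for i in order:
        x, y = float(xs[i]), float(ys[i])
        if all((x - kx) ** 2 + (y - ky) ** 2 >= half**2 for kx, ky in kept):
            kept.append((x, y))
    centres = np.asarray(kept)

    if raw_frame is not None and params.min_mean_intensity > 0:
        disc = _disc(max(half, 1.0))
        keep = []
        h, w = raw_frame.shape
        r = disc.shape[0] // 2
        for x, y in centres:
            xi, yi = int(round(x)), int(round(y))
            x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
            y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
            patch = np.asarray(raw_frame, dtype=float)[y0:y1, x0:x1]
            d = disc[r - (yi - y0) : r + (y1 - yi), r - (xi - x0) : r + (x1 - xi)]
            keep.append(patch[d].mean() >= params.min_mean_intensity)
        centres = centres[np.asarray(keep, dtype=bool)]
    # deterministic ordering for reproducible outputs
    if len(centres):
        centres = centres[np.lexsort((centres[:, 0], centres[:, 1]))]
    return centres


def detect_series(
    series: ImageSeries, params: SpotParams, channel: int | str = "rbc"
) -> SpotDetections:
    """Run LoG filtering + detection on every frame of a channel."""
    stack = series.channel(channel)
    centres = []
    log_filter(stack[0], params.log_size_um, series.pixel_size_um)  # warn once
    for frame in stack:
        filt = log_filter(frame, params.log_size_um, series.pixel_size_um, warn=False)
        centres.append(
            detect_spots(filt, params, series.pixel_size_um, raw_frame=frame)
        )
    return SpotDetections(
        centres=centres,
        image_size=stack.shape[1:3],
        pixel_size_um=series.pixel_size_um,
        frame_rate_fps=series.frame_rate_fps,
        params=params,
    )


def suggest_params(
    series: ImageSeries,
    channel: int | str = "rbc",
    prominences: np.ndarray | None = None,
) -> pd.DataFrame:
    """Detection count on frame 1 over a prominence grid.

    A reproducible replacement for interactive threshold picking: run it,
    look at the plateau, write the chosen values into the config.
    """
    frame = series.channel(channel)[0]
    filt = log_filter(frame, 6.5, series.pixel_size_um)
    if prominences is None:
        top = float(filt.max())
        prominences = np.linspace(max(top / 50.0, 1e-6), top, 20)
    rows = []
    for prom in prominences:
        params = SpotParams(prominence=float(prom))
        n = len(detect_spots(filt, params, series.pixel_size_um, raw_frame=frame))
        rows.append({"prominence": float(prom), "n_detections": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def vessel_mask(
    paths: list[VesselPath],
    image_size: tuple[int, int],
    pixel_size_um: float,
    diameters_um: dict[str, float] | None = None,
    default_diameter_um: float = 8.0,
) -> np.ndarray:
    """Binary mask of the vessel lumen: centrelines dilated to diameter."""
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    for path in paths:
        d_um = (diameters_um or {}).get(path.vessel_id, default_diameter_um)
        r_px = (d_um / 2.0) / pixel_size_um
        pts = sample_path_positions(path, sample_spacing_px=0.5)
        line = np.zeros((h, w), dtype=bool)
        xs = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        ys = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        line[ys, xs] = True
        mask |= ndimage.binary_dilation(line, _disc(max(r_px, 0.5)))
    return mask


def count_series(
    detections: SpotDetections,
    mask: np.ndarray,
    ma_window_s: float = 0.5,
) -> CountSeries:
    """Per-frame counts inside a mask, with a centred ~0.5 s moving average.

    The moving-average window is round(ma_window_s · f) frames; at the
    edges the window shrinks symmetrically rather than padding.
    """
    if not mask.any():
        raise ValueError("empty vessel mask")
    h, w = mask.shape
    counts = np.zeros(detections.n_frames, dtype=int)
    for k, c in enumerate(detections.centres):
        if len(c):
            xs = np.clip(np.round(c[:, 0]).astype(int), 0, w - 1)
            ys = np.clip(np.round(c[:, 1]).astype(int), 0, h - 1)
            counts[k] = int(mask[ys, xs].sum())
    n_ma = max(1, int(round(ma_window_s * detections.frame_rate_fps)))
    ma = (
        pd.Series(counts.astype(float))
        .rolling(window=n_ma, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return CountSeries(
        counts=counts,
        moving_average=ma,
        frame_rate_fps=detections.frame_rate_fps,
        ma_window_frames=n_ma,
    )


def count_map(
    detections: SpotDetections, t0_s: float, t1_s: float
) -> np.ndarray:
    """Pixel-wise cumulative detection counts over [t0, t1).

    Each detection centre contributes 1 to its (rounded) pixel on its
    frame; the map is the sum over all frames whose start time falls in
    the interval.  The map total equals the number of detections in the
    interval.
    """
    f = detections.frame_rate_fps
    k0 = int(np.ceil(t0_s * f - 1e-9))
    k1 = int(np.ceil(t1_s * f - 1e-9))
    k1 = min(k1, detections.n_frames)
    if k1 <= k0:
        raise ValueError(f"interval [{t0_s}, {t1_s}) s contains no frames")
    h, w = detections.image_size
    out = np.zeros((h, w), dtype=np.int64)
    for k in range(k0, k1):
        c = detections.centres[k]
        if len(c):
            xs = np.clip(np.round(c[:, 0]).astype(int), 0, w - 1)
            ys = np.clip(np.round(c[:, 1]).astype(int), 0, h - 1)
            np.add.at(out, (ys, xs), 1)
    return out


def count_maps_at(
    detections: SpotDetections,
    centres_s: list[float],
    span_s: float = 5.0,
) -> list[np.ndarray]:
    """Count maps for ``span_s``-second intervals centred at given times."""
    duration = detections.n_frames / detections.frame_rate_fps
    out = []
    for tc in centres_s:
        t0 = max(0.0, tc - span_s / 2.0)
        t1 = min(duration, tc + span_s / 2.0)
        out.append(count_map(detections, t0, t1))
    return out
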