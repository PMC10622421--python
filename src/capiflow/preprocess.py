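"""Pre-processing: denoising, frame alignment, temporal projections.

In vivo eye movies drift slightly (breathing, eye drift); every frame is
registered to the first frame by translation only, estimated on the
plasma channel by phase correlation with sub-pixel refinement and then
applied identically to all channels.  Denoising is a per-channel,
per-frame Gaussian or median filter with configurable radius — kept
deliberately simple so downstream measurements do not depend on any
particular denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core_io import ImageSeries, logger


@dataclass
class AlignmentResult:
    """Per-frame shifts and the registered series.

    ``shifts[k] = (dx, dy)`` is the estimated translation of frame k
    relative to frame 0 (x rightward, y downward); the registered frame
    is the input frame shifted by ``-shifts[k]``.  Frame 0 has (0, 0).
    """

    shifts: np.ndarray  # (T, 2) of (dx, dy)
    registered: ImageSeries


def denoise(series: ImageSeries, method: str, radius_px: float) -> ImageSeries:
    """Smooth each channel of each frame independently.

    ``method`` is "gaussian" (sigma = radius) or "median" (disc-like
    square footprint of half-width round(radius)); radius 0 is the
    identity.
    """
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    if radius_px == 0:
        return series
    frames = series.frames
    out = np.empty_like(frames, dtype=np.float32)
    if method == "gaussian":
        for t in range(frames.shape[0]):
            for c in range(frames.shape[3]):
                out[t, :, :, c] = ndimage.gaussian_filter(
                    frames[t, :, :, c].astype(np.float32), sigma=radius_px
                )
    elif method == "median":
        size = 2 * int(round(radius_px)) + 1
        for t in range(frames.shape[0]):
            for c in range(frames.shape[3]):
                out[t, :, :, c] = ndimage.median_filter(
                    frames[t, :, :, c].astype(np.float32), size=size
                )
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return series.with_frames(out)


def align(
    series: ImageSeries,
    reference_channel: int | str = "plasma",
    upsample_factor: int = 20,
    max_shift_px: float | None = None,
    interp_order: int = 1,
) -> AlignmentResult:
    """Register every frame to the first frame by translation.

    The shift of each frame is estimated on ``reference_channel`` by
    phase correlation (sub-pixel refinement by local upsampled cross
    correlation), and the *same* shift is removed from all channels so
    the channels stay co-registered.  Out-of-view pixels are filled with
    the channel median.
    """
    if series.n_frames < 2:
        raise ValueError("alignment needs at least 2 frames")
    ci = series.channel_index(reference_channel)
    ref = series.frames[0, :, :, ci].astype(np.float64)
    if np.ptp(ref) == 0:
        raise ValueError("reference frame is constant; cannot register")
    # mean-subtract and Hann-window before correlating: the plain FFT
    # cross-correlation is otherwise biased toward zero shift by the DC
    # level and by the circular wrap-around of non-periodic content
    window = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    ref = (ref - ref.mean()) * window

    t_frames = series.n_frames
    shifts = np.zeros((t_frames, 2))
    for k in range(1, t_frames):
        mov = series.frames[k, :, :, ci].astype(np.float64)
        mov = (mov - mov.mean()) * window
        (dy, dx), _, _ = phase_cross_correlation(
            ref, mov, upsample_factor=upsample_factor, normalization=None
        )
        # phase_cross_correlation returns the shift that maps mov onto ref;
        # the frame's displacement relative to frame 0 is the negative.
        shifts[k] = (-dx, -dy)
        if max_shift_px is not None and np.hypot(dx, dy) > max_shift_px:
            logger.warning(
                "frame %d: estimated shift (%.2f, %.2f) exceeds max %.2f px",
                k, -dx, -dy, max_shift_px,
            )

    out = np.empty_like(series.frames, dtype=np.float32)
    medians = [
        float(np.median(series.frames[..., c])) for c in range(series.frames.shape[3])
    ]
    out[0] = series.frames[0]
    for k in range(1, t_frames):
        dx, dy = shifts[k]
        for c in range(series.frames.shape[3]):
            out[k, :, :, c] = ndimage.shift(
                series.frames[k, :, :, c].astype(np.float32),
                shift=(-dy, -dx),
                order=interp_order,
                mode="constant",
                cval=medians[c],
            )
    return AlignmentResult(shifts=shifts, registered=series.with_frames(out))


def _window_stack(
    series: ImageSeries, channel: int | str, t0_s: float, t1_s: float
) -> np.ndarray:
    k0, k1 = series.time_to_frame_range(t0_s, t1_s)
    return series.channel(channel)[k0:k1]


def std_projection(
    series: ImageSeries, channel: int | str, t0_s: float | None = None,
    t1_s: float | None = None,
) -> np.ndarray:
    """Pixel-wise population standard deviation over frames in [t0, t1).

    This is the projection used to visualise RBC tracks: moving cells
    raise the temporal variance of the pixels they cross, so the map
    shows a bright ridge along each perfused vessel.
    """
    t0_s = 0.0 if t0_s is None else t0_s
    t1_s = series.duration_s if t1_s is None else t1_s
    stack = _window_stack(series, channel, t0_s, t1_s)
    if stack.shape[0] < 2:
        raise ValueError("std projection needs at least 2 frames in the window")
    return np.std(stack.astype(np.float64), axis=0)


def mean_projection(
    series: ImageSeries, channel: int | str, t0_s: float | None = None,
    t1_s: float | None = None,
) -> np.ndarray:
    t0_s = 0.0 if t0_s is None else t0_s
    t1_s = series.duration_s if t1_s is None else t1_s
    return np.mean(_window_stack(series, channel, t0_s, t1_s).astype(np.float64), axis=0)


def max_projection(
    series: ImageSeries, channel: int | str, t0_s: float | None = None,
    t1_s: float | None = None,
) -> np.ndarray:
    t0_s = 0.0 if t0_s is None else t0_s
    t1_s = series.duration_s if t1_s is None else t1_s
    return np.max(_window_stack(series, channel, t0_s, t1_s), axis=0)
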