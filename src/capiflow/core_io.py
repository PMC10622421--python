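"""Data model and file formats for capillary-flow analysis.

The pipeline operates on multi-frame fluorescence image series of the
retinal microvasculature together with user-supplied vessel ROIs:

* :class:`ImageSeries` — a T×H×W×C intensity stack with physical
  calibration (µm per pixel, frames per second).
* :class:`VesselPath` — a labelled centreline polyline drawn along a
  vessel segment from upstream to downstream.
* :class:`LineProbe` — a short line perpendicular to a vessel axis,
  used for diameter measurement.
* Measurement tables — long-format pandas DataFrames with one row per
  (rat, vessel, window) measurement, the interchange format between the
  imaging stages and the statistics stage.

Conventions used throughout the package: coordinates are 0-based pixel
coordinates with x rightward (columns) and y downward (rows); ROI
vertices refer to the *registered* series.  All randomness flows from a
single integer seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("capiflow")

#: Recognised retinal layers: superficial (SL) and deep (DL) plexus.
LAYERS = ("SL", "DL")

#: Vessel-type labels: arteriole branching generations A2–A4, capillary C,
#: capillary draining directly to a vein Vc, and venule generations V3, V2.
VESSEL_TYPES = ("A2", "A3", "A4", "C", "Vc", "V3", "V2")

#: Column order of the long-format measurement table (CSV header).
TABLE_COLUMNS = (
    "rat_id",
    "layer",
    "vessel_type",
    "vessel_id",
    "window_index",
    "value",
    "value_kind",
    "method",
)

VALUE_KINDS = ("speed_um_s", "diameter_um")
METHODS = ("invivo", "histology")


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageSeries:
    """A calibrated fluorescence time series.

    Parameters
    ----------
    frames
        Array of shape (T, H, W, C) of non-negative intensities.
    channel_names
        One name per channel, e.g. ``["plasma", "rbc"]``.  ``plasma`` is
        the vascular dye channel (FITC), ``rbc`` the labelled-cell
        channel (Cy5).
    pixel_size_um
        Lateral pixel size *p* in µm per pixel.
    frame_rate_fps
        Acquisition rate *f* in frames per second.
    origin_time_s
        Time of frame 0, seconds (defaults to 0).
    """

    frames: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    frame_rate_fps: float
    origin_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 3:
            self.frames = self.frames[..., None]
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (T, H, W, C)")
        t, h, w, c = self.frames.shape
        if t < 1:
            raise ValueError("series needs at least one frame")
        if c not in (1, 2):
            raise ValueError(f"expected 1 or 2 channels, got {c}")
        if len(self.channel_names) != c:
            raise ValueError("channel_names length must equal channel count")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.frame_rate_fps > 0:
            raise ValueError("frame_rate_fps must be positive")

    # -- convenience accessors ------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_fps

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        if not 0 <= channel < self.frames.shape[3]:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the (T, H, W) stack of one channel."""
        return self.frames[..., self.channel_index(channel)]

    def frame_times_s(self) -> np.ndarray:
        """Start time of every frame, in seconds."""
        return self.origin_time_s + np.arange(self.n_frames) / self.frame_rate_fps

    def time_to_frame_range(self, t0_s: float, t1_s: float) -> tuple[int, int]:
        """Half-open frame-index range of frames whose start time lies in [t0, t1)."""
        if not (self.origin_time_s <= t0_s < t1_s):
            raise ValueError("need origin <= t0 < t1")
        f = self.frame_rate_fps
        k0 = int(np.ceil((t0_s - self.origin_time_s) * f - 1e-9))
        k1 = int(np.ceil((t1_s - self.origin_time_s) * f - 1e-9))
        k1 = min(k1, self.n_frames)
        if k1 <= k0:
            raise ValueError(f"window [{t0_s}, {t1_s}) s contains no frames")
        return k0, k1

    def with_frames(self, frames: np.ndarray) -> "ImageSeries":
        return replace(self, frames=frames)


@dataclass(frozen=True)
class VesselPath:
    """Centreline polyline of one vessel segment, upstream → downstream."""

    vessel_id: str
    layer: str
    vessel_type: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"{self.vessel_id}: unknown layer {self.layer!r}")
        if self.vessel_type not in VESSEL_TYPES:
            raise ValueError(
                f"{self.vessel_id}: unknown vessel_type {self.vessel_type!r}"
            )
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 2:
            raise ValueError(f"{self.vessel_id}: path needs >= 2 vertices")
        for a, b in zip(verts, verts[1:]):
            if a == b:
                raise ValueError(
                    f"{self.vessel_id}: duplicated consecutive vertex {a}"
                )

    def as_array(self) -> np.ndarray:
        """Vertices as an (N, 2) float array of (x, y)."""
        return np.asarray(self.vertices, dtype=float)

    def length_px(self) -> float:
        v = self.as_array()
        return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))

    def validate_bounds(self, image_size: tuple[int, int]) -> None:
        h, w = image_size
        for x, y in self.vertices:
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise ValueError(
                    f"{self.vessel_id}: vertex ({x}, {y}) outside image {h}x{w}"
                )


@dataclass(frozen=True)
class LineProbe:
    """A line segment perpendicular to a vessel axis, for FWHM diametry."""

    vessel_id: str
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    layer: str = "SL"
    vessel_type: str = "C"

    def __post_init__(self) -> None:
        (x0, y0), (x1, y1) = self.endpoints
        pts = ((float(x0), float(y0)), (float(x1), float(y1)))
        object.__setattr__(self, "endpoints", pts)
        if pts[0] == pts[1]:
            raise ValueError(f"{self.vessel_id}: probe endpoints coincide")
        if self.length_px() < 3:
            raise ValueError(f"{self.vessel_id}: probe shorter than 3 px")
        if self.layer not in LAYERS:
            raise ValueError(f"{self.vessel_id}: unknown layer {self.layer!r}")
        if self.vessel_type not in VESSEL_TYPES:
            raise ValueError(
                f"{self.vessel_id}: unknown vessel_type {self.vessel_type!r}"
            )

    def length_px(self) -> float:
        (x0, y0), (x1, y1) = self.endpoints
        return float(np.hypot(x1 - x0, y1 - y0))


# ---------------------------------------------------------------------------
# Image series I/O
# ---------------------------------------------------------------------------


def read_series(
    path: str | Path,
    calibration: tuple[float, float],
    channel_names: Sequence[str] | None = None,
) -> ImageSeries:
    """Read a multi-page TIFF stack as an :class:`ImageSeries`.

    ``calibration`` is (pixel_size_um, frame_rate_fps) and always wins over
    any resolution tags embedded in the file (microscope TIFF metadata
    dialects are unreliable; a mismatch is logged as a warning).

    Accepted layouts: (T, H, W) single channel, or (T, C, H, W) with
    C ∈ {1, 2}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        frames = arr[..., None]
    elif arr.ndim == 4:
        if arr.shape[1] > 2:
            raise ValueError(
                f"{path}: expected at most 2 channels on axis 1, got {arr.shape[1]}"
            )
        frames = np.moveaxis(arr, 1, -1)
    else:
        raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")

    with tifffile.TiffFile(path) as tif:
        tags = tif.pages[0].tags
        xres = tags.get("XResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                tag_p = den / num  # pixels per unit -> unit per pixel
                if abs(tag_p - calibration[0]) / calibration[0] > 1e-3:
                    logger.warning(
                        "TIFF resolution tag (%.4g) disagrees with configured "
                        "pixel size (%.4g um/px); using the configuration",
                        tag_p,
                        calibration[0],
                    )

    c = frames.shape[3]
    if channel_names is None:
        channel_names = ["plasma", "rbc"][:c] if c == 2 else ["plasma"]
    return ImageSeries(
        frames=frames,
        channel_names=list(channel_names),
        pixel_size_um=float(calibration[0]),
        frame_rate_fps=float(calibration[1]),
    )


def write_series(series: ImageSeries, path: str | Path) -> None:
    """Write an :class:`ImageSeries` to a multi-page TIFF, bit-exact.

    Two-channel stacks are stored as (T, C, H, W); single-channel as
    (T, H, W).  Pixel size is recorded in the resolution tags.
    """
    path = Path(path)
    frames = series.frames
    if frames.shape[3] == 1:
        data = frames[..., 0]
    else:
        data = np.moveaxis(frames, -1, 1)
    res = 1.0 / series.pixel_size_um
    tifffile.imwrite(path, data, resolution=(res, res))


# ---------------------------------------------------------------------------
# ROI I/O
# ---------------------------------------------------------------------------

ROI_SCHEMA_KEYS = {"vessel_id", "kind", "layer", "vessel_type", "points"}


def read_rois(path: str | Path) -> list[VesselPath | LineProbe]:
    """Read vessel-path and line-probe ROIs from a JSON sidecar.

    Schema::

        {"image_size": [H, W],
         "rois": [{"vessel_id": str, "kind": "path"|"line",
                   "layer": "SL"|"DL", "vessel_type": str,
                   "points": [[x, y], ...]}, ...]}

    Vertices are validated against the declared image size.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if "rois" not in doc or "image_size" not in doc:
        raise ValueError(f"{path}: missing 'rois' or 'image_size'")
    h, w = (int(v) for v in doc["image_size"])
    out: list[VesselPath | LineProbe] = []
    for entry in doc["rois"]:
        missing = ROI_SCHEMA_KEYS - set(entry)
        if missing:
            raise ValueError(f"{path}: ROI entry missing keys {sorted(missing)}")
        kind = entry["kind"]
        pts = [(float(x), float(y)) for x, y in entry["points"]]
        if kind == "path":
            roi: VesselPath | LineProbe = VesselPath(
                vessel_id=entry["vessel_id"],
                layer=entry["layer"],
                vessel_type=entry["vessel_type"],
                vertices=tuple(pts),
            )
            roi.validate_bounds((h, w))
        elif kind == "line":
            if len(pts) != 2:
                raise ValueError(
                    f"{path}: line ROI {entry['vessel_id']} needs exactly 2 points"
                )
            roi = LineProbe(
                vessel_id=entry["vessel_id"],
                endpoints=(pts[0], pts[1]),
                layer=entry["layer"],
                vessel_type=entry["vessel_type"],
            )
            for x, y in pts:
                if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                    raise ValueError(
                        f"{entry['vessel_id']}: endpoint ({x}, {y}) outside "
                        f"image {h}x{w}"
                    )
        else:
            raise ValueError(f"{path}: unknown ROI kind {kind!r}")
        out.append(roi)
    if not out:
        logger.warning("%s: ROI file contains no ROIs", path)
    return out


def write_rois(
    rois: Iterable[VesselPath | LineProbe],
    image_size: tuple[int, int],
    path: str | Path,
) -> None:
    entries = []
    for roi in rois:
        if isinstance(roi, VesselPath):
            entries.append(
                {
                    "vessel_id": roi.vessel_id,
                    "kind": "path",
                    "layer": roi.layer,
                    "vessel_type": roi.vessel_type,
                    "points": [list(v) for v in roi.vertices],
                }
            )
        else:
            entries.append(
                {
                    "vessel_id": roi.vessel_id,
                    "kind": "line",
                    "layer": roi.layer,
                    "vessel_type": roi.vessel_type,
                    "points": [list(v) for v in roi.endpoints],
                }
            )
    doc = {"image_size": [int(image_size[0]), int(image_size[1])], "rois": entries}
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------


def make_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Build a validated long-format measurement table from row dicts."""
    df = pd.DataFrame(list(rows), columns=list(TABLE_COLUMNS))
    validate_table(df)
    return df


def validate_table(df: pd.DataFrame) -> None:
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    if len(df) == 0:
        return
    bad_kind = set(df["value_kind"]) - set(VALUE_KINDS)
    if bad_kind:
        raise ValueError(f"unknown value_kind values {sorted(bad_kind)}")
    bad_method = set(df["method"]) - set(METHODS)
    if bad_method:
        raise ValueError(f"unknown method values {sorted(bad_method)}")
    key = ["rat_id", "vessel_id", "window_index", "value_kind", "method"]
    if df.duplicated(subset=key).any():
        dupes = df[df.duplicated(subset=key, keep=False)][key]
        raise ValueError(f"duplicate measurement keys:\n{dupes}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV with the canonical header."""
    if len(df) == 0:
        raise ValueError("refusing to write an empty measurement table")
    validate_table(df)
    df.loc[:, list(TABLE_COLUMNS)].to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_table(df)
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Run configuration, usually loaded from YAML.

    ``pixel_size_um`` / ``frame_rate_fps`` calibrate the input series and
    take precedence over TIFF metadata; ``seed`` feeds every random
    generator in the pipeline.
    """

    pixel_size_um: float = 4.93
    frame_rate_fps: float = 58.25
    seed: int = 0
    denoise_method: str | None = None
    denoise_radius_px: float = 1.0
    reference_channel: str = "plasma"
    window_s: float = 3.0
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path | None) -> Config:
    if path is None:
        return Config()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in Config.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in doc.items() if k in known}
    extra = {k: v for k, v in doc.items() if k not in known}
    return Config(**kwargs, extra=extra)
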