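"""Wetting-front extraction from paper-microfluidic chip videos.

A wax-printed paper chip carries four straight nitrocellulose channels.
During an assay the sample wicks along each channel and the advancing
liquid-gas interface (the wetting front) darkens the paper behind it.
This module turns a video (or an ordered image stack) of the chip into
per-channel :class:`FlowProfile` objects: front position along the
channel's central axis, in cm, for every frame.

The detector is deliberately simple: intensity on the 1-pixel central
axis of each channel ROI (median over a 3-pixel band when the ROI is
wide enough), baseline-subtracted against a pre-flow frame; the front is
the farthest along-axis pixel whose absolute change exceeds a relative
threshold of the maximum wetted change seen anywhere in that channel.
Capillary fronts cannot recede, so profiles are monotone-enforced.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VideoStack",
    "ChannelROI",
    "ChannelLayout",
    "FlowProfile",
    "track_front",
    "enforce_monotone",
    "frames_to_seconds",
    "read_video",
    "write_profiles_csv",
    "read_profiles_csv",
]


class GeometryError(ValueError):
    """A channel ROI is inconsistent with the frame or chip geometry."""


@dataclass(frozen=True)
class VideoStack:
    """An ordered stack of single-luminance frames plus calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; intensities in any
        consistent scale (uint8 counts or floats).
    frame_rate
        Frames per second (> 0).
    pixel_scale
        Pixels per centimetre (> 0).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_scale: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W); got shape {frames.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ChannelROI:
    """Axis-aligned channel rectangle, 0-based, half-open pixel coords.

    ``axis`` gives the flow direction inside the ROI: ``"+x"`` (left to
    right, the default chip orientation), ``"-x"``, ``"+y"`` or ``"-y"``.
    """

    x0: int
    y0: int
    x1: int
    y1: int
    axis: str = "+x"
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise GeometryError(f"empty ROI {self}")
        if self.axis not in ("+x", "-x", "+y", "-y"):
            raise GeometryError(f"unknown flow axis {self.axis!r}")

    @property
    def along_extent_px(self) -> int:
        return self.x1 - self.x0 if self.axis in ("+x", "-x") else self.y1 - self.y0


@dataclass(frozen=True)
class ChannelLayout:
    """Chip geometry: channel ROIs plus physical channel dimensions.

    Distances in a :class:`FlowProfile` are measured from the ROI's
    upstream edge, i.e. the downstream exit of the loading zone; ROIs
    are therefore expected to cover the channel proper, not the loading
    area (default channel 2.1 cm x 0.3 cm with a 0.3 cm loading square).
    """

    channel_rois: tuple[ChannelROI, ...]
    channel_length_cm: float = 2.1
    channel_width_cm: float = 0.3
    loading_zone_cm: float = 0.3

    def __post_init__(self) -> None:
        rois = tuple(self.channel_rois)
        for i, a in enumerate(rois):
            for b in rois[i + 1 :]:
                if a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1:
                    raise GeometryError(f"ROIs overlap: {a} and {b}")
        object.__setattr__(self, "channel_rois", rois)

    def validate_against(self, stack: VideoStack) -> None:
        _, h, w = stack.frames.shape
        for roi in self.channel_rois:
            if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > w or roi.y1 > h:
                raise GeometryError(f"ROI {roi} outside frame bounds {h}x{w}")
            extent_cm = roi.along_extent_px / stack.pixel_scale
            if extent_cm < 0.95 * self.channel_length_cm:
                raise GeometryError(
                    f"ROI {roi.channel_id} spans {extent_cm:.2f} cm along the flow "
                    f"axis; need >= 95% of channel_length_cm={self.channel_length_cm}"
                )


@dataclass(frozen=True)
class FlowProfile:
    """Wetting-front distance versus frame for one channel.

    ``frame_index`` starts at 0 at the tracking baseline (first frame
    after sample loading); ``distance_cm`` is measured from the
    loading-zone exit.  ``dry`` flags a channel where no intensity
    change was ever observed.
    """

    channel_id: str
    frame_index: np.ndarray
    distance_cm: np.ndarray
    frame_rate: float
    dry: bool = False

    def __post_init__(self) -> None:
        fi = np.asarray(self.frame_index, dtype=int)
        d = np.asarray(self.distance_cm, dtype=float)
        if fi.shape != d.shape:
            raise ValueError("frame_index and distance_cm must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        object.__setattr__(self, "frame_index", fi)
        object.__setattr__(self, "distance_cm", d)

    @property
    def times_s(self) -> np.ndarray:
        return frames_to_seconds(self.frame_index, self.frame_rate)

    def __len__(self) -> int:
        return len(self.frame_index)


def frames_to_seconds(frame_index, frame_rate: float):
    """Convert frame counts to seconds (e.g. 1,500 frames at 30 fps = 50 s)."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    fi = np.asarray(frame_index)
    if np.any(fi < 0):
        raise ValueError("negative frame index")
    out = fi / float(frame_rate)
    return float(out) if np.isscalar(frame_index) else out


def enforce_monotone(profile: FlowProfile) -> FlowProfile:
    """Replace distances by their running maximum (fronts cannot recede)."""
    return replace(profile, distance_cm=np.maximum.accumulate(profile.distance_cm))


def _central_axis_trace(frames: np.ndarray, roi: ChannelROI) -> np.ndarray:
    """Intensity along the ROI's central axis, shape (T, n_along).

    Index 0 of the along-axis dimension is the upstream (loading-zone)
    end.  Median over a 3-pixel transverse band when available.
    """
    sub = frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1]
    if roi.axis in ("+y", "-y"):
        sub = np.swapaxes(sub, 1, 2)  # -> (T, across, along)
    if roi.axis in ("-x", "-y"):
        sub = sub[:, :, ::-1]
    mid = sub.shape[1] // 2
    if sub.shape[1] >= 3:
        band = sub[:, max(mid - 1, 0) : mid + 2, :]
        return np.median(band, axis=1)
    return sub[:, mid, :].astype(float)


def track_front(
    stack: VideoStack,
    layout: ChannelLayout,
    threshold_rel: float = 0.5,
    baseline_frame: int = 0,
) -> list[FlowProfile]:
    """Track the wetting front in every channel ROI.

    Per frame, the front is the farthest along-axis pixel whose
    baseline-subtracted central-axis change exceeds ``threshold_rel``
    times the maximum wetted-region change observed in that channel.
    The returned profiles are monotone-enforced and capped at
    ``channel_length_cm``; frame 0 of each profile is ``baseline_frame``.
    """
    if not 0 < threshold_rel < 1:
        raise ValueError("threshold_rel must be in (0, 1)")
    if stack.n_frames == 0:
        raise ValueError("empty video stack")
    if not 0 <= baseline_frame < stack.n_frames:
        raise ValueError("baseline_frame outside the stack")
    layout.validate_against(stack)

    profiles = []
    for roi in layout.channel_rois:
        trace = _central_axis_trace(stack.frames, roi)
        delta = np.abs(trace[baseline_frame:] - trace[baseline_frame])
        max_change = float(delta.max())
        n_t = delta.shape[0]
        if max_change <= 0:
            warnings.warn(
                f"channel {roi.channel_id}: no intensity change anywhere — dry channel",
                stacklevel=2,
            )
            prof = FlowProfile(
                roi.channel_id, np.arange(n_t), np.zeros(n_t), stack.frame_rate, dry=True
            )
            profiles.append(prof)
            continue
        wetted = delta > threshold_rel * max_change
        # wetted pixel count = index of farthest wetted pixel + 1
        any_wet = wetted.any(axis=1)
        last_idx = wetted.shape[1] - 1 - np.argmax(wetted[:, ::-1], axis=1)
        front_px = np.where(any_wet, last_idx + 1, 0)
        dist = np.minimum(front_px / stack.pixel_scale, layout.channel_length_cm)
        prof = FlowProfile(roi.channel_id, np.arange(n_t), dist, stack.frame_rate)
        profiles.append(enforce_monotone(prof))
    return profiles


# ---------------------------------------------------------------------------
# I/O

def read_video(path: str | os.PathLike, frame_rate: float, pixel_scale: float) -> VideoStack:
    """Read an MP4/AVI file or a lexicographically ordered frame directory.

    Color frames are collapsed to a single luminance plane.
    """
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {p}")
        frames = np.stack([_to_luminance(iio.imread(f)) for f in files])
    else:
        frames = np.stack([_to_luminance(f) for f in iio.imiter(p)])
    return VideoStack(frames=frames, frame_rate=frame_rate, pixel_scale=pixel_scale)


def _to_luminance(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(float)
    from skimage.color import rgb2gray

    return rgb2gray(frame[..., :3]) * 255.0


def write_profiles_csv(
    profiles: Sequence[FlowProfile], path: str | os.PathLike, chip_id: str = "chip0"
) -> None:
    """Write profiles as chip_id, channel_id, frame, time_s, distance_cm."""
    rows = [
        pd.DataFrame(
            {
                "chip_id": chip_id,
                "channel_id": p.channel_id,
                "frame": p.frame_index,
                "time_s": p.times_s,
                "distance_cm": p.distance_cm,
            }
        )
        for p in profiles
    ]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path: str | os.PathLike) -> list[FlowProfile]:
    df = pd.read_csv(path, comment="#")
    profiles = []
    for cid, g in df.groupby("channel_id", sort=False):
        g = g.sort_values("frame")
        nz = g[g["time_s"] > 0]
        if nz.empty:
            raise ValueError(f"channel {cid}: cannot infer frame rate (all time_s == 0)")
        frame_rate = float(nz["frame"].iloc[-1] / nz["time_s"].iloc[-1])
        profiles.append(
            FlowProfile(
                channel_id=str(cid),
                frame_index=g["frame"].to_numpy(),
                distance_cm=g["distance_cm"].to_numpy(),
                frame_rate=frame_rate,
            )
        )
    return profiles
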