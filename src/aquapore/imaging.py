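"""Silhouette imaging: synthetic oocyte frames and area extraction.

An oocyte filmed from above is a near-circular dark silhouette; its
projected area per frame, normalized to the first frame, drives the
swelling-kinetics estimators.  Segmentation is deliberately minimal:
global Otsu threshold, keep the largest 8-connected component, fill
interior holes, count pixels.  Foreground polarity (dark-on-light or the
inverse) is auto-detected as the minority intensity class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .swelling import SwellingTrace

__all__ = [
    "FrameStack",
    "NoObjectError",
    "render_oocyte_frame",
    "extract_area",
    "trace_from_frames",
    "render_stack_from_trace",
]


class NoObjectError(ValueError):
    """The frame contains no segmentable object."""


@dataclass
class FrameStack:
    """Ordered grayscale frames with acquisition times (seconds)."""

    frames: list[np.ndarray]
    times: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != self.times.size:
            raise ValueError("one time stamp per frame required")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames differ in shape: {sorted(shapes)}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def render_oocyte_frame(
    radius_px: float,
    shape: tuple[int, int] = (256, 256),
    fg: float = 0.1,
    bg: float = 0.9,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render a centered dark disc on a light background.

    A pixel belongs to the disc when its center lies within ``radius_px``
    of the frame center.  Additive Gaussian noise of standard deviation
    ``noise_sd`` (intensity units) is applied uniformly; ``radius_px = 0``
    yields a pure background frame.
    """
    if radius_px < 0:
        raise ValueError("radius must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    h, w = shape
    if radius_px > 0 and radius_px + 2 > min(h, w) / 2:
        raise ValueError(
            f"radius {radius_px} px does not fit a {shape} frame with a 2 px margin"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    frame = np.full(shape, bg, dtype=float)
    frame[mask] = fg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, noise_sd, size=shape)
    return frame


def extract_area(frame: np.ndarray) -> int:
    """Silhouette area in pixels of the dominant object in a frame.

    Otsu's global threshold splits the frame into two intensity classes;
    the minority class is taken as foreground.  The largest 8-connected
    foreground component is kept, its interior holes are filled, and its
    pixel count returned.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise NoObjectError("frame has a single intensity; nothing to segment")
    thresh = threshold_otsu(frame)
    below = frame <= thresh
    # minority class is the object
    fg = below if below.sum() <= below.size / 2 else ~below
    if not fg.any():
        raise NoObjectError("no foreground pixels after thresholding")
    labels = label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == counts.argmax()
    filled = ndimage.binary_fill_holes(largest)
    return int(filled.sum())


def trace_from_frames(
    stack: FrameStack,
    oocyte_id: str = "frames",
    group: str = "expressing",
    condition: str = "water",
) -> SwellingTrace:
    """Area time series from a frame stack, normalized to the first frame."""
    if len(stack) < 2:
        raise ValueError("at least 2 frames are required for a trace")
    areas = np.array([extract_area(f) for f in stack.frames], dtype=float)
    if areas[0] == 0:
        raise NoObjectError("zero area in the first frame")
    rel_area = areas / areas[0]
    rel_area[0] = 1.0
    return SwellingTrace(
        oocyte_id=oocyte_id,
        group=group,
        condition=condition,
        times=stack.times - stack.times[0],
        rel_area=rel_area,
    )


def render_stack_from_trace(
    trace: SwellingTrace,
    r0_px: float = 60.0,
    shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FrameStack:
    """Render a frame per trace point, radius scaling as sqrt(A/A0)."""
    rng = np.random.default_rng(seed)
    frames = []
    for ra in trace.rel_area:
        sub = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
        frames.append(
            render_oocyte_frame(
                r0_px * float(np.sqrt(ra)), shape=shape, noise_sd=noise_sd, seed=sub
            )
        )
    return FrameStack(frames=frames, times=trace.times.copy())
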