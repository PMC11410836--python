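"""Encode axis annotations as 6-channel training heatmaps.

Each bone axis is rasterized as a 1-pixel 8-connected line, thickened to a
5-pixel cross-section by morphological dilation, and blurred with a Gaussian
whose standard deviation depends on the bone and on the segment length L and
image height h:

    sigma = h / (2.5 L)   for PH1
    sigma = h / L         for MT1..MT5

(the shorter phalanx gets the tighter kernel).  After blurring, each channel
is renormalized to peak 1 so the regression target has the same scale for
every bone length.  Channels are built independently, which is what lets the
encoding represent overlapping bone regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation, disk

from .errors import BoundsError, DegenerateGeometryError
from .geometry import BONES, AxisAnnotation, AxisSegment

#: truncation radius of the Gaussian kernel, in standard deviations
GAUSSIAN_TRUNCATE = 4.0


@dataclass(frozen=True)
class HeatmapStack:
    """A ``height x width x 6`` stack of per-bone axis heatmaps in [0, 1].

    Channel order follows :data:`halluxmetry.geometry.BONES`:
    (PH1, MT1, MT2, MT3, MT4, MT5).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[2] != len(BONES):
            raise ValueError(f"expected HxWx{len(BONES)} array, got shape {v.shape}")
        if v.min() < 0.0 or v.max() > 1.0 + 1e-12:
            raise ValueError("heatmap values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def channel(self, bone: str) -> np.ndarray:
        return self.values[:, :, BONES.index(bone)]


def rasterize_segment(segment: AxisSegment, height: int, width: int) -> np.ndarray:
    """Draw the segment as a 1-pixel-wide 8-connected binary line.

    The continuous segment is sampled densely and each sample rounded to its
    nearest pixel ("the pixels beneath the line").  Sampling the exact
    fractional endpoints — rather than running a Bresenham line between
    rounded endpoints — avoids an angle bias of up to ~1 degree on short
    segments.  For integer endpoints the result coincides with the
    Bresenham 8-connected line.
    """
    for pt in (segment.p_proximal, segment.p_distal):
        x, y = pt
        if not (0 <= x <= width - 1 and 0 <= y <= height - 1):
            raise BoundsError(f"endpoint {pt} outside {width}x{height} canvas")
    (x0, y0), (x1, y1) = segment.p_proximal, segment.p_distal
    n = max(2, int(np.ceil(4.0 * segment.length)) + 1)
    t = np.linspace(0.0, 1.0, n)
    cc = np.clip(np.round(x0 + t * (x1 - x0)).astype(int), 0, width - 1)
    rr = np.clip(np.round(y0 + t * (y1 - y0)).astype(int), 0, height - 1)
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc] = True
    return mask


def thicken(mask: np.ndarray, width_px: int = 5) -> np.ndarray:
    """Dilate a binary line mask to the requested cross-section width.

    A disk of radius ``(width_px - 1) // 2`` turns a 1-pixel line into a band
    ``width_px`` pixels across (perpendicular to the line, away from borders).
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd integer")
    mask = np.asarray(mask, dtype=bool)
    if width_px == 1 or not mask.any():
        return mask.copy()
    return dilation(mask, disk((width_px - 1) // 2)).astype(bool)


def gaussian_sigma(bone_label: str, h: float, L: float) -> float:
    """Blur standard deviation in pixels for one bone channel."""
    if bone_label not in BONES:
        raise ValueError(f"unknown bone label {bone_label!r}")
    if h <= 0:
        raise ValueError("image height must be positive")
    if L <= 0:
        raise DegenerateGeometryError("segment length must be positive")
    if bone_label == "PH1":
        return h / (2.5 * L)
    return h / L


def make_channel(segment: AxisSegment, height: int, width: int,
                 line_width_px: int = 5) -> np.ndarray:
    """Rasterize -> thicken -> Gaussian blur -> renormalize one channel."""
    mask = thicken(rasterize_segment(segment, height, width), line_width_px)
    sigma = gaussian_sigma(segment.bone_label, height, segment.length)
    blurred = gaussian_filter(mask.astype(np.float64), sigma=sigma,
                              mode="constant", cval=0.0, truncate=GAUSSIAN_TRUNCATE)
    peak = blurred.max()
    if peak > 0:
        blurred /= peak
    return np.clip(blurred, 0.0, 1.0)


def make_heatmaps(annotation: AxisAnnotation, line_width_px: int = 5) -> HeatmapStack:
    """Build the 6-channel heatmap stack for one annotation."""
    h, w = annotation.image_height, annotation.image_width
    stack = np.stack(
        [make_channel(annotation.segments[b], h, w, line_width_px) for b in BONES],
        axis=-1,
    )
    return HeatmapStack(stack)


def save_stack(stack: HeatmapStack, path) -> None:
    """Write a stack to a compressed ``.npz`` container, bit-exactly."""
    np.savez_compressed(path, values=stack.values,
                        channels=np.array(BONES, dtype="U4"))


def load_stack(path) -> HeatmapStack:
    """Read a stack written by :func:`save_stack`; validates channel order."""
    with np.load(path) as data:
        channels = tuple(data["channels"])
        if channels != BONES:
            raise ValueError(f"unexpected channel order {channels}")
        return HeatmapStack(data["values"])
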