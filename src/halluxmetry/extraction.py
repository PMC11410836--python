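"""Recover axis angles from heatmap channels.

The "high-value area" of a channel (pixels at or above a fraction tau of
the channel maximum) is summarized by its value-weighted second-moment
matrix; the principal eigenvector is the total-least-squares line through
the area.  Total least squares is used instead of y-on-x regression because
metatarsal axes are near-vertical in the dorsoplantar view, where y-on-x
fitting is ill-conditioned; the principal-axis fit is rotation-invariant.

The fitted axis is undirected; each direction is subsequently oriented
toward the toe side of the image (determined from the PH1 channel centroid)
so that the geometry module can form signed angle differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import (ConfigurationError, DegenerateAxisError,
                     InsufficientSignalError)
from .geometry import BONES, AngleSet, wrap_angle
from .heatmaps import HeatmapStack
from .nn.unet import UNet, predict


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of the high-value-area axis fit.

    ``threshold_fraction`` is the fraction of the channel maximum defining
    the high-value area; ``weighting`` selects whether moments use the
    heatmap values as weights or treat the area as a binary set.
    """

    threshold_fraction: float = 0.5
    min_support_pixels: int = 20
    weighting: str = "heatmap-value"
    #: smallest anisotropy (major/minor eigenvalue) accepted as a line
    min_eigenvalue_ratio: float = 1.05

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ConfigurationError("threshold_fraction must lie in (0, 1)")
        if self.min_support_pixels < 3:
            raise ConfigurationError("min_support_pixels must be >= 3")
        if self.weighting not in ("binary", "heatmap-value"):
            raise ConfigurationError("weighting must be 'binary' or 'heatmap-value'")


@dataclass(frozen=True)
class AxisFit:
    """A fitted undirected axis: centroid (pixel coords), unit direction
    (y-up frame), and the inclination in degrees within [0, 180)."""

    centroid: Tuple[float, float]
    direction: Tuple[float, float]
    inclination: float


def channel_moments(channel: np.ndarray, config: ExtractionConfig):
    """Weighted centroid and second-moment matrix of the high-value area.

    Coordinates are (x, y_up): the pixel y axis is negated so angles follow
    the counterclockwise-positive convention.
    """
    ch = np.asarray(channel, dtype=np.float64)
    peak = float(ch.max())
    if peak <= 0.0:
        raise InsufficientSignalError("channel is empty (max <= 0)")
    rows, cols = np.nonzero(ch >= config.threshold_fraction * peak)
    if rows.size < config.min_support_pixels:
        raise InsufficientSignalError(
            f"only {rows.size} supra-threshold pixels "
            f"(< {config.min_support_pixels})")
    w = ch[rows, cols] if config.weighting == "heatmap-value" else np.ones(rows.size)
    x = cols.astype(np.float64)
    y = -rows.astype(np.float64)  # y-up frame
    wsum = w.sum()
    mx, my = (w * x).sum() / wsum, (w * y).sum() / wsum
    dx, dy = x - mx, y - my
    cov = np.array([[np.sum(w * dx * dx), np.sum(w * dx * dy)],
                    [np.sum(w * dx * dy), np.sum(w * dy * dy)]]) / wsum
    return (mx, my), cov


def extract_axis(channel: np.ndarray, config: ExtractionConfig = ExtractionConfig()) -> AxisFit:
    """Total-least-squares axis of one heatmap channel.

    Returns the weighted centroid (in pixel coordinates), the principal unit
    direction in the y-up frame, and the undirected inclination in [0, 180).
    Raises :class:`InsufficientSignalError` when the high-value area is too
    small and :class:`DegenerateAxisError` when it has no principal
    direction (near-isotropic support).
    """
    (mx, my), cov = channel_moments(channel, config)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0.0:
        raise DegenerateAxisError("zero spatial extent")
    ratio = lam_major / max(lam_minor, 1e-300)
    if ratio < config.min_eigenvalue_ratio:
        raise DegenerateAxisError(
            f"isotropic support (eigenvalue ratio {ratio:.3f})")
    vx, vy = float(evecs[0, 1]), float(evecs[1, 1])
    theta = math.degrees(math.atan2(vy, vx)) % 180.0
    if theta >= 180.0:
        theta -= 180.0
    if vy < 0 or (vy == 0 and vx < 0):
        vx, vy = -vx, -vy
    return AxisFit(centroid=(mx, -my), direction=(vx, vy), inclination=theta)


def orient_inclination(undirected_deg: float, direction: Tuple[float, float],
                       toe_direction: Tuple[float, float]) -> float:
    """Resolve the 180-degree ambiguity toward the toe side of the image."""
    dot = direction[0] * toe_direction[0] + direction[1] * toe_direction[1]
    theta = undirected_deg if dot >= 0 else undirected_deg - 180.0
    return wrap_angle(theta)


@dataclass(frozen=True)
class MeasurementResult:
    """Per-image measurement outcome with per-bone status flags.

    ``status[bone]`` is ``"ok"``, ``"insufficient-signal"`` or
    ``"degenerate-axis"``; ``angles`` is None unless all six fits succeeded.
    """

    angles: Optional[AngleSet]
    status: Dict[str, str]
    fits: Dict[str, Optional[AxisFit]]

    @property
    def ok(self) -> bool:
        return self.angles is not None


def measure_stack(stack: HeatmapStack,
                  config: ExtractionConfig = ExtractionConfig()) -> MeasurementResult:
    """Fit all six axes of a heatmap stack and derive the angle set.

    Channel failures are recorded per bone without aborting the others.
    The undirected fits are oriented proximal->distal using the PH1 channel
    centroid as the toe side (falling back to image-up when PH1 failed).
    """
    fits: Dict[str, Optional[AxisFit]] = {}
    status: Dict[str, str] = {}
    for bone in BONES:
        try:
            fits[bone] = extract_axis(stack.channel(bone), config)
            status[bone] = "ok"
        except InsufficientSignalError:
            fits[bone], status[bone] = None, "insufficient-signal"
        except DegenerateAxisError:
            fits[bone], status[bone] = None, "degenerate-axis"

    mt_centroids = [fits[b].centroid for b in BONES[1:] if fits[b] is not None]
    if fits["PH1"] is not None and mt_centroids:
        cx = float(np.mean([c[0] for c in mt_centroids]))
        cy = float(np.mean([c[1] for c in mt_centroids]))
        px, py = fits["PH1"].centroid
        toe = (px - cx, -(py - cy))  # y-up frame
        if toe == (0.0, 0.0):
            toe = (0.0, 1.0)
    else:
        toe = (0.0, 1.0)  # toes at the top of the canvas

    angles = None
    if all(status[b] == "ok" for b in BONES):
        # MT1 is oriented toward the toes; every other axis then takes the
        # 180-degree representative nearest MT1's direction.  Forefoot axes
        # never diverge more than 90 degrees from MT1, and a global flip
        # (wrong toe side) cancels in the derived angle differences.
        mt1 = orient_inclination(fits["MT1"].inclination,
                                 fits["MT1"].direction, toe)
        inclinations = {"MT1": mt1}
        for b in BONES:
            if b == "MT1":
                continue
            theta = fits[b].inclination
            candidates = (wrap_angle(theta), wrap_angle(theta - 180.0))
            inclinations[b] = min(
                candidates, key=lambda c: abs(wrap_angle(c - mt1)))
        angles = AngleSet.from_inclinations(inclinations)
    return MeasurementResult(angles=angles, status=status, fits=fits)


def measure_image(network: UNet, image: np.ndarray,
                  config: ExtractionConfig = ExtractionConfig()) -> MeasurementResult:
    """Predict heatmaps for a standardized image and measure its angles."""
    return measure_stack(predict(network, image), config)
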