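"""Axis geometry: inclination angles and the derived HVA / IMA.

Coordinate conventions
----------------------
Pixel coordinates are ``(x, y)`` with ``x`` growing rightward and ``y``
growing *downward* (image convention).  All angles are reported in a
mathematically oriented frame (y up), measured counterclockwise from the
right-facing horizontal, so a positive angle is a counterclockwise rotation
as the radiograph is viewed.  Axes are directed proximal -> distal
(heel to toes); on a dorsoplantar view with the toes at the top every bone
axis then sits near +90 deg and the hallux valgus angle (HVA) and first-second
intermetatarsal angle (IMA) are small signed differences:

    HVA = PH1a - MT1a
    IMA = MT2a - MT1a

where PH1a is the inclination of the first proximal phalanx axis and
MT1a..MT5a those of the metatarsal axes.  All angles and differences are
wrapped to ``(-180, 180]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Tuple

from .errors import BoundsError, DegenerateGeometryError

BONES: Tuple[str, ...] = ("PH1", "MT1", "MT2", "MT3", "MT4", "MT5")
SIDES: Tuple[str, ...] = ("left", "right")

Point = Tuple[float, float]


def wrap_angle(theta: float) -> float:
    """Reduce an angle in degrees to the interval ``(-180, 180]``.

    Ties at +-180 resolve to +180 so every angle has a unique representative.
    """
    t = math.fmod(theta, 360.0)
    if t <= -180.0:
        t += 360.0
    elif t > 180.0:
        t -= 360.0
    # fmod can return -180.0 exactly for inputs like -180.0
    if t == -180.0:
        t = 180.0
    return t


@dataclass(frozen=True)
class AxisSegment:
    """A labeled bone-axis line segment, directed proximal -> distal.

    Endpoints are 0-based pixel-center coordinates ``(x, y)``.
    """

    bone_label: str
    p_proximal: Point
    p_distal: Point

    def __post_init__(self) -> None:
        if self.bone_label not in BONES:
            raise ValueError(f"unknown bone label {self.bone_label!r}")
        if tuple(self.p_proximal) == tuple(self.p_distal):
            raise DegenerateGeometryError(
                f"{self.bone_label}: proximal and distal endpoints coincide"
            )
        object.__setattr__(self, "p_proximal", (float(self.p_proximal[0]), float(self.p_proximal[1])))
        object.__setattr__(self, "p_distal", (float(self.p_distal[0]), float(self.p_distal[1])))

    @property
    def length(self) -> float:
        dx = self.p_distal[0] - self.p_proximal[0]
        dy = self.p_distal[1] - self.p_proximal[1]
        return math.hypot(dx, dy)


@dataclass(frozen=True)
class AxisAnnotation:
    """The six bone-axis segments for one image, plus image size and foot side."""

    image_height: int
    image_width: int
    side: str
    segments: Mapping[str, AxisSegment]

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        segs = dict(self.segments)
        missing = [b for b in BONES if b not in segs]
        if missing:
            raise ValueError(f"missing bone labels: {missing}")
        extra = [b for b in segs if b not in BONES]
        if extra:
            raise ValueError(f"unknown bone labels: {extra}")
        for label, seg in segs.items():
            if seg.bone_label != label:
                raise ValueError(f"segment under key {label!r} is labeled {seg.bone_label!r}")
            for pt in (seg.p_proximal, seg.p_distal):
                x, y = pt
                if not (0 <= x <= self.image_width - 1 and 0 <= y <= self.image_height - 1):
                    raise BoundsError(
                        f"{label}: endpoint {pt} outside {self.image_width}x{self.image_height} image"
                    )
        object.__setattr__(self, "segments", segs)

    def __iter__(self) -> Iterable[AxisSegment]:
        return (self.segments[b] for b in BONES)


@dataclass(frozen=True)
class AngleSet:
    """Per-bone inclination angles (degrees) and the derived HVA and IMA.

    Invariants ``HVA = PH1a - MT1a`` and ``IMA = MT2a - MT1a`` hold by
    construction (wrapped to ``(-180, 180]``).
    """

    PH1a: float
    MT1a: float
    MT2a: float
    MT3a: float
    MT4a: float
    MT5a: float
    HVA: float
    IMA: float

    @classmethod
    def from_inclinations(cls, inclinations: Mapping[str, float]) -> "AngleSet":
        ang = {b: wrap_angle(float(inclinations[b])) for b in BONES}
        return cls(
            PH1a=ang["PH1"],
            MT1a=ang["MT1"],
            MT2a=ang["MT2"],
            MT3a=ang["MT3"],
            MT4a=ang["MT4"],
            MT5a=ang["MT5"],
            HVA=wrap_angle(ang["PH1"] - ang["MT1"]),
            IMA=wrap_angle(ang["MT2"] - ang["MT1"]),
        )

    def inclination(self, bone: str) -> float:
        return getattr(self, f"{bone}a" if bone != "PH1" else "PH1a")

    def as_dict(self) -> dict:
        return {
            "PH1a": self.PH1a,
            "MT1a": self.MT1a,
            "MT2a": self.MT2a,
            "MT3a": self.MT3a,
            "MT4a": self.MT4a,
            "MT5a": self.MT5a,
            "HVA": self.HVA,
            "IMA": self.IMA,
        }


def inclination_angle(segment: AxisSegment) -> float:
    """Inclination of the proximal->distal direction, degrees in ``(-180, 180]``.

    Measured counterclockwise from the right-facing horizontal in a y-up
    frame; the sign flip of the pixel-frame ``y`` makes "counterclockwise"
    match the visual orientation of the displayed radiograph.
    """
    dx = segment.p_distal[0] - segment.p_proximal[0]
    dy = segment.p_distal[1] - segment.p_proximal[1]
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("zero-length segment has no direction")
    return wrap_angle(math.degrees(math.atan2(-dy, dx)))


def derive_angles(annotation: AxisAnnotation) -> AngleSet:
    """Per-bone inclination angles plus HVA and IMA for one annotation."""
    return AngleSet.from_inclinations(
        {b: inclination_angle(annotation.segments[b]) for b in BONES}
    )


def normalize_side(angles: AngleSet, side: str) -> AngleSet:
    """Map a left-foot angle set onto the right-foot sign convention.

    A left foot is the mirror image of a right foot, so each inclination is
    reflected across the vertical axis (theta -> 180 - theta) and the derived
    angles recomputed; this negates HVA and IMA while preserving their
    magnitudes.  Right-foot angle sets are returned unchanged.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if side == "right":
        return angles
    reflected = {b: wrap_angle(180.0 - angles.inclination(b)) for b in BONES}
    return AngleSet.from_inclinations(reflected)


def transform_segment(segment: AxisSegment, matrix) -> AxisSegment:
    """Apply a 3x3 affine matrix (pixel-frame, homogeneous) to both endpoints."""
    def _apply(p: Point) -> Point:
        x = matrix[0][0] * p[0] + matrix[0][1] * p[1] + matrix[0][2]
        y = matrix[1][0] * p[0] + matrix[1][1] * p[1] + matrix[1][2]
        return (x, y)

    return replace(segment, p_proximal=_apply(segment.p_proximal), p_distal=_apply(segment.p_distal))


def transform_annotation(annotation: AxisAnnotation, matrix,
                         image_height: int | None = None,
                         image_width: int | None = None,
                         side: str | None = None) -> AxisAnnotation:
    """Apply an affine matrix to every segment, optionally changing size/side."""
    return AxisAnnotation(
        image_height=image_height if image_height is not None else annotation.image_height,
        image_width=image_width if image_width is not None else annotation.image_width,
        side=side if side is not None else annotation.side,
        segments={b: transform_segment(annotation.segments[b], matrix) for b in BONES},
    )
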