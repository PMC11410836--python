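"""Synthetic dorsoplantar foot phantoms with known ground-truth axes.

A phantom is a dark, noisy canvas carrying six bright capsule-shaped "bones"
(the first proximal phalanx PH1 and metatarsals MT1-MT5) whose midlines are
the ground-truth axis segments.  The construction is driven directly by the
target angles, so ``derive_angles`` on the ground truth reproduces the
requested hallux valgus angle (HVA) and intermetatarsal angle (IMA) exactly:

* MT1 is placed at ``MT1_base_angle``;
* MT2 at ``MT1_base_angle + true_IMA``;
* PH1 at ``MT1_base_angle + true_HVA``, end-to-end with MT1 across a small
  simulated first metatarsophalangeal joint gap;
* MT3-MT5 fan laterally from MT2.

Sign convention (right foot, toes up, lateral side to the right): a
clinically valgus hallux deviates laterally, giving negative signed HVA and
IMA; mirrored left feet give positive signs.  Only the magnitudes carry
clinical meaning.

The module also simulates human raters by jittering ground-truth endpoints
and rotating segments about their midpoints, providing inputs for the
agreement statistics without any clinical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import LayoutError
from .geometry import (BONES, AxisAnnotation, AxisSegment, Point)
from .preprocess import Sample

#: bone intensity plateau and background level (arbitrary units in [0, 1])
BONE_INTENSITY = 0.85
BACKGROUND_INTENSITY = 0.10
#: soft-edge half-width of the capsule profile, pixels (at 512 canvas)
EDGE_SOFTNESS = 2.0

# layout as fractions of the (square) canvas height, tuned for a 512 canvas
_LENGTH_FRAC = {"PH1": 0.14, "MT1": 0.30, "MT2": 0.33, "MT3": 0.31,
                "MT4": 0.29, "MT5": 0.26}
_WIDTH_FRAC = {"PH1": 0.042, "MT1": 0.055, "MT2": 0.032, "MT3": 0.030,
               "MT4": 0.028, "MT5": 0.028}
_BASE_Y_FRAC = 0.80          # proximal metatarsal row
_MT1_BASE_X_FRAC = 0.32      # medial-most metatarsal base (right foot)
_JOINT_GAP_FRAC = 0.02       # simulated first MTP joint gap
_FAN_OFFSETS = {"MT3": -5.0, "MT4": -10.0, "MT5": -16.0}  # rel. MT2, right foot


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic radiograph.

    ``overlap_factor`` in [0, 1] crowds the metatarsal bases together
    laterally (1 = strongly overlapping bone regions, as in severe
    deformity); ``noise_sd`` is the additive Gaussian intensity noise.
    """

    image_height: int = 512
    image_width: int = 512
    side: str = "right"
    true_HVA: float = -25.0
    true_IMA: float = -12.0
    MT1_base_angle: Optional[float] = None
    bone_lengths: Optional[Dict[str, float]] = None
    bone_widths: Optional[Dict[str, float]] = None
    noise_sd: float = 0.03
    overlap_factor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("canvas dimensions must be positive")
        if abs(self.true_HVA) > 60:
            raise ValueError("|true_HVA| must be <= 60 degrees")
        if abs(self.true_IMA) > 30:
            raise ValueError("|true_IMA| must be <= 30 degrees")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.overlap_factor <= 1.0:
            raise ValueError("overlap_factor must lie in [0, 1]")
        lengths = self.bone_lengths or {
            b: _LENGTH_FRAC[b] * self.image_height for b in BONES}
        widths = self.bone_widths or {
            b: _WIDTH_FRAC[b] * self.image_height for b in BONES}
        if any(v <= 0 for v in lengths.values()) or any(v <= 0 for v in widths.values()):
            raise ValueError("bone lengths and widths must be positive")
        object.__setattr__(self, "bone_lengths", dict(lengths))
        object.__setattr__(self, "bone_widths", dict(widths))

    @property
    def mt1_angle(self) -> float:
        if self.MT1_base_angle is not None:
            return self.MT1_base_angle
        return 95.0 if self.side == "right" else 85.0


@dataclass(frozen=True)
class RaterModel:
    """Noise model for simulated human raters.

    Each rater redraws every axis by jittering both endpoints with isotropic
    Gaussian noise (``endpoint_noise_sd`` pixels) and rotating the segment
    about its midpoint by a Gaussian angle (``angular_noise_sd`` degrees);
    the induced angle error is zero-mean.
    """

    angular_noise_sd: float = 1.5
    endpoint_noise_sd: float = 2.0
    n_raters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.angular_noise_sd < 0 or self.endpoint_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_raters < 1:
            raise ValueError("n_raters must be at least 1")


def _endpoint(base: Point, angle_deg: float, length: float) -> Point:
    """Distal endpoint in pixel coordinates (y down) for a y-up inclination."""
    phi = math.radians(angle_deg)
    return (base[0] + length * math.cos(phi), base[1] - length * math.sin(phi))


def true_annotation(spec: PhantomSpec) -> AxisAnnotation:
    """Ground-truth axis segments implied by a phantom specification."""
    h, w = spec.image_height, spec.image_width
    lateral = 1.0 if spec.side == "right" else -1.0
    mt1a = spec.mt1_angle
    angles = {
        "MT1": mt1a,
        "MT2": mt1a + spec.true_IMA,
        "PH1": mt1a + spec.true_HVA,
    }
    for bone, off in _FAN_OFFSETS.items():
        angles[bone] = angles["MT2"] + lateral * off

    base_y = _BASE_Y_FRAC * h
    x0 = _MT1_BASE_X_FRAC * w if lateral > 0 else (1.0 - _MT1_BASE_X_FRAC) * w
    spacing = lateral * w * (0.105 - 0.045 * spec.overlap_factor)

    segments: Dict[str, AxisSegment] = {}
    for i, bone in enumerate(("MT1", "MT2", "MT3", "MT4", "MT5")):
        prox = (x0 + i * spacing, base_y)
        dist = _endpoint(prox, angles[bone], spec.bone_lengths[bone])
        segments[bone] = AxisSegment(bone, prox, dist)

    gap = _JOINT_GAP_FRAC * h
    ph1_prox = _endpoint(segments["MT1"].p_distal, angles["PH1"], gap)
    ph1_dist = _endpoint(ph1_prox, angles["PH1"], spec.bone_lengths["PH1"])
    segments["PH1"] = AxisSegment("PH1", ph1_prox, ph1_dist)

    for bone, seg in segments.items():
        margin = spec.bone_widths[bone] / 2.0 + 2.0
        for x, y in (seg.p_proximal, seg.p_distal):
            if not (margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin):
                raise LayoutError(
                    f"{bone} endpoint ({x:.1f}, {y:.1f}) too close to the "
                    f"border of the {w}x{h} canvas")

    return AxisAnnotation(image_height=h, image_width=w, side=spec.side,
                          segments=segments)


def _capsule_profile(h: int, w: int, seg: AxisSegment, half_width: float,
                     edge: float) -> np.ndarray:
    """Soft indicator of a capsule (stadium) around the segment midline."""
    ys, xs = np.mgrid[0:h, 0:w]
    px, py = seg.p_proximal
    dx = seg.p_distal[0] - px
    dy = seg.p_distal[1] - py
    L2 = dx * dx + dy * dy
    t = np.clip(((xs - px) * dx + (ys - py) * dy) / L2, 0.0, 1.0)
    dist = np.hypot(xs - (px + t * dx), ys - (py + t * dy))
    return np.clip((half_width - dist) / edge + 0.5, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec,
                     rng: Optional[np.random.Generator] = None) -> Sample:
    """Render one phantom image and return it with its ground-truth annotation."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ann = true_annotation(spec)
    h, w = spec.image_height, spec.image_width
    edge = EDGE_SOFTNESS * max(h, w) / 512.0

    bone = np.zeros((h, w), dtype=np.float64)
    for label in BONES:
        prof = _capsule_profile(h, w, ann.segments[label],
                                spec.bone_widths[label] / 2.0, edge)
        np.maximum(bone, prof, out=bone)

    img = BACKGROUND_INTENSITY + (BONE_INTENSITY - BACKGROUND_INTENSITY) * bone
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return Sample(img, ann, sample_id=f"phantom-{spec.seed}",
                  transform_log=({"op": "generate_phantom", "seed": spec.seed},))


def random_spec(rng: np.random.Generator, size: int = 512,
                side: Optional[str] = None, noise_sd: float = 0.03,
                overlap_factor: Optional[float] = None) -> PhantomSpec:
    """Draw a clinic-like phantom specification.

    Angle magnitudes follow the spread seen in hallux valgus clinic
    populations (HVA ~ N(30, 14.6), IMA ~ N(14.3, 4.3), clipped), signed for
    lateral deviation of the hallux on the given side.
    """
    if side is None:
        side = "right" if rng.random() < 0.5 else "left"
    lateral = 1.0 if side == "right" else -1.0
    hva_mag = float(np.clip(rng.normal(30.0, 14.6), 0.0, 55.0))
    ima_mag = float(np.clip(rng.normal(14.3, 4.3), 1.0, 28.0))
    if overlap_factor is None:
        overlap_factor = float(rng.uniform(0.0, 0.8))
    base = 95.0 if side == "right" else 85.0
    base += float(rng.uniform(-4.0, 4.0))
    return PhantomSpec(
        image_height=size, image_width=size, side=side,
        true_HVA=-lateral * hva_mag, true_IMA=-lateral * ima_mag,
        MT1_base_angle=base, noise_sd=noise_sd,
        overlap_factor=overlap_factor,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _jitter_segment(seg: AxisSegment, model: RaterModel,
                    rng: np.random.Generator, h: int, w: int) -> AxisSegment:
    pts = []
    for x, y in (seg.p_proximal, seg.p_distal):
        jx = x + rng.normal(0.0, model.endpoint_noise_sd)
        jy = y + rng.normal(0.0, model.endpoint_noise_sd)
        pts.append((jx, jy))
    # rotate about the midpoint of the jittered segment
    phi = math.radians(rng.normal(0.0, model.angular_noise_sd))
    mx = (pts[0][0] + pts[1][0]) / 2.0
    my = (pts[0][1] + pts[1][1]) / 2.0
    c, s = math.cos(phi), math.sin(phi)
    rotated = []
    for x, y in pts:
        u, v = x - mx, y - my
        # visual-CCW rotation in pixel coordinates (y down)
        rotated.append((mx + c * u + s * v, my - s * u + c * v))
    clipped = [
        (min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0)) for x, y in rotated
    ]
    return AxisSegment(seg.bone_label, clipped[0], clipped[1])


def simulate_raters(truth: AxisAnnotation, model: RaterModel,
                    rng: Optional[np.random.Generator] = None) -> List[AxisAnnotation]:
    """Per-rater re-annotations of the ground truth under the noise model."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    h, w = truth.image_height, truth.image_width
    out = []
    for _ in range(model.n_raters):
        segs = {b: _jitter_segment(truth.segments[b], model, rng, h, w)
                for b in BONES}
        out.append(AxisAnnotation(image_height=h, image_width=w,
                                  side=truth.side, segments=segs))
    return out
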