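"""Geometric and intensity standardization, paired augmentation, splitting.

Images and their axis annotations always travel together: every geometric
transform applied to pixel data is applied, in exact affine form, to the
annotation endpoints, so re-deriving angles from a transformed annotation
matches the analytic transform of the original angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import math
import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .errors import ConfigurationError
from .geometry import AxisAnnotation, transform_annotation

#: network input side length (pixels)
DEFAULT_TARGET = 512
#: augmentation rotation bound, degrees (either direction)
MAX_ROTATION_DEG = 15.0
#: maximum number of augmented copies per source image
MAX_AUGMENT_COPIES = 6


@dataclass(frozen=True)
class Sample:
    """A standardized image with its annotation and a transform provenance log."""

    image: np.ndarray
    annotation: AxisAnnotation
    sample_id: str = ""
    transform_log: Tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("image must be a 2-D grayscale array")
        if img.shape != (self.annotation.image_height, self.annotation.image_width):
            raise ValueError(
                f"image shape {img.shape} does not match annotation "
                f"{(self.annotation.image_height, self.annotation.image_width)}"
            )
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "transform_log", tuple(self.transform_log))


def _rescale_01(image: np.ndarray) -> np.ndarray:
    """Per-image min-max rescale to [0, 1]; a constant image maps to zeros."""
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def standardize(image: np.ndarray, annotation: AxisAnnotation,
                target: int = DEFAULT_TARGET, sample_id: str = "") -> Sample:
    """Pad to square with black, resize to ``target`` x ``target``, rescale.

    The black border is split evenly between the two sides of the short axis
    (odd remainder goes to the trailing side).  Annotation endpoints are
    mapped through the same pad-then-scale affine; the uniform scale keeps
    all inclination angles unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape
    side = max(h, w)
    pad_top = (side - h) // 2
    pad_left = (side - w) // 2
    padded = np.zeros((side, side), dtype=np.float64)
    padded[pad_top:pad_top + h, pad_left:pad_left + w] = img

    scale = target / side
    out = _sk_resize(padded, (target, target), order=1, mode="constant",
                     cval=0.0, anti_aliasing=scale < 1.0, preserve_range=True)
    out = _rescale_01(out)

    matrix = [[scale, 0.0, pad_left * scale],
              [0.0, scale, pad_top * scale],
              [0.0, 0.0, 1.0]]
    ann = transform_annotation(annotation, matrix,
                               image_height=target, image_width=target)
    log = ({"op": "standardize", "pad_top": pad_top, "pad_left": pad_left,
            "scale": scale, "target": target},)
    return Sample(out, ann, sample_id=sample_id, transform_log=log)


def _flip_horizontal(sample: Sample) -> Sample:
    """Mirror the image and annotation; a flipped right foot becomes a left foot."""
    w = sample.annotation.image_width
    matrix = [[-1.0, 0.0, float(w - 1)], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    new_side = "left" if sample.annotation.side == "right" else "right"
    ann = transform_annotation(sample.annotation, matrix, side=new_side)
    return replace(sample, image=np.fliplr(sample.image).copy(), annotation=ann)


def _rotate(sample: Sample, angle_deg: float) -> Sample:
    """Rotate image and annotation about the image center.

    ``angle_deg`` is counterclockwise in the displayed (y-up) frame, so every
    inclination angle increases by exactly ``angle_deg``.  Pixel data is
    resampled bilinearly with black fill; endpoints get the exact affine.
    """
    h, w = sample.image.shape
    img = _sk_rotate(sample.image, angle_deg, resize=False, center=None,
                     order=1, mode="constant", cval=0.0, preserve_range=True)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    phi = math.radians(angle_deg)
    c, s = math.cos(phi), math.sin(phi)
    # visual-CCW rotation expressed in pixel coordinates (y down)
    matrix = [[c, s, cx - c * cx - s * cy],
              [-s, c, cy + s * cx - c * cy],
              [0.0, 0.0, 1.0]]
    ann = transform_annotation(sample.annotation, matrix)
    return replace(sample, image=np.clip(img, 0.0, 1.0), annotation=ann)


def augment(sample: Sample, n_copies: int, rng: np.random.Generator) -> List[Sample]:
    """Random horizontal flips and rotations in [-15, +15] degrees.

    Each copy independently flips with probability 1/2 and then rotates by a
    uniform random angle.  Both operations are applied identically to pixels
    and endpoints, and are recorded in the transform log.
    """
    if n_copies > MAX_AUGMENT_COPIES:
        raise ConfigurationError(
            f"n_copies={n_copies} exceeds the cap of {MAX_AUGMENT_COPIES}")
    if n_copies < 0:
        raise ConfigurationError("n_copies must be non-negative")
    out: List[Sample] = []
    for k in range(n_copies):
        flip = bool(rng.random() < 0.5)
        angle = float(rng.uniform(-MAX_ROTATION_DEG, MAX_ROTATION_DEG))
        aug = _flip_horizontal(sample) if flip else sample
        aug = _rotate(aug, angle)
        entry = {"op": "augment", "copy": k, "flip": flip, "rotation_deg": angle}
        aug = replace(aug, sample_id=f"{sample.sample_id}/aug{k}",
                      transform_log=sample.transform_log + (entry,))
        out.append(aug)
    return out


def split_dataset(samples: Sequence, ratios: Tuple[float, float, float] = (0.70, 0.20, 0.10),
                  seed: int = 0) -> Tuple[list, list, list]:
    """Seeded random train/validation/test partition.

    Split sizes are the largest-remainder rounding of ``n * ratios``; the
    three parts are disjoint and exhaustive.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("split ratios must sum to 1")
    n = len(samples)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    exact = [n * r for r in ratios]
    sizes = [int(math.floor(e)) for e in exact]
    # round remainders so float noise cannot flip ties; ties go to the
    # earlier group
    remainders = [round(e - s, 9) for e, s in zip(exact, sizes)]
    short = n - sum(sizes)
    for idx in sorted(range(3), key=lambda i: (-remainders[i], i))[:short]:
        sizes[idx] += 1
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum([0] + sizes)
    groups = tuple(
        [samples[i] for i in perm[bounds[g]:bounds[g + 1]]] for g in range(3)
    )
    return groups
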