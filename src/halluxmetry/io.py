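"""Readers and writers: annotation JSON, grayscale PNG, angle/report CSV.

Annotation JSON schema (one document per image)::

    {
      "image_height": 512,
      "image_width": 512,
      "side": "right",
      "axes": [
        {"bone": "PH1", "proximal": [x, y], "distal": [x, y]},
        ... one object per bone PH1, MT1..MT5 ...
      ]
    }

Coordinates are 0-based pixel centers.  Validation failures raise
:class:`~halluxmetry.errors.AnnotationSchemaError` naming the offending
field or bone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import AnnotationSchemaError, BoundsError
from .geometry import BONES, SIDES, AngleSet, AxisAnnotation, AxisSegment


def annotation_to_dict(annotation: AxisAnnotation) -> dict:
    return {
        "image_height": annotation.image_height,
        "image_width": annotation.image_width,
        "side": annotation.side,
        "axes": [
            {"bone": b,
             "proximal": list(annotation.segments[b].p_proximal),
             "distal": list(annotation.segments[b].p_distal)}
            for b in BONES
        ],
    }


def annotation_from_dict(doc: dict, source: str = "<annotation>") -> AxisAnnotation:
    for key in ("image_height", "image_width", "side", "axes"):
        if key not in doc:
            raise AnnotationSchemaError(f"{source}: missing field {key!r}")
    if doc["side"] not in SIDES:
        raise AnnotationSchemaError(
            f"{source}: side must be one of {SIDES}, got {doc['side']!r}")
    segments: Dict[str, AxisSegment] = {}
    for i, axis in enumerate(doc["axes"]):
        for key in ("bone", "proximal", "distal"):
            if key not in axis:
                raise AnnotationSchemaError(f"{source}: axes[{i}] missing {key!r}")
        bone = axis["bone"]
        if bone not in BONES:
            raise AnnotationSchemaError(f"{source}: axes[{i}] unknown bone {bone!r}")
        if bone in segments:
            raise AnnotationSchemaError(f"{source}: duplicate bone {bone!r}")
        for key in ("proximal", "distal"):
            pt = axis[key]
            if len(pt) != 2:
                raise AnnotationSchemaError(
                    f"{source}: {bone}.{key} must be [x, y], got {pt!r}")
        segments[bone] = AxisSegment(bone, tuple(axis["proximal"]),
                                     tuple(axis["distal"]))
    missing = [b for b in BONES if b not in segments]
    if missing:
        raise AnnotationSchemaError(f"{source}: missing bone(s) {missing}")
    try:
        return AxisAnnotation(image_height=doc["image_height"],
                              image_width=doc["image_width"],
                              side=doc["side"], segments=segments)
    except BoundsError as exc:
        raise AnnotationSchemaError(f"{source}: {exc}") from exc


def read_annotation(path) -> AxisAnnotation:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    return annotation_from_dict(doc, source=str(path))


def write_annotation(annotation: AxisAnnotation, path) -> None:
    with open(path, "w") as fh:
        json.dump(annotation_to_dict(annotation), fh, indent=1)
        fh.write("\n")


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG as floats scaled to [0, 1]."""
    img = Image.open(path)
    if img.mode not in ("L", "I;16", "I"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=np.float64)
    scale = 65535.0 if img.mode in ("I;16", "I") else 255.0
    return arr / scale


def write_image(image: np.ndarray, path, bit_depth: int = 16) -> None:
    """Write a [0, 1] float image as an 8- or 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 16:
        Image.fromarray((arr * 65535.0).round().astype(np.uint16)).save(path)
    elif bit_depth == 8:
        Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)
    else:
        raise ValueError("bit_depth must be 8 or 16")


def angles_to_frame(records: Sequence[dict]) -> pd.DataFrame:
    """Assemble measurement records into the angles CSV layout.

    Each record holds ``case_id``, ``side``, an :class:`AngleSet` (or None)
    under ``angles`` and a per-bone status dict under ``status``.
    """
    rows: List[dict] = []
    for rec in records:
        angles: AngleSet | None = rec.get("angles")
        row = {"case_id": rec["case_id"], "side": rec.get("side", "")}
        if angles is not None:
            row.update({k: round(v, 2) for k, v in angles.as_dict().items()})
        else:
            row.update({k: np.nan for k in
                        ("PH1a", "MT1a", "MT2a", "MT3a", "MT4a", "MT5a",
                         "HVA", "IMA")})
        for bone, flag in (rec.get("status") or {}).items():
            row[f"status_{bone}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def write_angles_csv(records: Sequence[dict], path) -> None:
    angles_to_frame(records).to_csv(path, index=False)


def read_angles_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
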