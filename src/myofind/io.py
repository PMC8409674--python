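"""Reading and writing the tool's on-disk formats.

Videos and focal stacks are multi-page TIFF (one page per frame, 16-bit
grayscale); annotations and detections are JSON; configs are YAML. All
coordinates are (row, col), 0-based, with half-open bounding boxes.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml

from .frame import FrameStack
from .motion import MotionConfig
from .phantom import PhantomSpec
from .static_detect import CellCandidate, DetectorConfig

COORD_NOTE = ("(row, col), 0-based; bbox half-open "
              "(min_row, min_col, max_row, max_col)")


def write_stack(path, stack: FrameStack) -> None:
    """Write a stack as multi-page 16-bit grayscale TIFF."""
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    meta = {"pixel_size_um": stack.pixel_size}
    if stack.frame_rate:
        meta["frame_rate_fps"] = stack.frame_rate
    tifffile.imwrite(path, data, photometric="minisblack", metadata=meta)


def read_stack(path, pixel_size: Optional[float] = None,
               frame_rate: Optional[float] = None) -> FrameStack:
    """Read a multi-page TIFF into a stack.

    Calibration is taken from the TIFF's ImageJ/shaped metadata when present;
    an explicit ``pixel_size`` argument overrides it and is required when the
    file carries none.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata or tf.imagej_metadata
    if isinstance(meta, (list, tuple)) and meta:
        meta = meta[0]
    meta = meta or {}
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate_fps")
    if ps is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size")
    if data.ndim == 2:
        data = data[None]
    return FrameStack(data.astype(np.float64), float(ps),
                      frame_rate=float(fr) if fr else None)


def write_detections(path, candidates: Sequence[CellCandidate] | Sequence[dict],
                     pixel_size: float) -> None:
    items = [c.to_dict() if isinstance(c, CellCandidate) else c
             for c in candidates]
    payload = {"coordinate_convention": COORD_NOTE,
               "pixel_size_um": pixel_size,
               "detections": items}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_detections(path) -> list[dict]:
    with open(path) as fh:
        payload = json.load(fh)
    return payload["detections"] if isinstance(payload, dict) else payload


def load_configs(path) -> tuple[DetectorConfig, MotionConfig, dict]:
    """Load detector/motion configs (and any extras) from one YAML file.

    Recognised top-level keys: ``detector``, ``motion``; everything else is
    returned untouched in the extras dict.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    det = DetectorConfig(**raw.pop("detector", {}))
    mot = MotionConfig(**raw.pop("motion", {}))
    return det, mot, raw


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("image_size", "cell_length_range", "cell_width_range",
                "sarcomere_period_range", "orientation_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PhantomSpec(**raw)


def save_phantom_spec(path, spec: PhantomSpec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)
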