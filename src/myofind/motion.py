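"""Beating detection from per-pixel temporal variance (shifted-data form).

The per-pixel variance of intensity through time marks moving pixels, but a
naive two-pass computation needs the temporal mean first. The shifted-data
(computations-with-shifted-data) form needs a single pass given any constant
shift K inside the sample range; the first frame of the stream is used as K.
The variance map, normalised to [0, 255], is binarised into "motion" pixels
and a candidate is called beating when motion pixels cover at least 5% of its
mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .frame import Frame, FrameStack
from .static_detect import CellCandidate, otsu_threshold


@dataclass
class MotionConfig:
    """Parameters of the motion (beating) classifier.

    ``n_frames`` is the stream length used for variance accumulation (default
    20, i.e. about one second at 20 fps — at 2 Hz pacing that covers at least
    one full beat). ``motion_pixel_threshold`` is either ``"otsu"`` (threshold
    the normalised variance map by Otsu) or a fixed numeric threshold on the
    [0, 255] scale. Maps whose raw variance maximum is below
    ``noise_floor_factor`` times the median per-pixel variance are treated as
    pure noise (no motion pixels). A candidate is beating when the motion
    pixel fraction of its mask is at least ``motion_area_ratio_threshold``
    (inclusive).
    """

    n_frames: int = 20
    motion_pixel_threshold: Union[str, float] = "otsu"
    motion_area_ratio_threshold: float = 0.05
    noise_floor_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 < self.motion_area_ratio_threshold < 1:
            raise ValueError("motion_area_ratio_threshold must be in (0, 1)")


class MotionAccumulator:
    """One-pass shifted-data variance over a stream of frames.

    The first accumulated frame becomes the shift K; subsequent frames add
    ``x - K`` and ``(x - K)²`` into float64 running sums, so 16-bit input is
    safe for at least 1e4 frames. ``finalize`` needs at least two frames
    (the estimator divides by n - 1).
    """

    def __init__(self) -> None:
        self.K: Optional[np.ndarray] = None
        self.Ex: Optional[np.ndarray] = None
        self.Ex2: Optional[np.ndarray] = None
        self.n: int = 0

    def accumulate(self, frame: Frame | np.ndarray) -> "MotionAccumulator":
        x = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, float)
        if self.K is None:
            self.K = x.astype(np.float64).copy()
            self.Ex = np.zeros_like(self.K)
            self.Ex2 = np.zeros_like(self.K)
        elif x.shape != self.K.shape:
            raise ValueError(
                f"frame shape {x.shape} does not match stream shape {self.K.shape}")
        d = x - self.K
        self.Ex += d
        self.Ex2 += d * d
        self.n += 1
        return self

    def finalize(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (variance, normalized) images.

        variance = (Ex2 - Ex²/n) / (n - 1); normalized is an affine rescale
        of variance with min -> 0 and max -> 255 (all-zero when the variance
        map is constant).
        """
        if self.n < 2:
            raise ValueError(f"finalize needs at least 2 frames, got {self.n}")
        variance = (self.Ex2 - (self.Ex * self.Ex) / self.n) / (self.n - 1)
        variance = np.maximum(variance, 0.0)  # clamp float cancellation error
        vmin, vmax = float(variance.min()), float(variance.max())
        if vmax > vmin:
            normalized = np.clip((variance - vmin) * (255.0 / (vmax - vmin)),
                                 0.0, 255.0)
        else:
            normalized = np.zeros_like(variance)
        return variance, normalized


def variance_map(stack: FrameStack, n_frames: Optional[int] = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate the first ``n_frames`` of a stack and finalize."""
    acc = MotionAccumulator()
    n = len(stack) if n_frames is None else min(n_frames, len(stack))
    for i in range(n):
        acc.accumulate(stack.data[i])
    return acc.finalize()


def motion_mask(normalized: np.ndarray, config: MotionConfig | None = None,
                variance: Optional[np.ndarray] = None) -> np.ndarray:
    """Binarise the normalised variance map into motion pixels.

    When ``variance`` is given, a noise floor is applied first: if its
    maximum is below ``noise_floor_factor`` times its median the whole map is
    treated as sensor noise and no pixel is motion. Otherwise the normalised
    map is thresholded by Otsu (default) or by the fixed numeric threshold in
    the config.
    """
    config = config or MotionConfig()
    if variance is not None:
        med = float(np.median(variance))
        if float(variance.max()) < config.noise_floor_factor * med:
            return np.zeros(normalized.shape, dtype=bool)
    if normalized.max() == normalized.min():
        return np.zeros(normalized.shape, dtype=bool)
    if config.motion_pixel_threshold == "otsu":
        t = otsu_threshold(normalized)
    else:
        t = float(config.motion_pixel_threshold)
    return normalized >= t


def is_beating(candidate: CellCandidate, normalized: np.ndarray,
               config: MotionConfig | None = None,
               variance: Optional[np.ndarray] = None,
               precomputed_mask: Optional[np.ndarray] = None
               ) -> tuple[bool, float]:
    """Classify one candidate as beating from the motion map.

    motion_ratio = (motion pixels inside the candidate mask) / (mask area);
    the candidate beats when the ratio reaches the 5% threshold (inclusive).
    Returns ``(beating, motion_ratio)`` and stores both on the candidate.
    """
    config = config or MotionConfig()
    area = int(candidate.mask.sum())
    if area == 0:
        raise ValueError("candidate mask is empty")
    mmask = precomputed_mask if precomputed_mask is not None else motion_mask(
        normalized, config, variance)
    ratio = float(mmask[candidate.mask].sum()) / area
    beating = ratio >= config.motion_area_ratio_threshold
    candidate.motion_ratio = ratio
    candidate.is_beating = beating
    return beating, ratio


def min_stream_length(frame_rate: float, pacing_rate: float) -> int:
    """Frames needed to cover at least one full beat at the pacing rate."""
    return int(np.ceil(frame_rate / pacing_rate))
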