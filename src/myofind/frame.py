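"""Core image containers: a calibrated frame and a stack of frames.

Coordinates are always (row, col), 0-based; bounding boxes are half-open
``(min_row, min_col, max_row, max_col)``. Physical calibration is carried as
``pixel_size`` in micrometres per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MIN_FRAME_SIDE = 64


@dataclass
class Frame:
    """One calibrated 2D grayscale image.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities (any numeric dtype; converted to float64).
    pixel_size : float
        Calibration in µm/pixel; must be positive.
    frame_index : int
        Position of this frame in its parent stream.
    z : float, optional
        Focal position in µm, when the frame comes from a focal sweep.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_index: int = 0
    z: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < MIN_FRAME_SIDE:
            raise ValueError(
                f"frame must be at least {MIN_FRAME_SIDE}x{MIN_FRAME_SIDE} "
                f"pixels, got {self.pixels.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FrameStack:
    """A time-ordered stream of frames sharing one calibration.

    ``data`` has shape (n_frames, rows, cols). ``frame_rate`` is frames per
    second and is needed only when traces are expressed against time.
    """

    data: np.ndarray
    pixel_size: float
    frame_rate: Optional[float] = None
    z: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (t, rows, cols), got {self.data.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def __len__(self) -> int:
        return self.data.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.data[i], self.pixel_size, frame_index=i, z=self.z)

    def __iter__(self):
        for i in range(len(self)):
            yield self.frame(i)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]
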