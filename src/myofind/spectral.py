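"""Sarcomere-length measurement by 1D FFT of a column-averaged profile.

A 256x30 pixel region is averaged column-wise into a 1D intensity profile;
the magnitude spectrum of the mean-subtracted profile is searched within the
spatial-frequency band corresponding to sarcomere spacings of 1-2 µm. The
in-band peak Fmax, a baseline Fbase (the higher of the two local minima
flanking the peak) and their ratio FSNR score the signal quality; the
sarcomere length is the reciprocal of the (parabolically refined) peak
frequency. Cells whose FSNR falls below 2.5 are conventionally excluded as
low quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .frame import Frame, FrameStack
from .static_detect import CellCandidate

SL_BAND_UM = (1.0, 2.0)  # sarcomere-length measurement band
DEFAULT_FSNR_THRESHOLD = 2.5
PROFILE_WIDTH = 256
PROFILE_HEIGHT = 30


@dataclass
class MeasureRegion:
    """A 256x30 oriented measurement window.

    ``center`` is the (row, col) pixel centre; ``angle`` rotates the window
    counter-clockwise as displayed. At angle 0 the 256-pixel width runs along
    image columns, so column averaging assumes vertical sarcomere bands.
    """

    center: tuple[float, float]
    width: int = PROFILE_WIDTH
    height: int = PROFILE_HEIGHT
    angle: float = 0.0

    def sample_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) sample coordinates, each of shape (height, width)."""
        da = np.arange(self.height) - (self.height - 1) / 2.0
        db = np.arange(self.width) - (self.width - 1) / 2.0
        da, db = np.meshgrid(da, db, indexing="ij")
        th = np.deg2rad(self.angle)
        rows = self.center[0] + da * np.cos(th) - db * np.sin(th)
        cols = self.center[1] + da * np.sin(th) + db * np.cos(th)
        return rows, cols


@dataclass
class SarcomereSpectrum:
    """Magnitude spectrum of one profile with its in-band summary scores."""

    magnitudes: np.ndarray  # f_i, one per rfft bin
    freqs: np.ndarray  # cycles/µm per bin
    band: tuple[int, int]  # [i_min, i_max], inclusive bin indices
    Fmax: float
    peak_bin: Optional[int]
    Fbase: float
    FSNR: float
    sarcomere_length: Optional[float]  # µm, None when no peak is reported


def extract_region(frame: Frame, region: MeasureRegion) -> np.ndarray:
    """Bilinear sample of the oriented window; shape (height, width)."""
    rows, cols = region.sample_coords()
    h, w = frame.shape
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() > h - 1 or cols.max() > w - 1):
        raise ValueError(
            f"measure region (center={region.center}, angle={region.angle}) "
            f"extends outside the {h}x{w} frame")
    return ndimage.map_coordinates(frame.pixels, [rows, cols], order=1)


def profile(frame: Frame, region: MeasureRegion) -> np.ndarray:
    """Column-averaged 1D intensity profile of the measurement window."""
    return extract_region(frame, region).mean(axis=0)


def _flanking_minimum(mags: np.ndarray, start: int, step: int, stop: int) -> float:
    """Walk from ``start`` in direction ``step`` until magnitude stops
    decreasing; return the minimum found (band-edge value if reached)."""
    i = start
    while i != stop and mags[i + step] < mags[i]:
        i += step
    return float(mags[i])


def _parabolic_refine(logm: np.ndarray, i: int) -> float:
    """Sub-bin offset of a peak at bin i from its two neighbours."""
    a, b, c = logm[i - 1], logm[i], logm[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:  # not a strict local max in log-magnitude
        return 0.0
    offset = 0.5 * (a - c) / denom
    return float(np.clip(offset, -0.5, 0.5))


def spectrum(prof: np.ndarray, pixel_size: float,
             band_um: tuple[float, float] = SL_BAND_UM,
             refine: bool = True, window: Optional[str] = None,
             ) -> SarcomereSpectrum:
    """Score a 1D profile: in-band peak, flanking-minima baseline, FSNR, SL.

    The profile is mean-subtracted (so the DC bin can never be the peak) and
    optionally Hann-windowed, then transformed with a real FFT. Band limits
    are the bins whose period lies within ``band_um``. The peak frequency is
    refined by 3-point parabolic interpolation on log magnitudes unless
    ``refine`` is off; the sarcomere length is its reciprocal, clipped to the
    band.
    """
    prof = np.asarray(prof, dtype=np.float64)
    n = prof.size
    x = prof - prof.mean()
    if window == "hann":
        x = x * np.hanning(n)
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=pixel_size)  # cycles/µm
    f_lo, f_hi = 1.0 / band_um[1], 1.0 / band_um[0]
    in_band = np.nonzero((freqs >= f_lo) & (freqs <= f_hi))[0]
    if in_band.size < 3:
        raise ValueError(
            f"the {band_um} µm band holds {in_band.size} bins at pixel_size="
            f"{pixel_size} with a {n}-sample profile; need pixel_size <= "
            f"{band_um[0] / 2:.3f} µm/px for at least 3 bins")
    i_min, i_max = int(in_band[0]), int(in_band[-1])
    band_mags = mags[i_min:i_max + 1]
    Fmax = float(band_mags.max())
    if Fmax == 0.0:
        return SarcomereSpectrum(mags, freqs, (i_min, i_max), 0.0, None, 0.0,
                                 0.0, None)
    peak_bin = i_min + int(band_mags.argmax())
    left = _flanking_minimum(mags, peak_bin, -1, i_min)
    right = _flanking_minimum(mags, peak_bin, +1, i_max)
    Fbase = max(left, right)
    FSNR = float(Fmax / Fbase) if Fbase > 0 else float("inf")

    peak_freq = freqs[peak_bin]
    if refine and i_min < peak_bin < i_max:
        with np.errstate(divide="ignore"):
            logm = np.log(np.maximum(mags, 1e-300))
        df = freqs[1] - freqs[0]
        peak_freq = peak_freq + _parabolic_refine(logm, peak_bin) * df
    sl = float(np.clip(1.0 / peak_freq, band_um[0], band_um[1]))
    return SarcomereSpectrum(mags, freqs, (i_min, i_max), Fmax, peak_bin,
                             float(Fbase), FSNR, sl)


def measure_frame(frame: Frame, region: MeasureRegion, **kw) -> SarcomereSpectrum:
    """Profile + spectrum of one frame in one region."""
    return spectrum(profile(frame, region), frame.pixel_size, **kw)


def snr_filter(candidates: Sequence[CellCandidate],
               threshold: float = DEFAULT_FSNR_THRESHOLD
               ) -> list[CellCandidate]:
    """Keep candidates with FSNR >= threshold (inclusive).

    Candidates below threshold get ``rejected_by = "snr"``; the accepted
    list is returned, the input list is annotated in place.
    """
    kept = []
    for cand in candidates:
        if cand.fsnr is not None and cand.fsnr >= threshold:
            kept.append(cand)
        else:
            cand.rejected_by = cand.rejected_by or "snr"
    return kept


def measure_trace(stack: FrameStack, region: MeasureRegion,
                  fsnr_threshold: float = DEFAULT_FSNR_THRESHOLD,
                  **kw) -> pd.DataFrame:
    """Per-frame sarcomere length in one region.

    Returns a DataFrame with columns ``frame_index``, ``time_s``,
    ``sarcomere_length_um`` and ``fsnr``. Frames whose FSNR is below the
    threshold report NaN for the length rather than a fabricated value;
    ``time_s`` is NaN when the stack has no frame rate.
    """
    rows = []
    for i in range(len(stack)):
        spec = measure_frame(stack.frame(i), region, **kw)
        t = i / stack.frame_rate if stack.frame_rate else float("nan")
        sl = (spec.sarcomere_length
              if spec.FSNR >= fsnr_threshold and spec.sarcomere_length is not None
              else float("nan"))
        rows.append((i, t, sl, spec.FSNR))
    return pd.DataFrame(rows, columns=["frame_index", "time_s",
                                       "sarcomere_length_um", "fsnr"])


def trace_baseline(trace: pd.DataFrame) -> float:
    """Resting sarcomere length: the median of the valid per-frame values."""
    vals = trace["sarcomere_length_um"].dropna()
    return float(vals.median()) if len(vals) else float("nan")
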