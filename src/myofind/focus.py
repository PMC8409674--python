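"""Filter layer: reorientation, fine autofocus, angle correction, region pick.

After a beating cell is found, the measurement quality is optimised before
recording: the cell is digitally rotated so its long axis is horizontal
(sarcomere bands vertical, matching the column-averaging direction of the
profile), the focal plane is refined in two sweeps (first maximising the
in-band spectral peak Fmax, then the spectral SNR), the residual sarcomere
orientation is estimated from a double 2D FFT, and the best of three stacked
256x30 regions is selected by FSNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .frame import Frame
from .spectral import MeasureRegion, extract_region, measure_frame
from .static_detect import CellCandidate

logger = logging.getLogger(__name__)

ANGLE_GRID_STEP_DEG = 0.5
ANGLE_BAND_PEAK_RATIO = 6.0  # in-band peak/median below this -> no estimate
_DC_EXCLUSION_PX = 3


@dataclass
class FocusSweepConfig:
    """Two-sweep autofocus parameters.

    Ranges are µm half-widths around the sweep centre. ``frames_per_plane``
    frames are scored at each plane and the scores averaged, matching an
    instrument that dwells a few camera frames per z position; a source that
    always returns the same frame simply contributes identical scores.
    The sweep spectra use a Hann window (``window``): without one the
    baseline of the peak is dominated by rectangular-window sidelobe leakage,
    which scales with the peak itself and makes FSNR focus-insensitive.
    """

    coarse_range: float = 10.0
    coarse_step: float = 2.0
    fine_range: float = 2.0
    fine_step: float = 0.5
    frames_per_plane: int = 4
    window: Optional[str] = "hann"

    def __post_init__(self) -> None:
        if self.coarse_step <= 0 or self.fine_step <= 0:
            raise ValueError("sweep steps must be > 0")
        if not self.fine_range < self.coarse_range:
            raise ValueError("fine_range must be smaller than coarse_range")
        if self.frames_per_plane < 1:
            raise ValueError("frames_per_plane must be >= 1")


@dataclass
class FocusResult:
    """Outcome of the two autofocus sweeps.

    ``best_z_coarse`` maximises the in-band peak Fmax over the coarse sweep;
    ``best_z_fine`` maximises FSNR over the fine sweep centred there.
    ``per_z`` tabulates (sweep, z, Fmax, FSNR) for every evaluated plane.
    """

    best_z_coarse: float
    best_z_fine: float
    per_z: pd.DataFrame


def rotate_about(frame: Frame, angle_deg: float, center: tuple[float, float],
                 fill: Optional[float] = None) -> Frame:
    """Rotate frame content by ``angle_deg`` CCW (as displayed) about a point.

    Bilinear interpolation; pixels coming from outside the frame are filled
    with ``fill`` (default: the frame's median intensity).
    """
    if fill is None:
        fill = float(np.median(frame.pixels))
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    # output (r', c') pulls from input via the inverse rotation in (row, col)
    m_inv = np.array([[c, s], [-s, c]])
    center = np.asarray(center, dtype=float)
    offset = center - m_inv @ center
    out = ndimage.affine_transform(frame.pixels, m_inv, offset=offset,
                                   order=1, mode="constant", cval=fill)
    return Frame(out, frame.pixel_size, frame.frame_index, frame.z)


def reorient(frame: Frame, candidate: CellCandidate) -> Frame:
    """Rotate the frame so the candidate's long axis is horizontal."""
    return rotate_about(frame, -candidate.orientation, candidate.centroid)


def _sweep(source: Callable[[float], Frame], region: MeasureRegion,
           zs: np.ndarray, score: str, frames_per_plane: int,
           window: Optional[str]) -> tuple[float, list[tuple]]:
    rows = []
    for z in zs:
        fmaxes, fsnrs = [], []
        for _ in range(frames_per_plane):
            frame = source(float(z))
            if frame is None:
                raise RuntimeError(f"focus source returned no frame at z={z}")
            spec = measure_frame(frame, region, window=window)
            fmaxes.append(spec.Fmax)
            fsnrs.append(spec.FSNR)
        rows.append((float(z), float(np.mean(fmaxes)), float(np.mean(fsnrs))))
    vals = np.array([r[1] if score == "Fmax" else r[2] for r in rows])
    best = vals.max()
    centre = 0.5 * (zs[0] + zs[-1])
    winners = [z for z, v in zip(zs, vals) if v == best]
    winners.sort(key=lambda z: (abs(z - centre), z))
    return float(winners[0]), rows


def fine_autofocus(source: Callable[[float], Frame], region: MeasureRegion,
                   config: FocusSweepConfig | None = None,
                   center_z: float = 0.0) -> FocusResult:
    """Two-sweep autofocus over a focusable source (z -> Frame).

    Sweep 1 scans ``center_z ± coarse_range`` at ``coarse_step`` and picks the
    z maximising the in-band peak Fmax; sweep 2 scans the winner ±
    ``fine_range`` at ``fine_step`` and picks the z maximising FSNR. Ties go
    to the z closest to the sweep centre, then the lower z.
    """
    config = config or FocusSweepConfig()
    zs1 = center_z + np.arange(-config.coarse_range,
                               config.coarse_range + config.coarse_step / 2,
                               config.coarse_step)
    z_coarse, rows1 = _sweep(source, region, zs1, "Fmax",
                             config.frames_per_plane, config.window)
    zs2 = z_coarse + np.arange(-config.fine_range,
                               config.fine_range + config.fine_step / 2,
                               config.fine_step)
    z_fine, rows2 = _sweep(source, region, zs2, "FSNR",
                           config.frames_per_plane, config.window)
    per_z = pd.DataFrame(
        [("coarse",) + r for r in rows1] + [("fine",) + r for r in rows2],
        columns=["sweep", "z_um", "Fmax", "FSNR"])
    return FocusResult(z_coarse, z_fine, per_z)


def _line_samples(image: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Bilinear samples along lines through the image centre.

    The line at display angle a runs in direction (-sin a, cos a) in
    (row, col); a small disk around the centre is excluded so the residual
    DC term cannot dominate. Shape (n_angles, n_samples).
    """
    n = image.shape[0]
    c = n // 2  # fftshift places the zero-frequency bin here
    t = np.arange(_DC_EXCLUSION_PX, n // 2 - 1, dtype=float)
    t = np.concatenate([-t[::-1], t])
    th = np.deg2rad(angles_deg)
    rows = c - np.outer(np.sin(th), t)
    cols = c + np.outer(np.cos(th), t)
    vals = ndimage.map_coordinates(image, [rows.ravel(), cols.ravel()],
                                   order=1, mode="constant")
    return vals.reshape(len(angles_deg), -1)


def estimate_angle(frame: Frame, region: MeasureRegion,
                   band_um: tuple[float, float] = (1.0, 2.0),
                   band_peak_ratio: float = ANGLE_BAND_PEAK_RATIO
                   ) -> Optional[float]:
    """Residual sarcomere orientation from a double 2D FFT, in (-90, 90].

    The measurement window is mean-subtracted, Hann-tapered (a plain
    rectangular window leaves a sinc cross in the spectrum that swamps the
    orientation signal) and zero-padded to a square. The magnitude of its 2D
    FFT is transformed a second time; a periodic band structure then shows up
    as a bright line through the origin along the band direction, modulated
    by the window's own double-FFT envelope. The line angle is found by
    maximising the envelope-normalised magnitude summed along sampled lines
    (0.5° grid, parabolic refinement).

    Returns the correction angle: positive means the bands are rotated
    counter-clockwise from vertical, and rotating the frame content by the
    negated value makes them vertical. Returns ``None`` when the first
    spectrum has no credible sarcomere peak — the maximum magnitude in the
    ``band_um`` annulus below ``band_peak_ratio`` times the annulus median —
    as on an isotropic noise region.
    """
    patch = extract_region(frame, region)
    patch = patch - patch.mean()
    ph, pw = patch.shape
    taper = np.hanning(ph)[:, None] * np.hanning(pw)[None, :]
    n = max(ph, pw)
    square = np.zeros((n, n))
    support = np.zeros((n, n))
    r0, c0 = (n - ph) // 2, (n - pw) // 2
    square[r0:r0 + ph, c0:c0 + pw] = patch * taper
    support[r0:r0 + ph, c0:c0 + pw] = taper

    f1 = np.abs(np.fft.fftshift(np.fft.fft2(square)))

    # gate: credible periodicity in the sarcomere band of the first spectrum
    fgrid = np.fft.fftshift(np.fft.fftfreq(n, d=frame.pixel_size))
    rad = np.hypot(fgrid[None, :], fgrid[:, None])
    annulus = f1[(rad >= 1.0 / band_um[1]) & (rad <= 1.0 / band_um[0])]
    ann_med = float(np.median(annulus))
    if ann_med <= 0 or float(annulus.max()) / ann_med < band_peak_ratio:
        return None

    f2 = np.abs(np.fft.fftshift(np.fft.fft2(f1 - f1.mean())))
    w1 = np.abs(np.fft.fftshift(np.fft.fft2(support)))
    env = np.abs(np.fft.fftshift(np.fft.fft2(w1 - w1.mean())))

    angles = np.arange(-90.0 + ANGLE_GRID_STEP_DEG,
                       90.0 + ANGLE_GRID_STEP_DEG / 2, ANGLE_GRID_STEP_DEG)
    vf = _line_samples(f2, angles)
    ve = _line_samples(env, angles)
    # envelope-weighted score: fringe contrast survives, the window's
    # anisotropic envelope cancels
    sums = (ve * vf).sum(axis=1) / np.maximum((ve * ve).sum(axis=1), 1e-12)
    i = int(sums.argmax())
    best = angles[i]
    # parabolic refinement on the angular response (wrap at the grid ends)
    a = sums[(i - 1) % len(sums)]
    b = sums[i]
    cc = sums[(i + 1) % len(sums)]
    denom = a - 2 * b + cc
    if denom < 0:
        best = best + 0.5 * (a - cc) / denom * ANGLE_GRID_STEP_DEG
    # the bright line runs along the bands; bands vertical -> line at 90°
    correction = best - 90.0
    if correction <= -90.0:
        correction += 180.0
    return float(correction)


def select_region(frame: Frame, center: tuple[float, float],
                  offset_px: int = 30, angle: float = 0.0
                  ) -> tuple[MeasureRegion, list[tuple[MeasureRegion, float]]]:
    """Pick the best of three stacked 256x30 regions by FSNR.

    Candidates sit at the given centre and ``offset_px`` pixels above and
    below it (perpendicular to the profile direction). Offsets shrink
    symmetrically when the outer regions would not fit in the frame. Ties go
    to the centre region. Returns the winner and all (region, FSNR) pairs.
    """
    h, w = frame.shape
    half_h = MeasureRegion(center, angle=angle).height / 2.0
    max_up = center[0] - half_h
    max_down = (h - 1) - center[0] - half_h
    fit = int(max(0, min(offset_px, np.floor(max_up), np.floor(max_down))))
    if fit < offset_px:
        logger.info("select_region: shrinking offsets from %d to %d px to fit "
                    "the frame", offset_px, fit)
    scored = []
    for off in (0, -fit, fit):
        region = MeasureRegion((center[0] + off, center[1]), angle=angle)
        fsnr = measure_frame(frame, region).FSNR
        scored.append((region, float(fsnr)))
    best = max(scored, key=lambda rf: rf[1])
    # max() keeps the first maximum, and the centre region is listed first
    return best[0], scored
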