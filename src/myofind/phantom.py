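"""Synthetic brightfield cardiomyocyte phantoms with exact ground truth.

Emulates what an isolated adult cardiomyocyte looks like under a 20x
brightfield objective: a rod-shaped cell with a dark border and periodic
sarcomere striping (spatial period 1–2 µm) perpendicular to the long axis, on
a smoothly textured background with additive camera noise. Beating cells
shorten along the long axis following a raised-cosine pulse (~0.1 s per beat,
field-paced so all cells contract in phase); the striping compresses
proportionally, exactly as real sarcomeres do.

The generator returns pixel data together with exact annotations
(:class:`GroundTruthCell`), so detection, motion, spectral and focus code can
all be validated without recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .frame import Frame, FrameStack

# Fixed optical-appearance constants (intensity units on a 16-bit-ish scale).
STRIPE_AMPLITUDE = 350.0
INTERIOR_OFFSET = 120.0
BORDER_DROP = 500.0
BORDER_WIDTH_UM = 1.5
TEXTURE_AMPLITUDE = 60.0
TEXTURE_SIGMA_PX = 40.0
BEAT_DURATION_S = 0.1  # a paced contraction takes < 0.1 s
BEAT_PHASE_S = 0.25  # first pulse starts here, so frame 0 is at rest
INTENSITY_MAX = 65535.0

_PLACEMENT_TRIES = 200


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic dish / field of view.

    All lengths are micrometres unless the name says pixels. ``beat_fraction``
    of the cells beat; with field pacing at ``pacing_rate`` Hz all beating
    cells contract synchronously by ``contraction_amplitude`` fractional
    shortening. ``blur_per_z`` is the Gaussian blur sigma (pixels) added per
    µm of defocus when rendering focal stacks.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.25
    n_cells: int = 3
    cell_length_range: tuple[float, float] = (60.0, 100.0)
    cell_width_range: tuple[float, float] = (25.0, 40.0)
    sarcomere_period_range: tuple[float, float] = (1.6, 1.9)
    orientation_range: tuple[float, float] = (-8.0, 8.0)
    beat_fraction: float = 0.5
    pacing_rate: float = 2.0
    frame_rate: float = 20.0
    n_frames: int = 20
    contraction_amplitude: float = 0.08
    background_level: float = 2000.0
    noise_sd: float = 40.0
    blur_per_z: float = 2.5
    min_separation: float = 50.0
    clearance: float = 8.0
    placement_margin_px: int = 16
    placement_boxes: Optional[list[tuple[int, int, int, int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("cell_length_range", "cell_width_range",
                     "sarcomere_period_range", "orientation_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        lo, hi = self.sarcomere_period_range
        if lo < 1.0 or hi > 2.0:
            raise ValueError(
                "sarcomere_period_range must lie within [1.0, 2.0] µm, the "
                "band the spectral measurement assumes"
            )
        if not 0.0 <= self.beat_fraction <= 1.0:
            raise ValueError("beat_fraction must be in [0, 1]")


@dataclass
class GroundTruthCell:
    """Exact annotation for one phantom cell (resting geometry).

    ``bbox`` is the axis-aligned bounding box of the resting cell rectangle,
    0-based half-open (min_row, min_col, max_row, max_col). ``orientation`` is
    the long-axis angle in degrees, counter-clockwise from horizontal as
    displayed, in (-90, 90]. ``area`` is the analytic rectangle area in µm².
    """

    id: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    orientation: float
    sarcomere_period: float
    is_beating: bool
    area: float
    length: float = 0.0
    width: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthCell":
        d = dict(d)
        d["centroid"] = tuple(d["centroid"])
        d["bbox"] = tuple(d["bbox"])
        return cls(**d)


@dataclass
class _CellGeom:
    center: tuple[float, float]  # (row, col) px
    length: float  # µm
    width: float  # µm
    theta: float  # degrees CCW from horizontal
    period: float  # µm
    beating: bool

    def corners_px(self, pixel_size: float) -> np.ndarray:
        """Resting rectangle corners in (row, col) pixel coordinates."""
        hl, hw = self.length / 2.0, self.width / 2.0
        th = np.deg2rad(self.theta)
        pts = []
        for su, sv in ((1, 1), (1, -1), (-1, -1), (-1, 1)):
            u, v = su * hl, sv * hw
            x = u * np.cos(th) - v * np.sin(th)
            y_up = u * np.sin(th) + v * np.cos(th)
            pts.append((self.center[0] - y_up / pixel_size,
                        self.center[1] + x / pixel_size))
        return np.array(pts)


def _rect_overlap(a: np.ndarray, b: np.ndarray, pad_px: float) -> bool:
    """Do two convex quads, padded by ``pad_px``, intersect?

    Separating-axis test on the edge normals of both rectangles.
    """
    for quad in (a, b):
        for i in range(4):
            edge = quad[(i + 1) % 4] - quad[i]
            n = np.array([-edge[1], edge[0]])
            n = n / np.linalg.norm(n)
            pa = a @ n
            pb = b @ n
            if pa.max() + pad_px < pb.min() or pb.max() + pad_px < pa.min():
                return False
    return True


def _sample_cells(spec: PhantomSpec, rng: np.random.Generator) -> list[_CellGeom]:
    h, w = spec.image_size
    m = spec.placement_margin_px
    boxes = spec.placement_boxes or [(0, 0, h, w)]
    n_beat = int(round(spec.beat_fraction * spec.n_cells))
    beat_flags = np.zeros(spec.n_cells, dtype=bool)
    beat_flags[:n_beat] = True
    rng.shuffle(beat_flags)

    placed: list[_CellGeom] = []
    pad_px = spec.clearance / spec.pixel_size
    for i in range(spec.n_cells):
        ok = False
        for _ in range(_PLACEMENT_TRIES):
            length = rng.uniform(*spec.cell_length_range)
            width = rng.uniform(*spec.cell_width_range)
            theta = rng.uniform(*spec.orientation_range)
            period = rng.uniform(*spec.sarcomere_period_range)
            box = boxes[rng.integers(len(boxes))]
            geom = _CellGeom((0.0, 0.0), length, width, theta, period,
                             bool(beat_flags[i]))
            corners = geom.corners_px(spec.pixel_size)
            half_r = (corners[:, 0].max() - corners[:, 0].min()) / 2.0
            half_c = (corners[:, 1].max() - corners[:, 1].min()) / 2.0
            r_lo, c_lo = box[0] + m + half_r, box[1] + m + half_c
            r_hi, c_hi = box[2] - m - half_r, box[3] - m - half_c
            if r_lo >= r_hi or c_lo >= c_hi:
                continue
            center = (rng.uniform(r_lo, r_hi), rng.uniform(c_lo, c_hi))
            geom.center = center
            corners = geom.corners_px(spec.pixel_size)
            sep_px = spec.min_separation / spec.pixel_size
            too_close = any(
                np.hypot(center[0] - g.center[0], center[1] - g.center[1]) < sep_px
                or _rect_overlap(corners, g.corners_px(spec.pixel_size), pad_px)
                for g in placed
            )
            if not too_close:
                placed.append(geom)
                ok = True
                break
        if not ok:
            density = len(placed) / (h * w * spec.pixel_size ** 2 * 1e-6)
            raise PlacementError(
                f"could only place {len(placed)} of {spec.n_cells} cells in a "
                f"{h}x{w} px image (~{density:.0f} cells/mm² achievable); "
                f"reduce n_cells, min_separation or cell size"
            )
    return placed


def contraction_scale(t: float | np.ndarray, pacing_rate: float,
                      amplitude: float) -> float | np.ndarray:
    """Long-axis scale factor at time ``t`` (s) under field pacing.

    A raised-cosine pulse of duration 0.1 s repeats every 1/pacing_rate
    seconds; scale = 1 at rest, 1 - amplitude at peak contraction.
    """
    period = 1.0 / pacing_rate
    tau = np.mod(np.asarray(t, dtype=float) - BEAT_PHASE_S, period)
    w = np.where(tau < BEAT_DURATION_S,
                 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / BEAT_DURATION_S)),
                 0.0)
    out = 1.0 - amplitude * w
    return float(out) if np.isscalar(t) else out


def _render_cell(img: np.ndarray, geom: _CellGeom, spec: PhantomSpec,
                 scale: float) -> None:
    """Paint one cell into ``img`` in place, long axis scaled by ``scale``."""
    ps = spec.pixel_size
    hl = geom.length * scale / 2.0
    hw = geom.width / 2.0
    # conservative pixel bounding box of the (resting) cell plus margin
    corners = geom.corners_px(ps)
    r0 = max(int(np.floor(corners[:, 0].min())) - 2, 0)
    r1 = min(int(np.ceil(corners[:, 0].max())) + 3, img.shape[0])
    c0 = max(int(np.floor(corners[:, 1].min())) - 2, 0)
    c1 = min(int(np.ceil(corners[:, 1].max())) + 3, img.shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x = (cc - geom.center[1]) * ps
    y_up = (geom.center[0] - rr) * ps
    th = np.deg2rad(geom.theta)
    u = x * np.cos(th) + y_up * np.sin(th)
    v = -x * np.sin(th) + y_up * np.cos(th)
    inside = (np.abs(u) <= hl) & (np.abs(v) <= hw)
    if not inside.any():
        return
    edge_dist = np.minimum(hl - np.abs(u), hw - np.abs(v))
    material_u = u / scale  # stripes compress with the cell
    stripe = STRIPE_AMPLITUDE * np.cos(2.0 * np.pi * material_u / geom.period)
    interior = spec.background_level + INTERIOR_OFFSET + stripe
    border = spec.background_level - BORDER_DROP
    val = np.where(edge_dist < BORDER_WIDTH_UM, border, interior)
    block = img[r0:r1, c0:c1]
    block[inside] = val[inside]


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Static background: flat level plus smooth low-frequency texture."""
    h, w = spec.image_size
    bg = np.full((h, w), spec.background_level, dtype=np.float64)
    if TEXTURE_AMPLITUDE > 0:
        tex = rng.standard_normal((h, w))
        tex = ndimage.gaussian_filter(tex, TEXTURE_SIGMA_PX)
        sd = tex.std()
        if sd > 0:
            bg += TEXTURE_AMPLITUDE * tex / sd
    return bg


def _ground_truth(cells: Sequence[_CellGeom], spec: PhantomSpec) -> list[GroundTruthCell]:
    out = []
    for i, g in enumerate(cells):
        corners = g.corners_px(spec.pixel_size)
        bbox = (int(np.floor(corners[:, 0].min())),
                int(np.floor(corners[:, 1].min())),
                int(np.ceil(corners[:, 0].max())) + 1,
                int(np.ceil(corners[:, 1].max())) + 1)
        out.append(GroundTruthCell(
            id=i,
            centroid=(float(g.center[0]), float(g.center[1])),
            bbox=bbox,
            orientation=float(g.theta),
            sarcomere_period=float(g.period),
            is_beating=g.beating,
            area=float(g.length * g.width),
            length=float(g.length),
            width=float(g.width),
        ))
    return out


def generate_video(spec: PhantomSpec) -> tuple[FrameStack, list[GroundTruthCell]]:
    """Render a phantom video and its exact annotations.

    Returns a stack of ``spec.n_frames`` frames. Beating cells shorten along
    their long axis by ``spec.contraction_amplitude`` in a 0.1 s raised-cosine
    pulse at ``spec.pacing_rate``; static cells do not move. Identical specs
    (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _sample_cells(spec, rng)
    bg = _background(spec, rng)

    static_img = bg.copy()
    for g in cells:
        if not g.beating:
            _render_cell(static_img, g, spec, 1.0)

    frames = np.empty((spec.n_frames,) + spec.image_size, dtype=np.float64)
    for t_idx in range(spec.n_frames):
        t = t_idx / spec.frame_rate
        s = contraction_scale(t, spec.pacing_rate, spec.contraction_amplitude)
        img = static_img.copy()
        for g in cells:
            if g.beating:
                _render_cell(img, g, spec, float(s))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[t_idx] = np.clip(img, 0.0, INTENSITY_MAX)

    stack = FrameStack(frames, spec.pixel_size, frame_rate=spec.frame_rate)
    return stack, _ground_truth(cells, spec)


def generate_focal_stack(spec: PhantomSpec, z_positions: Sequence[float],
                         z_true: float) -> list[Frame]:
    """Render one resting phantom frame at a list of focal positions.

    The frame at focal position ``z`` is the in-focus image convolved with a
    Gaussian of sigma ``spec.blur_per_z * |z - z_true|`` pixels (strictly
    increasing blur with defocus), with fresh camera noise per plane. At
    ``z == z_true`` the in-focus image is returned unblurred.
    """
    z_positions = list(z_positions)
    if not z_positions:
        raise ValueError("z_positions must be non-empty")
    rng = np.random.default_rng(spec.seed)
    cells = _sample_cells(spec, rng)
    bg = _background(spec, rng)
    sharp = bg.copy()
    for g in cells:
        _render_cell(sharp, g, spec, 1.0)

    out = []
    for i, z in enumerate(z_positions):
        sigma = spec.blur_per_z * abs(z - z_true)
        img = ndimage.gaussian_filter(sharp, sigma) if sigma > 0 else sharp.copy()
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, INTENSITY_MAX)
        out.append(Frame(img, spec.pixel_size, frame_index=i, z=float(z)))
    return out


class FocalSource:
    """Live focusable-camera emulation over a resting phantom.

    Calling the source with a focal position returns a frame blurred by
    ``blur_per_z * |z - z_true|`` pixels with *fresh* camera noise on every
    call, the way a real camera behind a z-controllable objective would —
    repeated evaluation at one plane sees the same scene but new noise. The
    noise sequence is deterministic given the spec seed and the call order.
    Implements the focusable-source contract of the fine-autofocus sweep.
    """

    def __init__(self, spec: PhantomSpec, z_true: float):
        self.spec = spec
        self.z_true = float(z_true)
        rng = np.random.default_rng(spec.seed)
        cells = _sample_cells(spec, rng)
        sharp = _background(spec, rng)
        for g in cells:
            _render_cell(sharp, g, spec, 1.0)
        self._sharp = sharp
        self._cells = cells
        self._blur_cache: dict[float, np.ndarray] = {}
        self._noise_rng = np.random.default_rng((spec.seed, 0xF0CA))

    def __call__(self, z: float) -> Frame:
        z = float(z)
        if z not in self._blur_cache:
            sigma = self.spec.blur_per_z * abs(z - self.z_true)
            self._blur_cache[z] = (ndimage.gaussian_filter(self._sharp, sigma)
                                   if sigma > 0 else self._sharp)
        img = self._blur_cache[z]
        if self.spec.noise_sd > 0:
            img = img + self._noise_rng.normal(0.0, self.spec.noise_sd,
                                               size=img.shape)
        return Frame(np.clip(img, 0.0, INTENSITY_MAX), self.spec.pixel_size,
                     z=z)


def stripe_frame(period_um: float, angle_deg: float, pixel_size: float,
                 shape: tuple[int, int] = (256, 256), noise_sd: float = 0.0,
                 seed: int = 0, amplitude: float = STRIPE_AMPLITUDE,
                 level: float = 2000.0) -> Frame:
    """A full-frame sarcomere-like stripe pattern (test/calibration helper).

    Stripes are vertical bands at ``angle_deg == 0`` (intensity varies along
    columns with spatial period ``period_um``); positive angles rotate the
    bands counter-clockwise as displayed.
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    x = (cc - w / 2.0) * pixel_size
    y_up = (h / 2.0 - rr) * pixel_size
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y_up * np.sin(th)  # coordinate along the band normal
    img = level + amplitude * np.cos(2.0 * np.pi * u / period_um)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return Frame(img, pixel_size)


def save_annotations(path, cells: Sequence[GroundTruthCell]) -> None:
    """Write annotations as a JSON array (0-based, half-open bboxes)."""
    payload = {
        "coordinate_convention": "(row, col), 0-based; bbox half-open "
                                 "(min_row, min_col, max_row, max_col)",
        "cells": [c.to_dict() for c in cells],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_annotations(path) -> list[GroundTruthCell]:
    with open(path) as fh:
        payload = json.load(fh)
    items = payload["cells"] if isinstance(payload, dict) else payload
    return [GroundTruthCell.from_dict(d) for d in items]
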