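"""Scan orchestration and detection validation.

Plans an outward square-spiral tiling of a dish with overlapping fields of
view (FOVs), runs static + motion detection per FOV, measures each accepted
beating cell (reorient, angle refinement, region selection, sarcomere-length
trace, FSNR screen), suppresses duplicates across overlapping FOVs, and
scores detections against point annotations with sensitivity, precision and
F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .frame import Frame, FrameStack
from .static_detect import CellCandidate, DetectorConfig, detect_static
from .motion import MotionConfig, is_beating, motion_mask, variance_map
from .spectral import (DEFAULT_FSNR_THRESHOLD, MeasureRegion, measure_frame,
                       measure_trace, trace_baseline)
from .focus import estimate_angle, rotate_about

logger = logging.getLogger(__name__)

SUCCESS_FSNR_FRAME_FRACTION = 0.8  # trace "success": >= 80% frames pass FSNR


@dataclass
class ScanPlan:
    """Spiral tiling of a dish by overlapping FOVs.

    ``positions`` are FOV centres (row, col) in dish pixels, spiral order;
    consecutive grid steps are ``(1 - overlap_fraction) * fov_size`` in each
    axis.
    """

    fov_size: tuple[int, int]
    overlap_fraction: float
    grid_extent: tuple[int, int]
    positions: list[tuple[float, float]]

    @property
    def step(self) -> tuple[float, float]:
        return ((1.0 - self.overlap_fraction) * self.fov_size[0],
                (1.0 - self.overlap_fraction) * self.fov_size[1])


def plan_scan(fov_size: int | tuple[int, int],
              grid_extent: int | tuple[int, int],
              overlap_fraction: float = 0.30) -> ScanPlan:
    """Plan an outward square spiral over a grid of FOV positions.

    The spiral starts at the central grid cell, first moves +x (columns
    increasing), then turns counter-clockwise (as displayed), visiting every
    grid cell exactly once. A grid smaller than one FOV in either axis still
    yields at least the single central position.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if isinstance(fov_size, int):
        fov_size = (fov_size, fov_size)
    if isinstance(grid_extent, int):
        grid_extent = (grid_extent, grid_extent)
    ny, nx = max(1, grid_extent[0]), max(1, grid_extent[1])
    step_r = (1.0 - overlap_fraction) * fov_size[0]
    step_c = (1.0 - overlap_fraction) * fov_size[1]
    cy, cx = (ny - 1) // 2, (nx - 1) // 2

    # walk an unbounded square spiral, keep in-grid cells until all visited
    order: list[tuple[int, int]] = []
    seen = set()
    gy, gx = cy, cx
    # display CCW with first move +x: +x, then -row (up), -x, +row (down)
    dirs = [(0, 1), (-1, 0), (0, -1), (1, 0)]
    leg = 1
    d = 0
    if 0 <= gy < ny and 0 <= gx < nx:
        order.append((gy, gx))
        seen.add((gy, gx))
    while len(order) < ny * nx:
        for _ in range(2):
            dy, dx = dirs[d % 4]
            for _ in range(leg):
                gy, gx = gy + dy, gx + dx
                if 0 <= gy < ny and 0 <= gx < nx and (gy, gx) not in seen:
                    order.append((gy, gx))
                    seen.add((gy, gx))
            d += 1
        leg += 1
    positions = [(fov_size[0] / 2.0 + gy * step_r,
                  fov_size[1] / 2.0 + gx * step_c) for gy, gx in order]
    return ScanPlan(fov_size, overlap_fraction, (ny, nx), positions)


class DishSource:
    """A dish-sized phantom stack cut into overlapping FOV stacks.

    Mimics a microscope scanning one dish: ``fovs()`` yields the per-position
    video stream, and ``window(centroid, size)`` returns a measurement stack
    centred on a cell (the objective re-centres on the cell before
    measuring), padded with the median background where it leaves the dish.
    """

    def __init__(self, stack: FrameStack, plan: ScanPlan):
        self.stack = stack
        self.plan = plan

    def fovs(self) -> Iterable[tuple[int, tuple[int, int], FrameStack]]:
        h, w = self.stack.shape
        fh, fw = self.plan.fov_size
        for i, (pr, pc) in enumerate(self.plan.positions):
            r0 = int(round(pr - fh / 2.0))
            c0 = int(round(pc - fw / 2.0))
            r0 = min(max(r0, 0), h - fh)
            c0 = min(max(c0, 0), w - fw)
            sub = FrameStack(self.stack.data[:, r0:r0 + fh, c0:c0 + fw],
                             self.stack.pixel_size, self.stack.frame_rate)
            yield i, (r0, c0), sub

    def window(self, centroid: tuple[float, float], size: tuple[int, int]
               ) -> FrameStack:
        h, w = self.stack.shape
        sh, sw = size
        fill = float(np.median(self.stack.data[0]))
        r0 = int(round(centroid[0] - sh / 2.0))
        c0 = int(round(centroid[1] - sw / 2.0))
        out = np.full((len(self.stack), sh, sw), fill)
        rs, re = max(r0, 0), min(r0 + sh, h)
        cs, ce = max(c0, 0), min(c0 + sw, w)
        if rs < re and cs < ce:
            out[:, rs - r0:re - r0, cs - c0:ce - c0] = \
                self.stack.data[:, rs:re, cs:ce]
        return FrameStack(out, self.stack.pixel_size, self.stack.frame_rate)


@dataclass
class MeasuredCell:
    """One measured beating cell with full provenance."""

    fov_id: int
    candidate: CellCandidate
    dish_centroid: tuple[float, float]
    dish_bbox: tuple[int, int, int, int]
    fsnr: float
    trace: pd.DataFrame
    baseline_sl: Optional[float]
    angle_correction: Optional[float]
    successful: bool
    passed_snr: bool


@dataclass
class RunResult:
    measured: list[MeasuredCell]
    all_candidates: list[dict]  # provenance: every candidate of every FOV
    failures: list[tuple[int, str]]  # (fov_id, message)

    def accepted(self) -> list[MeasuredCell]:
        return [m for m in self.measured if m.passed_snr]


def _measure_cell(source: DishSource, cand: CellCandidate,
                  dish_centroid: tuple[float, float],
                  window_px: int, fsnr_threshold: float) -> tuple:
    """Re-centre on the cell, reorient, refine angle, pick region, trace."""
    win = source.window(dish_centroid, (window_px, window_px))
    center = (window_px / 2.0, window_px / 2.0)
    rot = [rotate_about(win.frame(i), -cand.orientation, center)
           for i in range(len(win))]
    ref = rot[0]
    region = MeasureRegion(center)
    correction = None
    try:
        correction = estimate_angle(ref, region)
    except ValueError:
        pass
    if correction is not None and abs(correction) > 0.25:
        rot = [rotate_about(f, -correction, center) for f in rot]
        ref = rot[0]
    from .focus import select_region
    best_region, _ = select_region(ref, center)
    rot_stack = FrameStack(np.stack([f.pixels for f in rot]),
                           win.pixel_size, win.frame_rate)
    trace = measure_trace(rot_stack, best_region, fsnr_threshold)
    fsnr = measure_frame(ref, best_region).FSNR
    return trace, fsnr, correction


def run(source: DishSource,
        detector: DetectorConfig | None = None,
        motion: MotionConfig | None = None,
        fsnr_threshold: float = DEFAULT_FSNR_THRESHOLD,
        measure_window_px: int = 320) -> RunResult:
    """Run the full two-layer pipeline over a dish scan.

    For each FOV in spiral order: static detection on the first frame, then
    variance-based beating classification over the stream; each accepted
    beating cell not already measured (its dish centroid at least
    ``detector.min_cell_separation`` µm from every previously measured cell)
    is re-centred, reoriented, angle-refined, region-selected and traced.
    Cells whose region FSNR is below the threshold are recorded but flagged
    as excluded. Per-FOV failures are logged and skipped, never fatal.
    """
    detector = detector or DetectorConfig()
    motion = motion or MotionConfig()
    measured: list[MeasuredCell] = []
    provenance: list[dict] = []
    failures: list[tuple[int, str]] = []
    ps = source.stack.pixel_size
    sep_px = detector.min_cell_separation / ps

    for fov_id, (r0, c0), sub in source.fovs():
        try:
            cands = detect_static(sub.frame(0), detector)
            variance, normalized = variance_map(sub, motion.n_frames)
            mmask = motion_mask(normalized, motion, variance)
            for cand in cands:
                if cand.accepted:
                    is_beating(cand, normalized, motion, precomputed_mask=mmask)
                rec = cand.to_dict()
                rec["fov_id"] = fov_id
                rec["dish_centroid"] = [cand.centroid[0] + r0,
                                        cand.centroid[1] + c0]
                provenance.append(rec)
                if not (cand.accepted and cand.is_beating):
                    continue
                dish_centroid = (cand.centroid[0] + r0, cand.centroid[1] + c0)
                dup = any(np.hypot(dish_centroid[0] - m.dish_centroid[0],
                                   dish_centroid[1] - m.dish_centroid[1]) < sep_px
                          for m in measured)
                if dup:
                    rec["duplicate_of_measured"] = True
                    continue
                trace, fsnr, correction = _measure_cell(
                    source, cand, dish_centroid, measure_window_px,
                    fsnr_threshold)
                cand.fsnr = fsnr
                rec["fsnr"] = fsnr
                ok_frames = (trace["fsnr"] >= fsnr_threshold).mean()
                bbox = cand.bbox
                measured.append(MeasuredCell(
                    fov_id=fov_id,
                    candidate=cand,
                    dish_centroid=dish_centroid,
                    dish_bbox=(bbox[0] + r0, bbox[1] + c0,
                               bbox[2] + r0, bbox[3] + c0),
                    fsnr=float(fsnr),
                    trace=trace,
                    baseline_sl=trace_baseline(trace),
                    angle_correction=correction,
                    successful=bool(ok_frames >= SUCCESS_FSNR_FRAME_FRACTION),
                    passed_snr=bool(fsnr >= fsnr_threshold),
                ))
        except Exception as exc:  # a scanning instrument must not halt
            logger.warning("FOV %d failed: %s", fov_id, exc)
            failures.append((fov_id, str(exc)))
    return RunResult(measured, provenance, failures)


# ---------------------------------------------------------------------------
# validation metrics


@dataclass
class DetectionMetrics:
    """TP/FP/FN counts and the derived scores.

    ``sensitivity`` and ``precision`` are ``None`` when their denominator is
    zero; F1 is the harmonic mean of the two when both are defined and
    nonzero.
    """

    tp: int
    fp: int
    fn: int
    sensitivity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    pct_successful: Optional[float] = None


def metrics_from_counts(tp: int, fp: int, fn: int) -> DetectionMetrics:
    sens = tp / (tp + fn) if tp + fn > 0 else None
    prec = tp / (tp + fp) if tp + fp > 0 else None
    f1 = None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2.0 * sens * prec / (sens + prec)
    return DetectionMetrics(tp, fp, fn, sens, prec, f1)


def match_detections(detections: Sequence, annotations: Sequence,
                     criterion: str = "point_in_bbox",
                     iou_threshold: float = 0.3) -> DetectionMetrics:
    """Greedy one-to-one matching of detections to annotations.

    ``detections`` provide ``dish_bbox``/``bbox`` (half-open) and
    ``dish_centroid``/``centroid``; ``annotations`` provide ``centroid`` (the
    annotation point) and optionally ``bbox``. With the default
    ``point_in_bbox`` criterion a detection is a true positive when an
    unmatched annotation point falls inside its bounding box (nearest
    centroid wins a tie); ``iou`` instead requires bounding-box IoU at or
    above ``iou_threshold``, for mask-level ground truth. Unmatched
    detections are false positives, unmatched annotations false negatives.
    """

    def det_box(d):
        return tuple(getattr(d, "dish_bbox", None) or getattr(d, "bbox"))

    def det_centroid(d):
        c = getattr(d, "dish_centroid", None)
        return tuple(c if c is not None else getattr(d, "centroid"))

    ann_pts = [tuple(a.centroid) for a in annotations]
    matched = [False] * len(annotations)
    tp = 0
    for det in detections:
        box = det_box(det)
        dc = det_centroid(det)
        best_j, best_dist = None, np.inf
        for j, pt in enumerate(ann_pts):
            if matched[j]:
                continue
            if criterion == "point_in_bbox":
                hit = box[0] <= pt[0] < box[2] and box[1] <= pt[1] < box[3]
            elif criterion == "iou":
                hit = _bbox_iou(box, tuple(annotations[j].bbox)) >= iou_threshold
            else:
                raise ValueError(f"unknown matching criterion {criterion!r}")
            if hit:
                dist = float(np.hypot(dc[0] - pt[0], dc[1] - pt[1]))
                if dist < best_dist:
                    best_j, best_dist = j, dist
        if best_j is not None:
            matched[best_j] = True
            tp += 1
    fp = len(detections) - tp
    fn = len(annotations) - tp
    return metrics_from_counts(tp, fp, fn)


def _bbox_iou(a: tuple, b: tuple) -> float:
    rr = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    cc = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = rr * cc
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def round2(x: float, places: int = 2) -> float:
    """Round-half-even to ``places`` decimals (reporting convention).

    The value is first truncated to 10 decimals so binary representation
    noise (0.8250000000000001) cannot tip an exact half the wrong way.
    """
    q = Decimal(1).scaleb(-places)
    return float(Decimal(f"{float(x):.10f}").quantize(q, rounding=ROUND_HALF_EVEN))


def summarize(per_dish: Sequence[DetectionMetrics]) -> pd.DataFrame:
    """Across-dish mean ± sample standard deviation of each metric.

    Returns one row per metric with raw mean/sd plus values rounded
    half-even to 2 decimals. A single dish reports sd 0 with
    ``single_dish=True``.
    """
    if not per_dish:
        raise ValueError("need at least one dish")
    rows = []
    single = len(per_dish) == 1
    for name in ("sensitivity", "precision", "f1", "pct_successful"):
        vals = [getattr(m, name) for m in per_dish]
        vals = [v for v in vals if v is not None]
        if not vals:
            continue
        mean = float(np.mean(vals))
        sd = 0.0 if single else float(np.std(vals, ddof=1))
        rows.append({"metric": name, "mean": mean, "sd": sd,
                     "mean_2dp": round2(mean), "sd_2dp": round2(sd),
                     "n_dishes": len(vals), "single_dish": single})
    return pd.DataFrame(rows)
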