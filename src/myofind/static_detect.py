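"""Static (single-frame) cardiomyocyte finding from edge information.

Adult cardiomyocytes in brightfield have strong edges on the cell border and
on the internal sarcomere striations, so a Sobel edge map followed by
smoothing, contrast stretching and Otsu thresholding segments them from a
smooth background. Candidate regions are then screened by a fixed, ordered
list of rejection criteria: area, bounding-box aspect ratio, distance to the
frame border, fill ratio (to exclude regions containing more than one cell)
and centroid separation from already-accepted cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .frame import Frame

#: rejection tags, in the order the criteria are applied
REJECT_AREA = "area"
REJECT_ASPECT = "aspect_ratio"
REJECT_BORDER = "border"
REJECT_FILL = "fill_ratio"
REJECT_SEPARATION = "separation"


@dataclass
class DetectorConfig:
    """Tunable parameters of the static detector.

    Areas are µm² (converted with the frame's pixel size); ``min_aspect`` /
    ``max_aspect`` bound the bounding-box short/long side ratio; candidates
    whose bounding box comes within ``border_margin`` pixels of the frame
    border are rejected; regions with mask/bbox area ratio below
    ``fill_ratio_threshold`` are taken to contain more than one cell.
    """

    gaussian_radius: float = 5.0
    saturated_fraction: float = 0.004
    opening_radius: int = 3
    min_area: float = 1500.0
    max_area: float = 5500.0
    min_aspect: float = 0.1
    max_aspect: float = 0.7
    border_margin: int = 10
    fill_ratio_threshold: float = 0.55
    min_cell_separation: float = 40.0  # µm, centroid to centroid

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if not 0 < self.min_aspect < self.max_aspect <= 1:
            raise ValueError("need 0 < min_aspect < max_aspect <= 1")
        if not 0 <= self.saturated_fraction < 1:
            raise ValueError("saturated_fraction must be in [0, 1)")


@dataclass
class CellCandidate:
    """One connected region proposed as a cell.

    ``rejected_by`` names the first failed rejection criterion, or ``None``
    for accepted candidates. ``orientation`` is the long-axis angle in
    degrees, counter-clockwise from horizontal as displayed, in (-90, 90].
    """

    id: int
    mask: np.ndarray  # boolean, full-frame shape
    bbox: tuple[int, int, int, int]  # half-open
    centroid: tuple[float, float]
    area: float  # µm²
    aspect_ratio: float
    fill_ratio: float
    orientation: float
    rejected_by: Optional[str] = None
    motion_ratio: Optional[float] = None
    is_beating: Optional[bool] = None
    fsnr: Optional[float] = None

    @property
    def accepted(self) -> bool:
        return self.rejected_by is None

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "bbox": [int(b) for b in self.bbox],
            "centroid": [float(c) for c in self.centroid],
            "area_um2": float(self.area),
            "aspect_ratio": float(self.aspect_ratio),
            "fill_ratio": float(self.fill_ratio),
            "orientation_deg": float(self.orientation),
            "rejected_by": self.rejected_by,
            "motion_ratio": self.motion_ratio,
            "is_beating": self.is_beating,
            "fsnr": self.fsnr,
        }


def edge_map(frame: Frame, config: DetectorConfig | None = None) -> Frame:
    """Sobel gradient magnitude, Gaussian-smoothed and contrast-stretched.

    The Sobel responses in the two axes are combined as the Euclidean
    magnitude. The result is smoothed with a Gaussian of sigma
    ``config.gaussian_radius`` pixels, then linearly rescaled so that
    ``config.saturated_fraction`` of pixels saturate at each end, into the
    intensity range of the input frame. A constant frame yields an all-zero
    edge map.
    """
    config = config or DetectorConfig()
    px = frame.pixels
    edges = filters.sobel(px)  # Euclidean magnitude of h/v responses
    edges = ndimage.gaussian_filter(edges, config.gaussian_radius)
    lo_in, hi_in = float(px.min()), float(px.max())
    if hi_in <= lo_in or edges.max() == edges.min():
        return Frame(np.zeros_like(px), frame.pixel_size, frame.frame_index, frame.z)
    sf = config.saturated_fraction
    p_lo, p_hi = np.percentile(edges, [100.0 * sf, 100.0 * (1.0 - sf)])
    if p_hi <= p_lo:
        return Frame(np.zeros_like(px), frame.pixel_size, frame.frame_index, frame.z)
    stretched = (edges - p_lo) / (p_hi - p_lo)
    stretched = lo_in + np.clip(stretched, 0.0, 1.0) * (hi_in - lo_in)
    return Frame(stretched, frame.pixel_size, frame.frame_index, frame.z)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on a ``nbins``-bin histogram of ``values``.

    Maximises the between-class variance; ties resolve to the lowest
    threshold. Raises on a degenerate (single-valued) histogram.
    """
    return float(filters.threshold_otsu(np.asarray(values, dtype=np.float64),
                                        nbins=nbins))


def segment(edges: Frame, config: DetectorConfig | None = None) -> np.ndarray:
    """Binarise an edge map into a candidate mask.

    Otsu threshold on the edge-intensity histogram (mask = edges >= t),
    morphological opening with a disk of ``config.opening_radius`` to remove
    specks and split touching cells, then hole filling. A degenerate
    (single-valued) edge map yields an empty mask.
    """
    config = config or DetectorConfig()
    px = edges.pixels
    if px.max() == px.min():
        return np.zeros(px.shape, dtype=bool)
    t = otsu_threshold(px)
    mask = px >= t
    if config.opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(config.opening_radius))
    return ndimage.binary_fill_holes(mask)


def _orientation_deg(props) -> float:
    """Long-axis angle in degrees CCW from horizontal (displayed), (-90, 90]."""
    # skimage orientation: angle between the row axis and the major axis.
    deg = np.degrees(props.orientation) - 90.0
    if deg <= -90.0:
        deg += 180.0
    return float(deg)


def extract_candidates(mask: np.ndarray, frame: Frame,
                       config: DetectorConfig | None = None) -> list[CellCandidate]:
    """Label connected components and apply the rejection criteria in order.

    Criteria, applied in this fixed order with only the first failure
    recorded: (1) area within [min_area, max_area] µm²; (2) bounding-box
    aspect ratio within [min_aspect, max_aspect]; (3) bounding box at least
    ``border_margin`` pixels from every frame border; (4) fill ratio >=
    ``fill_ratio_threshold``; (5) centroid at least ``min_cell_separation``
    µm from every previously accepted candidate. All candidates are returned,
    accepted or not.
    """
    config = config or DetectorConfig()
    if mask.shape != frame.shape:
        raise ValueError("mask and frame shapes differ")
    labels = measure.label(mask, connectivity=2)
    ps = frame.pixel_size
    h, w = frame.shape
    candidates: list[CellCandidate] = []
    accepted_centroids: list[tuple[float, float]] = []
    for props in measure.regionprops(labels):
        min_r, min_c, max_r, max_c = props.bbox
        bbox_sides = sorted((max_r - min_r, max_c - min_c))
        aspect = bbox_sides[0] / bbox_sides[1]
        area_um2 = props.area * ps * ps
        fill = props.area / ((max_r - min_r) * (max_c - min_c))
        cand = CellCandidate(
            id=len(candidates),
            mask=labels == props.label,
            bbox=(min_r, min_c, max_r, max_c),
            centroid=(float(props.centroid[0]), float(props.centroid[1])),
            area=float(area_um2),
            aspect_ratio=float(aspect),
            fill_ratio=float(fill),
            orientation=_orientation_deg(props),
        )
        if not (config.min_area <= area_um2 <= config.max_area):
            cand.rejected_by = REJECT_AREA
        elif not (config.min_aspect <= aspect <= config.max_aspect):
            cand.rejected_by = REJECT_ASPECT
        elif (min_r < config.border_margin or min_c < config.border_margin
              or max_r > h - config.border_margin
              or max_c > w - config.border_margin):
            cand.rejected_by = REJECT_BORDER
        elif fill < config.fill_ratio_threshold:
            cand.rejected_by = REJECT_FILL
        else:
            sep_px = config.min_cell_separation / ps
            for (r0, c0) in accepted_centroids:
                if np.hypot(cand.centroid[0] - r0, cand.centroid[1] - c0) < sep_px:
                    cand.rejected_by = REJECT_SEPARATION
                    break
        if cand.accepted:
            accepted_centroids.append(cand.centroid)
        candidates.append(cand)
    return candidates


def detect_static(frame: Frame, config: DetectorConfig | None = None
                  ) -> list[CellCandidate]:
    """Full static pipeline: edge map -> segmentation -> screened candidates."""
    config = config or DetectorConfig()
    edges = edge_map(frame, config)
    mask = segment(edges, config)
    return extract_candidates(mask, frame, config)
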