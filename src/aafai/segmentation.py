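"""Ascending-aorta segmentation: classical detector and slice-extent selection.

The built-in detector is intentionally simple and fully deterministic: the
contrast-filled lumen is bright (≥ ~150 HU), roughly disc-shaped, and of
known calibre, so per-slice thresholding + connected components +
shape gating suffices on phantoms and clean contrast CT.  The
:class:`~aafai.io.SegmentationMask` interface also accepts masks from any
external segmentation (e.g. a trained CNN) via :func:`aafai.io.read_mask`,
so the detector is a pluggable default, not a commitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .io import CTVolume, SegmentationMask


@dataclass
class DetectorConfig:
    """Thresholds and gates of the classical lumen detector.

    ``lumen_hu_threshold``: minimum HU of contrast-enhanced blood.
    ``radius_range``: admissible equivalent radius (mm) of the vessel
    cross-section.  ``min_circularity``: isoperimetric quotient 4πA/P²
    gate against non-circular bright structures.  ``extent_mm``: length of
    aorta analyzed distal to the anchor slice (the study analyzes 5 cm).
    """

    lumen_hu_threshold: float = 150.0
    radius_range: tuple[float, float] = (10.0, 25.0)
    min_circularity: float = 0.8
    extent_mm: float = 50.0
    anchor_index: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not lo < hi:
            raise ValueError("radius_range must satisfy min < max")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be > 0")
        if not 0 < self.min_circularity <= 1:
            raise ValueError("min_circularity must be in (0, 1]")


@dataclass
class DetectionReport:
    detected: np.ndarray          # per-slice bool
    circularity: np.ndarray       # per-slice float, nan where undetected
    centers_mm: np.ndarray        # per-slice (row_mm, col_mm), nan where undetected
    success: bool
    fraction_detected: float

    def to_jsonable(self) -> dict:
        return {
            "success": bool(self.success),
            "fraction_detected": float(self.fraction_detected),
            "detected": [bool(v) for v in self.detected],
            "circularity": [None if not np.isfinite(c) else float(c) for c in self.circularity],
        }


@dataclass
class _Candidate:
    filled: np.ndarray
    center_mm: tuple[float, float]
    circularity: float
    radius_mm: float


def _slice_candidates(plane: np.ndarray, spacing: tuple[float, float], cfg: DetectorConfig) -> list[_Candidate]:
    row_mm, col_mm = spacing
    px_area = row_mm * col_mm
    px_len = math.sqrt(px_area)  # in-plane pixels assumed near-isotropic
    bw = plane >= cfg.lumen_hu_threshold
    if not bw.any():
        return []
    labels = measure.label(bw, connectivity=1)
    out = []
    for prop in measure.regionprops(labels):
        area_mm2 = prop.area * px_area
        radius = math.sqrt(area_mm2 / math.pi)
        if not cfg.radius_range[0] <= radius <= cfg.radius_range[1]:
            continue
        perim = measure.perimeter_crofton(labels == prop.label, directions=4) * px_len
        if perim <= 0:
            continue
        circ = min(4 * math.pi * area_mm2 / perim**2, 1.0)
        if circ < cfg.min_circularity:
            continue
        filled = ndi.binary_fill_holes(labels == prop.label)
        cy, cx = prop.centroid
        out.append(_Candidate(filled, (cy * row_mm, cx * col_mm), circ, radius))
    return out


def detect_aorta_classical(
    volume: CTVolume, config: DetectorConfig | None = None
) -> tuple[SegmentationMask, DetectionReport]:
    """Detect the ascending-aorta cross-section on every slice.

    Per slice: threshold at the lumen HU, label connected components, keep
    those whose equivalent radius falls in ``radius_range`` with
    circularity ≥ ``min_circularity``; among candidates pick the one
    nearest the previously detected centre (first detected slice: the most
    circular), ties broken by higher circularity then smaller row
    coordinate.  The mask holds the hole-filled component.  If no slice
    yields a candidate, ``success`` is False and downstream analysis must
    treat the case as unanalyzable.
    """
    cfg = config or DetectorConfig()
    rows, cols, nslices = volume.voxels.shape
    grid = np.zeros_like(volume.voxels, dtype=bool)
    detected = np.zeros(nslices, dtype=bool)
    circularity = np.full(nslices, np.nan)
    centers = np.full((nslices, 2), np.nan)

    prev_center: tuple[float, float] | None = None
    for k in range(nslices):
        cands = _slice_candidates(volume.voxels[:, :, k], volume.spacing[:2], cfg)
        if not cands:
            continue
        if prev_center is None:
            # deterministic: best circularity, then smaller row coordinate
            best = min(cands, key=lambda c: (-c.circularity, c.center_mm[0]))
        else:
            py, px = prev_center
            best = min(
                cands,
                key=lambda c: (
                    math.hypot(c.center_mm[0] - py, c.center_mm[1] - px),
                    -c.circularity,
                    c.center_mm[0],
                ),
            )
        grid[:, :, k] = best.filled
        detected[k] = True
        circularity[k] = best.circularity
        centers[k] = best.center_mm
        prev_center = best.center_mm

    report = DetectionReport(
        detected=detected,
        circularity=circularity,
        centers_mm=centers,
        success=bool(detected.any()),
        fraction_detected=float(detected.mean()) if nslices else 0.0,
    )
    mask = SegmentationMask(
        grid=grid,
        provenance="classical_detector",
        flags=frozenset() if detected.all() else frozenset({"undetected_slices"}),
    )
    return mask, report


@dataclass(frozen=True)
class ExtentSelection:
    """Contiguous slice range analyzed (``range(start, stop)``)."""

    start: int
    stop: int
    truncated: bool

    @property
    def indices(self) -> range:
        return range(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


def select_extent(
    mask: SegmentationMask, volume: CTVolume, config: DetectorConfig | None = None
) -> ExtentSelection:
    """Select the analyzed slice run covering ``extent_mm`` of vessel.

    The run holds ``ceil(extent_mm / slice_spacing)`` slices starting at
    the anchor (first slice with a detected vessel, in ascending slice
    order, unless ``config.anchor_index`` overrides it), truncated at the
    volume end with a flag.  With 5 mm slices and the default 50 mm extent
    this is 10 slices.
    """
    cfg = config or DetectorConfig()
    detected = mask.detected_slices
    if not detected.any():
        raise ValueError("no detected slices; cannot select an extent")
    anchor = int(np.argmax(detected)) if cfg.anchor_index is None else int(cfg.anchor_index)
    n = math.ceil(cfg.extent_mm / volume.spacing[2])
    stop = anchor + n
    truncated = stop > volume.slice_count
    return ExtentSelection(start=anchor, stop=min(stop, volume.slice_count), truncated=truncated)
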