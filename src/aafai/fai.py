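"""Perivascular ring, fat window, and the fat attenuation index (AA-FAI).

The computational core: given a CT volume and an ascending-aorta mask,
construct the perivascular ring (all non-vessel pixels whose centre lies
within a fixed physical distance — default 10 mm — of the nearest
vessel-pixel centre, measured in the axial plane with true pixel spacing),
keep the ring pixels whose attenuation falls in the fat window
[−190, 0] HU (bounds inclusive), and report

* ``aa_fai`` — the pooled mean HU over all fat pixels of all analyzed
  slices (a single sum divided by the total pixel count, not a mean of
  per-slice means), and
* ``ct_pvat_area`` — total fat-pixel area (mm²) divided by the number of
  analyzed slices, i.e. mm² per slice.

The ring is built per slice in 2-D: the area is reported per slice and
slice thickness (typically 5 mm) is half the ring width, so a 3-D
dilation would smear the ring across slices without improving the
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .io import CTVolume, SegmentationMask


@dataclass
class RingParams:
    """Perivascular-ring geometry and the fat attenuation window.

    ``ring_distance``: radial reach of the ring from the vessel boundary,
    mm (default 10).  ``fat_hu_low``/``fat_hu_high``: closed HU interval
    defining fat (default −190..0; the window is deliberately wide toward
    0 HU to capture inflamed, water-shifted adipose tissue).
    """

    ring_distance: float = 10.0
    fat_hu_low: float = -190.0
    fat_hu_high: float = 0.0

    def __post_init__(self) -> None:
        if self.ring_distance <= 0:
            raise ValueError("ring_distance must be > 0")
        if not self.fat_hu_low < self.fat_hu_high:
            raise ValueError("fat window must satisfy low < high")


@dataclass
class FAIResult:
    """Per-case AA-FAI summary.

    ``aa_fai`` is ``None`` when no fat pixel was found (``no_fat`` flag);
    such cases are excluded from cohort statistics rather than imputed.
    """

    aa_fai: float | None
    ct_pvat_area: float
    n_fat_pixels: int
    n_ring_pixels: int
    n_slices: int
    flags: frozenset[str] = frozenset()


def _slice_range(volume: CTVolume, slice_range) -> range:
    if slice_range is None:
        return range(volume.slice_count)
    if hasattr(slice_range, "indices") and not isinstance(slice_range, range):
        return slice_range.indices  # ExtentSelection
    return range(int(slice_range[0]), int(slice_range[-1]) + 1) if not isinstance(slice_range, range) else slice_range


def perivascular_ring(
    mask: SegmentationMask,
    volume: CTVolume,
    params: RingParams | None = None,
    slice_range=None,
) -> SegmentationMask:
    """Build the perivascular ring around the vessel, slice by slice.

    A pixel belongs to the ring iff it is outside the vessel mask and the
    Euclidean distance (mm, using row/column spacing) from its centre to
    the nearest vessel-pixel centre is ≤ ``ring_distance``.  Slices in the
    range with an empty vessel mask are skipped (``empty_mask_slice``
    flag).  If the ring reaches the image border the ``border_clipped``
    flag is set — the ring is then incomplete but still measured.
    """
    params = params or RingParams()
    rng = _slice_range(volume, slice_range)
    row_mm, col_mm = volume.spacing[:2]
    ring = np.zeros_like(mask.grid)
    flags: set[str] = set()

    for k in rng:
        m = mask.grid[:, :, k]
        if not m.any():
            flags.add("empty_mask_slice")
            continue
        dist = ndi.distance_transform_edt(~m, sampling=(row_mm, col_mm))
        r = (dist > 0) & (dist <= params.ring_distance)
        # the ring is clipped when the full annulus would cross the border:
        # any border pixel within ring reach of the vessel (or vessel on it)
        border_dist = np.concatenate([dist[0, :], dist[-1, :], dist[:, 0], dist[:, -1]])
        if (border_dist <= params.ring_distance).any():
            flags.add("border_clipped")
        ring[:, :, k] = r

    return SegmentationMask(grid=ring, target=mask.target, provenance=mask.provenance, flags=frozenset(flags))


def fat_mask(
    ring: SegmentationMask, volume: CTVolume, params: RingParams | None = None
) -> SegmentationMask:
    """Restrict the ring to pixels in the fat window (bounds inclusive)."""
    params = params or RingParams()
    hu = volume.voxels
    grid = ring.grid & (hu >= params.fat_hu_low) & (hu <= params.fat_hu_high)
    return SegmentationMask(grid=grid, target=ring.target, provenance=ring.provenance, flags=ring.flags)


def compute_fai(
    fat: SegmentationMask,
    volume: CTVolume,
    slice_range=None,
    ring: SegmentationMask | None = None,
    extra_flags: frozenset[str] | set[str] = frozenset(),
) -> FAIResult:
    """Pool fat pixels over the analyzed slices into an AA-FAI result.

    ``aa_fai`` sums the HU of every fat pixel across all analyzed slices
    and divides by their count; ``ct_pvat_area`` is
    ``n_fat_pixels × pixel_area / n_slices`` exactly.
    """
    rng = _slice_range(volume, slice_range)
    idx = np.asarray(list(rng), dtype=int)
    n_slices = len(idx)
    if n_slices == 0:
        raise ValueError("empty slice range")

    fat_sub = fat.grid[:, :, idx]
    hu_sub = volume.voxels[:, :, idx]
    n_fat = int(fat_sub.sum())
    n_ring = int(ring.grid[:, :, idx].sum()) if ring is not None else n_fat

    flags = set(extra_flags) | set(fat.flags)
    if n_fat == 0:
        flags.add("no_fat")
        aa_fai = None
    else:
        aa_fai = float(hu_sub[fat_sub].sum() / n_fat)

    return FAIResult(
        aa_fai=aa_fai,
        ct_pvat_area=n_fat * volume.pixel_area_mm2 / n_slices,
        n_fat_pixels=n_fat,
        n_ring_pixels=n_ring,
        n_slices=n_slices,
        flags=frozenset(flags),
    )


def analyze(
    volume: CTVolume,
    mask: SegmentationMask,
    params: RingParams | None = None,
    slice_range=None,
    extra_flags: frozenset[str] | set[str] = frozenset(),
) -> FAIResult:
    """Convenience wrapper: ring → fat window → pooled AA-FAI."""
    params = params or RingParams()
    ring = perivascular_ring(mask, volume, params, slice_range)
    fat = fat_mask(ring, volume, params)
    return compute_fai(fat, volume, slice_range, ring=ring, extra_flags=extra_flags)
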