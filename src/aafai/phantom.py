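"""Synthetic CT phantoms and simulated patient cohorts.

Two generators make the whole pipeline testable without patient data:

* :func:`make_phantom` builds a voxel phantom of a contrast-filled
  ascending aorta — a bright lumen disc, a thin wall annulus, and a
  perivascular region in which a seeded subset of pixels is adipose tissue
  (HU drawn in the fat window) and the rest soft tissue — together with an
  exact ground-truth record (true aorta mask, true fat-pixel set, the
  noiseless fat mean, and the true fat area per slice).

* :func:`simulate_fai_cohort` draws per-patient AA-FAI values as Gaussian
  groups.  The default :data:`STUDY_COHORT` carries the published group
  summaries for the clinical study this package models: 159 patients
  without hereditary connective tissue disorders (AA-FAI −62.02 ± 8.54 HU),
  36 with Marfan syndrome (−52.90 ± 12.69 HU) and 9 with Loeys–Dietz
  syndrome (−51.70 ± 7.99 HU).  Only mean ± SD summaries are published, so
  normality is the minimal distributional assumption.

A single master seed expands deterministically into independent per-slice
and per-patient streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps

from .io import CTVolume, SegmentationMask, HU_MIN, HU_MAX

FAT_HU_LOW = -190.0
FAT_HU_HIGH = 0.0


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a vessel phantom.

    All lengths are mm, all attenuations HU.  ``fat_fraction_of_ring`` is
    the fraction of perivascular-ring pixels assigned to fat; the rest are
    soft tissue.  Defaults emulate the study's imaging conditions: ~0.7 mm
    pixels, 5 mm slices, contrast-enhanced lumen, fat around the non-HCTD
    group mean, and a fat load giving a ct-PVAT area near the published
    ~414 mm²/slice.
    """

    lumen_radius: float = 15.0
    lumen_hu: float = 300.0
    wall_thickness: float = 2.0
    wall_hu: float = 40.0
    fat_hu_mean: float = -62.0
    fat_hu_sd: float = 8.5
    fat_fraction_of_ring: float = 0.4
    soft_tissue_hu: float = 50.0
    background_hu: float = -1000.0
    noise_sd: float = 5.0
    spacing: tuple[float, float, float] = (0.7, 0.7, 5.0)
    grid_shape: tuple[int, int, int] = (128, 128, 10)
    center_path: Sequence[tuple[float, float]] | None = None
    ring_distance: float = 10.0
    seed: int = 0
    allow_border_clip: bool = False

    def __post_init__(self) -> None:
        if not (FAT_HU_LOW < self.fat_hu_mean < FAT_HU_HIGH):
            raise ValueError(
                f"fat_hu_mean must lie in ({FAT_HU_LOW}, {FAT_HU_HIGH}) HU, got {self.fat_hu_mean}"
            )
        if self.lumen_hu <= 150:
            raise ValueError("lumen_hu must exceed 150 HU (contrast-enhanced semantics)")
        if not 0.0 <= self.fat_fraction_of_ring <= 1.0:
            raise ValueError("fat_fraction_of_ring must be in [0, 1]")
        if self.fat_hu_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.wall_thickness < 0 or self.lumen_radius <= 0 or self.ring_distance <= 0:
            raise ValueError("geometry parameters must be positive")


@dataclass
class PhantomGroundTruth:
    """Exact truth recorded at generation time.

    ``fat_mean_hu`` is the mean of the *noiseless* fat HU draws pooled over
    all slices (``None`` when no fat pixel exists); ``fat_area_mm2_per_slice``
    is total fat-pixel area divided by the slice count.
    """

    aorta: SegmentationMask
    fat: SegmentationMask
    fat_mean_hu: float | None
    fat_area_mm2_per_slice: float
    n_fat_pixels: int
    noiseless_voxels: np.ndarray

    def to_jsonable(self) -> dict:
        return {
            "fat_mean_hu": self.fat_mean_hu,
            "fat_area_mm2_per_slice": self.fat_area_mm2_per_slice,
            "n_fat_pixels": self.n_fat_pixels,
        }


def _truncated_fat_draws(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Fat HU values ~ Normal(mean, sd) truncated to the open fat window.

    Truncation keeps every ground-truth fat pixel inside (−190, 0) HU so
    the HU window can never exclude a true fat pixel.
    """
    if size == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(size, mean)
    a = (FAT_HU_LOW - mean) / sd
    b = (FAT_HU_HIGH - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, SegmentationMask, PhantomGroundTruth]:
    """Build a concentric vessel phantom with exact perivascular-fat truth.

    Per slice the structure is: contrast-filled lumen disc → wall annulus →
    perivascular region.  The perivascular ring is the set of pixels whose
    centre lies within ``ring_distance`` of the nearest lumen-pixel centre
    (outside the vessel); a seeded random subset of ``fat_fraction_of_ring``
    of those pixels is fat, the rest soft tissue; everything further out is
    background.  Additive Gaussian noise of ``noise_sd`` HU is applied
    everywhere afterwards.  The returned ground-truth mask marks the lumen
    disc — the structure a contrast threshold can actually delineate.
    """
    rows, cols, nslices = spec.grid_shape
    row_mm, col_mm, slice_mm = spec.spacing

    if spec.center_path is None:
        centers = [((rows - 1) / 2 * row_mm, (cols - 1) / 2 * col_mm)] * nslices
    else:
        centers = [tuple(map(float, c)) for c in spec.center_path]
        if len(centers) != nslices:
            raise ValueError("center_path must give one (row_mm, col_mm) centre per slice")

    reach = spec.lumen_radius + spec.wall_thickness + spec.ring_distance
    if not spec.allow_border_clip:
        for cy, cx in centers:
            if (
                cy - reach < 0
                or cx - reach < 0
                or cy + reach > (rows - 1) * row_mm
                or cx + reach > (cols - 1) * col_mm
            ):
                raise ValueError(
                    "vessel plus perivascular ring does not fit in the grid; "
                    "set allow_border_clip=True to test clipping"
                )

    ss = np.random.SeedSequence(spec.seed)
    sel_rng, fat_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    ys = np.arange(rows) * row_mm
    xs = np.arange(cols) * col_mm
    yy, xx = np.meshgrid(ys, xs, indexing="ij")

    voxels = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    lumen_mask = np.zeros(spec.grid_shape, dtype=bool)
    fat_mask = np.zeros(spec.grid_shape, dtype=bool)
    fat_values: list[np.ndarray] = []

    for k, (cy, cx) in enumerate(centers):
        d = np.hypot(yy - cy, xx - cx)
        lumen = d <= spec.lumen_radius
        wall = (d > spec.lumen_radius) & (d <= spec.lumen_radius + spec.wall_thickness)

        # ring by the same metric the analysis uses: Euclidean distance (mm)
        # to the nearest lumen-pixel centre, in plane
        dist = ndi.distance_transform_edt(~lumen, sampling=(row_mm, col_mm))
        ring = (dist > 0) & (dist <= spec.ring_distance) & ~wall

        plane = np.full((rows, cols), spec.background_hu)
        plane[ring] = spec.soft_tissue_hu
        plane[wall] = spec.wall_hu
        plane[lumen] = spec.lumen_hu

        ring_idx = np.flatnonzero(ring.ravel())
        n_fat = int(round(spec.fat_fraction_of_ring * len(ring_idx)))
        chosen = sel_rng.choice(ring_idx, size=n_fat, replace=False) if n_fat else np.empty(0, int)
        vals = _truncated_fat_draws(fat_rng, spec.fat_hu_mean, spec.fat_hu_sd, n_fat)
        plane.ravel()[chosen] = vals

        fat_plane = np.zeros((rows, cols), dtype=bool)
        fat_plane.ravel()[chosen] = True
        voxels[:, :, k] = plane
        lumen_mask[:, :, k] = lumen
        fat_mask[:, :, k] = fat_plane
        fat_values.append(vals)

    noiseless = voxels.copy()
    if spec.noise_sd > 0:
        voxels = voxels + noise_rng.normal(0.0, spec.noise_sd, size=voxels.shape)
    voxels = np.clip(voxels, HU_MIN, HU_MAX)

    volume = CTVolume(voxels=voxels, spacing=spec.spacing, source_id=f"phantom(seed={spec.seed})")
    aorta = SegmentationMask(grid=lumen_mask, provenance="ground_truth")
    fat = SegmentationMask(grid=fat_mask, provenance="ground_truth")

    all_vals = np.concatenate(fat_values) if fat_values else np.empty(0)
    n_fat_total = int(fat_mask.sum())
    truth = PhantomGroundTruth(
        aorta=aorta,
        fat=fat,
        fat_mean_hu=float(all_vals.mean()) if n_fat_total else None,
        fat_area_mm2_per_slice=n_fat_total * (row_mm * col_mm) / nslices,
        n_fat_pixels=n_fat_total,
        noiseless_voxels=noiseless,
    )
    return volume, aorta, truth


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: label, AA-FAI mean (HU), SD (HU), sample size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("group sd must be > 0")
        if self.n < 1:
            raise ValueError("group n must be ≥ 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0


#: published per-group AA-FAI summaries of the clinical cohort (HU)
STUDY_COHORT = CohortSpec(
    groups=(
        GroupSpec("non_HCTD", -62.02, 8.54, 159),
        GroupSpec("MFS", -52.90, 12.69, 36),
        GroupSpec("LDS", -51.70, 7.99, 9),
    )
)


def simulate_fai_cohort(spec: CohortSpec, seed: int | None = None):
    """Draw a simulated cohort of per-patient AA-FAI values.

    Per group, ``n`` independent Normal(mean, sd) draws; returns a pandas
    DataFrame with columns ``id``, ``group``, ``aa_fai``.  Reproducible
    under the spec's (or the overriding) seed.
    """
    import pandas as pd

    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    frames = []
    for child, g in zip(ss.spawn(len(spec.groups)), spec.groups):
        rng = np.random.default_rng(child)
        vals = rng.normal(g.mean, g.sd, size=g.n)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{g.label}_{i:04d}" for i in range(g.n)],
                    "group": g.label,
                    "aa_fai": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
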