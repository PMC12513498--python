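"""Reading and writing CT volumes, aorta masks, and result tables.

Volumes are held as 3-D arrays of Hounsfield units (HU) with axis order
(row, column, slice) and physical spacing in millimetres.  DICOM series are
rescaled per slice (stored value × slope + intercept) and sorted by
physical slice position; NIfTI volumes are assumed to already carry HU
after the header scaling that nibabel applies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HU_MIN = -1100.0
HU_MAX = 3200.0

#: default CT rescale when DICOM rescale tags are absent
DEFAULT_SLOPE = 1.0
DEFAULT_INTERCEPT = -1024.0


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with physical geometry.

    Attributes
    ----------
    voxels:
        float array, shape ``(rows, cols, slices)``, values in HU.
    spacing:
        ``(row_mm, col_mm, slice_mm)`` — physical size of one voxel step
        along each axis.  All components must be positive.
    origin:
        physical coordinates (mm) of the centre of voxel ``(0, 0, 0)``.
    source_id:
        opaque identifier of where the volume came from (series UID,
        filename, phantom tag).
    flags:
        provenance warnings, e.g. ``default_rescale`` when DICOM rescale
        tags were missing and the CT convention (slope 1, intercept −1024)
        was applied.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_id: str = ""
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (rows, cols, slices)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        lo, hi = self.voxels.min(), self.voxels.max()
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}] after rescale: "
                f"range [{lo:.1f}, {hi:.1f}]"
            )

    @property
    def slice_count(self) -> int:
        return self.voxels.shape[2]

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane area of one pixel (mm²)."""
        return self.spacing[0] * self.spacing[1]


@dataclass
class SegmentationMask:
    """Boolean grid aligned to a :class:`CTVolume`, marking the ascending aorta.

    ``provenance`` records how the mask was produced: the built-in classical
    detector, an external file (e.g. CNN output), or phantom ground truth.
    """

    grid: np.ndarray
    target: str = "ascending_aorta"
    provenance: str = "external_file"
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D (rows, cols, slices)")

    @property
    def detected_slices(self) -> np.ndarray:
        """Boolean per-slice flag: slice contains at least one true voxel."""
        return self.grid.any(axis=(0, 1))


# ---------------------------------------------------------------------------
# CT series reading


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # skip non-DICOM clutter (DICOMDIR, reports)
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image files found in {path}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise ValueError(f"mixed DICOM series in {path}: {sorted(map(str, uids))}")

    def zpos(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        sl = getattr(ds, "SliceLocation", None)
        if sl is not None:
            return float(sl)
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=zpos)

    first = slices[0]
    ps = getattr(first, "PixelSpacing", None)
    if ps is None:
        raise ValueError("DICOM series is missing PixelSpacing")
    row_mm, col_mm = float(ps[0]), float(ps[1])

    positions = [zpos(ds) for ds in slices]
    if len(slices) > 1:
        diffs = np.diff(positions)
        slice_mm = float(np.median(np.abs(diffs)))
        if slice_mm <= 0:
            raise ValueError("could not determine slice spacing from positions")
    else:
        st = getattr(first, "SliceThickness", None)
        if st is None:
            raise ValueError("single-slice series without SliceThickness")
        slice_mm = float(st)

    flags: set[str] = set()
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            slope, intercept = DEFAULT_SLOPE, DEFAULT_INTERCEPT
            flags.add("default_rescale")
        planes.append(arr * float(slope) + float(intercept))

    voxels = np.stack(planes, axis=-1)
    ipp = getattr(first, "ImagePositionPatient", [0.0, 0.0, positions[0]])
    origin = (float(ipp[1]), float(ipp[0]), float(positions[0]))
    return CTVolume(
        voxels=voxels,
        spacing=(row_mm, col_mm, slice_mm),
        origin=origin,
        source_id=str(next(iter(uids))),
        flags=frozenset(flags),
    )


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(
        voxels=data,
        spacing=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        origin=origin,
        source_id=os.fspath(path),
    )


def read_ct_series(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    DICOM stored values are converted to HU via the per-slice linear
    rescale (value × slope + intercept) and slices are sorted by ascending
    physical position regardless of on-disk order.  Missing rescale tags
    fall back to the CT convention (slope 1, intercept −1024) and set the
    ``default_rescale`` flag; missing pixel spacing is an error, as is a
    directory containing more than one series.
    """
    p = Path(path)
    if p.is_dir():
        return _read_dicom_dir(p)
    if p.name.endswith((".nii", ".nii.gz")):
        return _read_nifti(p)
    raise ValueError(f"unrecognised CT input: {p} (expected DICOM dir or NIfTI)")


def write_volume_nifti(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI-1 with spacing encoded in the affine."""
    import nibabel as nib

    affine = np.diag([volume.spacing[0], volume.spacing[1], volume.spacing[2], 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def write_mask_nifti(mask: SegmentationMask, volume: CTVolume, path: str | os.PathLike) -> None:
    import nibabel as nib

    affine = np.diag([volume.spacing[0], volume.spacing[1], volume.spacing[2], 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Mask reading


def _points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Which points fall inside the closed polygon (centre-inside rule).

    Vertices are (x, y) pairs in mm; the polygon is treated as closed
    (last vertex joins the first).  A pixel belongs to the mask iff its
    centre is inside.
    """
    from matplotlib.path import Path as MplPath

    verts = np.asarray(vertices, dtype=float)
    if not np.array_equal(verts[0], verts[-1]):
        verts = np.vstack([verts, verts[:1]])
    return MplPath(verts).contains_points(points)


def _rasterize_polygons(payload: dict, reference: CTVolume) -> np.ndarray:
    rows, cols, nslices = reference.voxels.shape
    row_mm, col_mm, _ = reference.spacing
    oy, ox = reference.origin[0], reference.origin[1]
    # pixel centres in mm: x along columns, y along rows
    xs = ox + np.arange(cols) * col_mm
    ys = oy + np.arange(rows) * row_mm
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    grid = np.zeros((rows, cols, nslices), dtype=bool)
    for entry in payload["slices"]:
        k = int(entry["index"])
        if not 0 <= k < nslices:
            raise ValueError(f"polygon slice index {k} outside volume")
        plane = np.zeros(rows * cols, dtype=bool)
        for poly in entry["polygons"]:
            verts = np.asarray(poly, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise ValueError("polygon must be a list of ≥3 (x, y) mm vertices")
            plane |= _points_in_polygon(pts, verts)
        grid[:, :, k] = plane.reshape(rows, cols)
    return grid


def read_mask(path: str | os.PathLike, reference: CTVolume) -> SegmentationMask:
    """Read an aorta mask aligned to ``reference``.

    Accepts a NIfTI label volume (nonzero = aorta) or a JSON file of
    per-slice closed polygons (``{"slices": [{"index": k, "polygons":
    [[[x_mm, y_mm], ...], ...]}]}``) rasterized with the pixel
    centre-inside rule.  Shape or spacing mismatch beyond a relative
    tolerance of 1e-3 is an error.  Slices without any foreground voxel
    are reported via the ``undetected_slices`` flag.
    """
    p = Path(path)
    if p.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(p))
        data = np.asarray(img.get_fdata())
        if data.shape != reference.voxels.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match volume {reference.voxels.shape}"
            )
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        ref_sp = np.asarray(reference.spacing, dtype=float)
        if np.any(np.abs(zooms - ref_sp) > 1e-3 * ref_sp):
            raise ValueError(f"mask spacing {tuple(zooms)} does not match volume {reference.spacing}")
        grid = data != 0
    elif p.suffix == ".json":
        with open(p) as fh:
            payload = json.load(fh)
        grid = _rasterize_polygons(payload, reference)
    else:
        raise ValueError(f"unrecognised mask format: {p}")

    flags: set[str] = set()
    if not grid.any(axis=(0, 1)).all():
        flags.add("undetected_slices")
    return SegmentationMask(grid=grid, provenance="external_file", flags=frozenset(flags))


# ---------------------------------------------------------------------------
# Report writing

REPORT_COLUMNS = [
    "id",
    "group",
    "aa_fai_hu",
    "ct_pvat_area_mm2_per_slice",
    "n_fat_pixels",
    "n_ring_pixels",
    "n_slices",
    "flags",
]


def write_report(results: Iterable[dict], path: str | os.PathLike) -> pd.DataFrame:
    """Write per-patient AA-FAI results to CSV with a fixed column order.

    Each element of ``results`` is a mapping with (a subset of) the report
    columns; missing numeric fields are left empty.  Floats are written at
    full repr precision so re-reading the CSV reproduces them exactly.
    Returns the DataFrame that was written.
    """
    rows = []
    for r in results:
        row = {c: r.get(c, "") for c in REPORT_COLUMNS}
        if isinstance(row["flags"], (set, frozenset, list, tuple)):
            row["flags"] = ";".join(sorted(map(str, row["flags"])))
        rows.append(row)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    # repr of a Python float round-trips the double exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return df
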