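"""SUV volume data model, NIfTI I/O, and VOI-construction strategies.

The substrate of every quantity in this package is a 3D grid of standardized
uptake values (SUV, g/mL) with known voxel spacing. Volumes of interest (VOIs)
delimit where threshold segmentation is allowed; three construction strategies
are provided, mirroring how readers contour lymphoma lesions in practice:

* :func:`extrude_single_roi` — a single planar ROI drawn on one axial slice and
  extruded as a prism between two limiting slices. Fast, but the prism can
  sweep up physiological hot structures lying inside the 2D footprint at other
  depths. This failure mode is intentional and must not be "fixed" here: the
  comparison between strategies is the point.
* :func:`stack_slicewise_rois` — one ROI per slice, edited to track the tumor
  and avoid physiological uptake; the VOI is the union of the per-slice
  footprints.
* :func:`union_lesions` — individual VOIs per lesion, combined by disjoint
  union (the "multiple ROI" approach).

Coordinate convention: 0-based voxel indices; the center of voxel (i, j, k)
sits at ``origin_mm + (i, j, k) * spacing_mm`` in world millimetres. Polygon
membership is decided by a strict voxel-center-in-interior test. Axis 2 is
axial (slice) by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import shapely

__all__ = [
    "SuvVolume",
    "Voi",
    "PlanarRoi",
    "LesionSet",
    "read_suv_volume",
    "write_suv_volume",
    "read_mask",
    "write_mask",
    "read_planar_roi",
    "write_planar_roi",
    "extrude_single_roi",
    "stack_slicewise_rois",
    "union_lesions",
]


@dataclass(frozen=True)
class SuvVolume:
    """A 3D SUV image with voxel spacing and world origin (RAS mm)."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default=None)  # type: ignore[assignment]
    axial_axis: int = 2

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got shape {values.shape}")
        if np.any(values < 0):
            raise ValueError("SUV values must be nonnegative")
        spacing = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        if np.any(spacing <= 0):
            raise ValueError(f"spacing_mm must be positive, got {spacing}")
        origin = self.origin_mm
        origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=np.float64).reshape(3)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)
        if self.axial_axis not in (0, 1, 2):
            raise ValueError("axial_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (spacing product / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.spacing_mm[axis]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass(frozen=True)
class Voi:
    """A boolean mask aligned voxel-for-voxel to a :class:`SuvVolume`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"VOI mask must be 3D, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_cm3(self, vol: SuvVolume) -> float:
        self.check_aligned(vol)
        return self.voxel_count * vol.voxel_volume_cm3

    def check_aligned(self, vol: SuvVolume) -> None:
        if self.shape != vol.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {vol.shape}"
            )


@dataclass(frozen=True)
class PlanarRoi:
    """A 2D region of interest on one axial slice.

    Either a polygon (ordered vertices in world mm, in the in-plane axes'
    coordinates) or an explicit 2D boolean mask. A polygon must be simple
    (non-self-intersecting) with at least three vertices.
    """

    slice_index: int
    polygon_mm: np.ndarray | None = None
    mask2d: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.polygon_mm is None) == (self.mask2d is None):
            raise ValueError("provide exactly one of polygon_mm or mask2d")
        if self.polygon_mm is not None:
            poly = np.asarray(self.polygon_mm, dtype=np.float64)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError("polygon_mm must be an (n>=3, 2) vertex array")
            if not shapely.Polygon(poly).is_valid:
                raise ValueError("polygon must be simple (non-self-intersecting)")
            object.__setattr__(self, "polygon_mm", poly)
        if self.mask2d is not None:
            m = np.asarray(self.mask2d)
            if m.ndim != 2:
                raise ValueError("mask2d must be 2D")
            object.__setattr__(self, "mask2d", m.astype(bool))

    def footprint(self, vol: SuvVolume) -> np.ndarray:
        """2D boolean footprint on the volume's in-plane grid.

        Polygon membership uses voxel centers with a strict-interior test:
        a voxel belongs to the ROI iff its center lies strictly inside the
        polygon (boundary points excluded).
        """
        ax = vol.axial_axis
        in_plane = [a for a in range(3) if a != ax]
        shape2d = tuple(vol.shape[a] for a in in_plane)
        if self.mask2d is not None:
            if self.mask2d.shape != shape2d:
                raise ValueError(
                    f"mask2d shape {self.mask2d.shape} does not match in-plane "
                    f"shape {shape2d}"
                )
            return self.mask2d.copy()
        xs = vol.voxel_centers_mm(in_plane[0])
        ys = vol.voxel_centers_mm(in_plane[1])
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        poly = shapely.Polygon(self.polygon_mm)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        return inside.reshape(shape2d)


@dataclass(frozen=True)
class LesionSet:
    """Per-lesion VOIs; masks must be pairwise disjoint."""

    vois: tuple[Voi, ...]

    def __init__(self, vois: Sequence[Voi]):
        object.__setattr__(self, "vois", tuple(vois))
        if not self.vois:
            raise ValueError("LesionSet must contain at least one lesion VOI")
        shape = self.vois[0].shape
        acc = np.zeros(shape, dtype=np.int32)
        for v in self.vois:
            if v.shape != shape:
                raise ValueError("lesion VOIs must share one grid shape")
            acc += v.mask
        if np.any(acc > 1):
            raise ValueError("lesion VOIs overlap; masks must be pairwise disjoint")

    def __len__(self) -> int:
        return len(self.vois)

    def __iter__(self):
        return iter(self.vois)


# ---------------------------------------------------------------------------
# NIfTI and JSON I/O


def write_suv_volume(vol: SuvVolume, path: str | Path) -> None:
    """Write as NIfTI-1 (float32, RAS, spacing in the affine)."""
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.affine())
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def read_suv_volume(path: str | Path) -> SuvVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    # negatives can appear from float round-trip of a clipped image; SUV >= 0
    data = np.clip(data, 0.0, None)
    aff = img.affine
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    origin = aff[:3, 3].astype(np.float64)
    return SuvVolume(values=data, spacing_mm=spacing, origin_mm=origin)


def write_mask(voi: Voi, vol: SuvVolume, path: str | Path) -> None:
    """Write a VOI as a 0/1 uint8 NIfTI aligned to ``vol``."""
    voi.check_aligned(vol)
    img = nib.Nifti1Image(voi.mask.astype(np.uint8), vol.affine())
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def read_mask(path: str | Path, vol: SuvVolume) -> Voi:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.shape != vol.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match volume shape {vol.shape}"
        )
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    if not np.allclose(spacing, vol.spacing_mm, rtol=1e-4):
        raise ValueError(
            f"mask spacing {tuple(spacing)} does not match volume spacing "
            f"{tuple(vol.spacing_mm)}"
        )
    return Voi(mask=data > 0)


def write_planar_roi(roi: PlanarRoi, path: str | Path) -> None:
    if roi.polygon_mm is None:
        raise ValueError("only polygon ROIs have a JSON representation")
    payload = {
        "slice_index": int(roi.slice_index),
        "vertices_mm": np.asarray(roi.polygon_mm).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_planar_roi(path: str | Path) -> PlanarRoi:
    payload = json.loads(Path(path).read_text())
    return PlanarRoi(
        slice_index=int(payload["slice_index"]),
        polygon_mm=np.asarray(payload["vertices_mm"], dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# VOI-construction strategies


def _slice_indexer(ax: int, k: int) -> tuple:
    idx: list = [slice(None)] * 3
    idx[ax] = k
    return tuple(idx)


def extrude_single_roi(roi: PlanarRoi, z_min: int, z_max: int, vol: SuvVolume) -> Voi:
    """Extrude one planar ROI into a prism VOI over slices [z_min, z_max].

    The 2D footprint is copied identically to every slice in the closed
    range; everything outside is empty. The prism deliberately can include
    non-tumoral hot structures that lie inside the footprint at other depths.
    """
    ax = vol.axial_axis
    n_slices = vol.shape[ax]
    if not (0 <= z_min <= roi.slice_index <= z_max < n_slices):
        raise ValueError(
            f"need 0 <= z_min <= roi.slice_index <= z_max < {n_slices}; got "
            f"z_min={z_min}, slice_index={roi.slice_index}, z_max={z_max}"
        )
    fp = roi.footprint(vol)
    if not fp.any():
        raise ValueError("ROI footprint contains no voxel centers")
    mask = np.zeros(vol.shape, dtype=bool)
    for k in range(z_min, z_max + 1):
        mask[_slice_indexer(ax, k)] = fp
    return Voi(mask=mask)


def stack_slicewise_rois(rois: Sequence[PlanarRoi], vol: SuvVolume) -> Voi:
    """Union of per-slice ROI footprints (slice-by-slice edited contour)."""
    seen: set[int] = set()
    mask = np.zeros(vol.shape, dtype=bool)
    ax = vol.axial_axis
    for roi in rois:
        if roi.slice_index in seen:
            raise ValueError(f"duplicate ROI for slice index {roi.slice_index}")
        if not (0 <= roi.slice_index < vol.shape[ax]):
            raise ValueError(f"slice index {roi.slice_index} outside grid")
        seen.add(roi.slice_index)
        mask[_slice_indexer(ax, roi.slice_index)] = roi.footprint(vol)
    return Voi(mask=mask)


def union_lesions(ls: LesionSet) -> Voi:
    """Voxelwise OR of disjoint per-lesion VOIs."""
    mask = np.zeros(ls.vois[0].shape, dtype=bool)
    for v in ls:
        mask |= v.mask
    return Voi(mask=mask)
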