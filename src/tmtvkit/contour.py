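"""Emulated readers: turn ground-truth lesion masks into the three VOI styles.

On clinical images a human draws the contours; on phantoms the drawing is
emulated from ground truth so the comparison between strategies is isolated
from reader variability:

* prism (single-ROI) reader — draws one generous in-plane contour around the
  axial projection of *all* lesions on one slice and extrudes it between the
  lesions' limiting slices. Like its clinical counterpart it cannot avoid a
  physiological hot structure hiding inside the footprint at another depth.
* slicewise reader — edits the contour on every slice, tracking each lesion
  cross-section and explicitly erasing physiological voxels.
* multiple-ROI reader — one contour per lesion, also avoiding physiology.

All readers dilate the true contour by a small margin, as a human would draw
generously around the visible uptake.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .phantom import Phantom
from .volume import LesionSet, PlanarRoi, Voi, extrude_single_roi, stack_slicewise_rois

__all__ = [
    "prism_single_voi",
    "slicewise_voi",
    "multiple_roi_lesions",
    "STRATEGIES",
]

DEFAULT_MARGIN_VOX = 2


def _dilate2d(mask2d: np.ndarray, margin_vox: int) -> np.ndarray:
    if margin_vox <= 0 or not mask2d.any():
        return mask2d
    return ndimage.binary_dilation(mask2d, iterations=margin_vox)


def _lesion_union(phantom: Phantom) -> np.ndarray:
    acc = np.zeros(phantom.volume.shape, dtype=bool)
    for m in phantom.lesion_masks:
        acc |= m.mask
    return acc


def prism_single_voi(phantom: Phantom, margin_vox: int = DEFAULT_MARGIN_VOX) -> Voi:
    """Single-slice contour around every lesion focus, extruded as a prism."""
    union = _lesion_union(phantom)
    ax = phantom.volume.axial_axis
    slices_with_lesion = np.nonzero(union.any(axis=tuple(a for a in range(3) if a != ax)))[0]
    if slices_with_lesion.size == 0:
        raise ValueError(f"{phantom.subject_id}: no lesion voxels to contour")
    z_min, z_max = int(slices_with_lesion[0]), int(slices_with_lesion[-1])
    footprint = _dilate2d(union.max(axis=ax).astype(bool), margin_vox)
    areas = [union.take(k, axis=ax).sum() for k in range(z_min, z_max + 1)]
    draw_slice = z_min + int(np.argmax(areas))
    roi = PlanarRoi(slice_index=draw_slice, mask2d=footprint)
    return extrude_single_roi(roi, z_min, z_max, phantom.volume)


def slicewise_voi(phantom: Phantom, margin_vox: int = DEFAULT_MARGIN_VOX) -> Voi:
    """Slice-by-slice contours tracking the lesions, erasing physiology."""
    union = _lesion_union(phantom)
    physio = phantom.physio_mask.mask
    ax = phantom.volume.axial_axis
    rois = []
    for k in range(phantom.volume.shape[ax]):
        cross = union.take(k, axis=ax)
        if not cross.any():
            continue
        fp = _dilate2d(cross, margin_vox) & ~physio.take(k, axis=ax)
        rois.append(PlanarRoi(slice_index=k, mask2d=fp))
    if not rois:
        raise ValueError(f"{phantom.subject_id}: no lesion voxels to contour")
    return stack_slicewise_rois(rois, phantom.volume)


def multiple_roi_lesions(
    phantom: Phantom, margin_vox: int = DEFAULT_MARGIN_VOX
) -> LesionSet:
    """One dilated VOI per lesion, physiology erased, overlaps resolved.

    Dilated contours of nearby lesions can touch; contested voxels stay with
    the earlier lesion so the set remains pairwise disjoint.
    """
    physio = phantom.physio_mask.mask
    claimed = np.zeros(phantom.volume.shape, dtype=bool)
    vois = []
    ax = phantom.volume.axial_axis
    for lesion in phantom.lesion_masks:
        grown = np.zeros_like(lesion.mask)
        for k in range(phantom.volume.shape[ax]):
            cross = lesion.mask.take(k, axis=ax)
            if cross.any():
                idx: list = [slice(None)] * 3
                idx[ax] = k
                grown[tuple(idx)] = _dilate2d(cross, margin_vox)
        grown &= ~physio
        grown &= ~claimed
        claimed |= grown
        vois.append(Voi(mask=grown))
    return LesionSet(vois)


STRATEGIES = {
    "prism_single": prism_single_voi,
    "slicewise_single": slicewise_voi,
    "multiple_roi": multiple_roi_lesions,
}
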