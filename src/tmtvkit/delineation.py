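"""Threshold segmentation within a VOI and PET metric extraction.

Given an SUV volume, a VOI and a cutoff — absolute (a fixed SUV such as 2.5)
or relative (a fraction of the VOI's SUVmax such as 0.41 or 0.50) — the
segmentation keeps the voxels whose SUV lies strictly above the cutoff.
From the resulting mask it extracts:

* TMTV — total metabolic tumor volume, voxel count × voxel volume, in cm³;
* SUVmean, SUVmax — mean and maximum voxel SUV over the mask;
* SUVpeak — maximum over candidate centers of the mean SUV inside a 1.0 cm³
  sphere (EANM-style), with the candidate-center scope configurable;
* TLG — total lesion glycolysis, SUVmean × TMTV.

The selection is purely voxelwise: no connected-component filtering and no
adaptive or background-ratio rules. Excluding physiological uptake is the
VOI's job, not the threshold's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LesionSet, SuvVolume, Voi, union_lesions

__all__ = [
    "ThresholdSpec",
    "DelineationResult",
    "apply_threshold",
    "compute_metrics",
    "delineate",
    "delineate_multiple",
    "suv_peak",
    "PEAK_SPHERE_VOLUME_CM3",
]

logger = logging.getLogger(__name__)

#: Volume of the SUVpeak averaging sphere (cm³); radius ≈ 6.2 mm.
PEAK_SPHERE_VOLUME_CM3 = 1.0


def _voxel_above(values: np.ndarray, threshold_suv: float) -> np.ndarray:
    """The single voxel-selection predicate: SUV strictly above the cutoff.

    Isolated here so the opposite convention (>=) is a one-line change.
    """
    return values > threshold_suv


@dataclass(frozen=True)
class ThresholdSpec:
    """An absolute SUV cutoff or a relative fraction of the VOI's SUVmax."""

    kind: str  # "absolute" | "relative"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"kind must be 'absolute' or 'relative', got {self.kind!r}")
        if self.kind == "absolute" and not self.value > 0:
            raise ValueError("absolute threshold must be > 0 SUV")
        if self.kind == "relative" and not (0 < self.value < 1):
            raise ValueError("relative threshold must lie in (0, 1)")

    @classmethod
    def parse(cls, text: str) -> "ThresholdSpec":
        """Parse 'abs:2.5' or 'rel:0.41'."""
        kind, _, num = text.partition(":")
        mapping = {"abs": "absolute", "rel": "relative"}
        if kind not in mapping or not num:
            raise ValueError(f"cannot parse threshold {text!r}; use abs:<suv> or rel:<frac>")
        return cls(kind=mapping[kind], value=float(num))

    @property
    def label(self) -> str:
        if self.kind == "absolute":
            return f"abs{self.value:g}"
        return f"rel{int(round(self.value * 100))}"


@dataclass(frozen=True)
class DelineationResult:
    """Mask plus the PET metrics for one (volume, VOI, threshold) triple."""

    mask: Voi
    tmtv_cm3: float
    suv_mean: float
    suv_max: float
    suv_peak: float
    tlg_cm3: float
    threshold_used_suv: float

    def to_dict(self) -> dict:
        return {
            "tmtv_cm3": self.tmtv_cm3,
            "suv_mean": self.suv_mean,
            "suv_max": self.suv_max,
            "suv_peak": self.suv_peak,
            "tlg_cm3": self.tlg_cm3,
            "threshold_used_suv": self.threshold_used_suv,
            "n_voxels": self.mask.voxel_count,
        }


def apply_threshold(
    vol: SuvVolume, voi: Voi, t: ThresholdSpec
) -> tuple[Voi, float]:
    """Select the VOI voxels with SUV strictly above the cutoff.

    For a relative threshold the cutoff in SUV units is
    ``t.value × max(SUV over the VOI)`` — the SUVmax is taken over the VOI,
    not the whole volume. Returns the mask and the cutoff actually used.
    """
    voi.check_aligned(vol)
    if voi.voxel_count == 0:
        raise ValueError("cannot apply a threshold to an empty VOI")
    if t.kind == "absolute":
        threshold_suv = t.value
    else:
        suv_max = float(vol.values[voi.mask].max())
        if suv_max <= 0:
            raise ValueError("relative threshold undefined: VOI SUVmax is 0")
        threshold_suv = t.value * suv_max
    mask = voi.mask & _voxel_above(vol.values, threshold_suv)
    return Voi(mask=mask), float(threshold_suv)


def _sphere_offsets(spacing_mm: np.ndarray, volume_cm3: float) -> np.ndarray:
    """Binary kernel of voxel offsets whose centers fall in the peak sphere."""
    radius_mm = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = np.ceil(radius_mm / spacing_mm).astype(int)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return (dist2 <= radius_mm**2).astype(np.float64)


def suv_peak(
    vol: SuvVolume,
    scope: Voi,
    sphere_volume_cm3: float = PEAK_SPHERE_VOLUME_CM3,
) -> float:
    """SUVpeak: max over scope voxels of the mean SUV in a ~1 cm³ sphere.

    For every candidate center in ``scope`` the sphere collects the voxels
    whose centers lie within the sphere radius; at grid edges the sphere is
    clipped and the mean is taken over the in-grid voxels only.
    """
    scope.check_aligned(vol)
    if scope.voxel_count == 0:
        raise ValueError("SUVpeak scope mask is empty")
    kernel = _sphere_offsets(vol.spacing_mm, sphere_volume_cm3)
    sums = ndimage.convolve(vol.values, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(
        np.ones_like(vol.values), kernel, mode="constant", cval=0.0
    )
    means = sums / counts
    return float(means[scope.mask].max())


def compute_metrics(
    vol: SuvVolume,
    mask: Voi,
    peak_scope_mask: Voi,
    threshold_used_suv: float,
    sphere_volume_cm3: float = PEAK_SPHERE_VOLUME_CM3,
) -> DelineationResult:
    """Extract TMTV, SUVmean, SUVmax, SUVpeak and TLG from a segmented mask."""
    mask.check_aligned(vol)
    if mask.voxel_count == 0:
        raise ValueError(
            f"segmentation is empty at threshold {threshold_used_suv:g} SUV; "
            "no metrics can be extracted"
        )
    suv = vol.values[mask.mask]
    tmtv = mask.voxel_count * vol.voxel_volume_cm3
    mean = float(suv.mean())
    result = DelineationResult(
        mask=mask,
        tmtv_cm3=float(tmtv),
        suv_mean=mean,
        suv_max=float(suv.max()),
        suv_peak=suv_peak(vol, peak_scope_mask, sphere_volume_cm3),
        tlg_cm3=float(mean * tmtv),
        threshold_used_suv=float(threshold_used_suv),
    )
    return result


def delineate(
    vol: SuvVolume,
    voi: Voi,
    t: ThresholdSpec,
    peak_scope: str = "voi",
    sphere_volume_cm3: float = PEAK_SPHERE_VOLUME_CM3,
) -> DelineationResult:
    """Threshold a VOI and extract metrics in one step.

    ``peak_scope`` chooses the candidate-center set for SUVpeak: ``"voi"``
    makes SUVpeak threshold-invariant (the whole VOI is always scanned),
    while ``"mask"`` restricts candidates to the segmented voxels, making
    SUVpeak depend on the threshold. Both behaviors occur in clinical
    software, so the choice is explicit.
    """
    if peak_scope not in ("voi", "mask"):
        raise ValueError("peak_scope must be 'voi' or 'mask'")
    mask, threshold_suv = apply_threshold(vol, voi, t)
    scope = voi if peak_scope == "voi" else mask
    return compute_metrics(vol, mask, scope, threshold_suv, sphere_volume_cm3)


def delineate_multiple(
    vol: SuvVolume,
    ls: LesionSet,
    t: ThresholdSpec,
    suvmax_scope: str = "per_lesion",
    peak_scope: str = "voi",
    sphere_volume_cm3: float = PEAK_SPHERE_VOLUME_CM3,
) -> DelineationResult:
    """Delineate each lesion VOI independently and pool the metrics.

    Relative thresholds use each lesion's own SUVmax (``suvmax_scope=
    "per_lesion"``, the default) or the SUVmax over the union of lesion VOIs
    (``"global"``). TMTV is the sum of per-lesion TMTVs; SUVmean is the
    volume-weighted mean over the union mask; a lesion whose segmentation
    comes out empty contributes zero with a warning rather than aborting
    the whole subject.
    """
    if suvmax_scope not in ("per_lesion", "global"):
        raise ValueError("suvmax_scope must be 'per_lesion' or 'global'")
    union_voi = union_lesions(ls)
    if t.kind == "relative" and suvmax_scope == "global":
        global_max = float(vol.values[union_voi.mask].max())
        if global_max <= 0:
            raise ValueError("relative threshold undefined: union SUVmax is 0")
        eff_t = ThresholdSpec(kind="absolute", value=t.value * global_max)
    else:
        eff_t = t

    combined = np.zeros(vol.shape, dtype=bool)
    threshold_suvs: list[float] = []
    for i, lesion_voi in enumerate(ls):
        mask, used = apply_threshold(vol, lesion_voi, eff_t)
        threshold_suvs.append(used)
        if mask.voxel_count == 0:
            warnings.warn(
                f"lesion {i} produced an empty segmentation at "
                f"{used:g} SUV; it contributes 0 to TMTV",
                stacklevel=2,
            )
            logger.warning("lesion %d empty at threshold %g SUV", i, used)
            continue
        combined |= mask.mask

    pooled = Voi(mask=combined)
    if pooled.voxel_count == 0:
        raise ValueError("every lesion produced an empty segmentation")
    if peak_scope not in ("voi", "mask"):
        raise ValueError("peak_scope must be 'voi' or 'mask'")
    scope = union_voi if peak_scope == "voi" else pooled
    # per-lesion cutoffs may differ; the min is the bound every pooled voxel
    # is guaranteed to exceed
    return compute_metrics(
        vol, pooled, scope, min(threshold_suvs), sphere_volume_cm3
    )
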