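"""Synthetic FDG-PET phantom cohorts with ground truth and outcomes.

No public dataset accompanies the delineation-comparison problem this package
addresses, so the study conditions are emulated: torso-like SUV volumes
containing one or more avid ellipsoidal lesions, a nearby physiological hot
structure (a cardiac analogue), low uniform background, Gaussian
reconstruction blur (point-spread FWHM 6.0 or 4.8 mm, matching common
clinical reconstructions), and additive Gaussian noise in SUV space.

Ground truth for every lesion is the unblurred voxel-center ellipsoid
membership, so segmentation accuracy can be scored against a known volume.
Outcome (progression-free survival) times are drawn from an exponential model
whose hazard increases with total true lesion volume, with uniform censoring
over a clinically plausible follow-up window — so a larger tumor burden
really does predict earlier treatment failure in the synthetic cohort.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import SuvVolume, Voi, write_mask, write_suv_volume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "OutcomeRecord",
    "Phantom",
    "CohortSampler",
    "StepHazard",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "FWHM_TO_SIGMA",
]

#: FWHM = sigma * 2*sqrt(2 ln 2) ≈ 2.355 * sigma for a Gaussian PSF.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Plausible clinical follow-up window (months) used for uniform censoring.
FOLLOW_UP_MONTHS = (3.0, 104.0)


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal avid structure: center, semi-axes (mm), plateau SUV."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    uptake_suv: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("ellipsoid semi-axes must all be positive")
        if self.uptake_suv <= 0:
            raise ValueError("uptake_suv must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    background_suv: float
    lesions: tuple[LesionSpec, ...]
    physiological: tuple[LesionSpec, ...] = ()
    psf_fwhm_mm: float = 6.0
    noise_sd_suv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        object.__setattr__(self, "physiological", tuple(self.physiological))
        if any(n < m for n, m in zip(self.grid_shape, (8, 8, 4))):
            raise ValueError(f"grid_shape must be at least (8, 8, 4), got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.background_suv < 0 or self.psf_fwhm_mm < 0 or self.noise_sd_suv < 0:
            raise ValueError("background, FWHM and noise SD must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OutcomeRecord:
    """Progression-free-survival record: time in months, event observed?"""

    subject_id: str
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError("time_months must be positive")


@dataclass(frozen=True)
class Phantom:
    """A generated subject: image, per-lesion ground truth, physiology."""

    subject_id: str
    spec: PhantomSpec
    volume: SuvVolume
    lesion_masks: tuple[Voi, ...]
    physio_mask: Voi

    @property
    def true_volume_cm3(self) -> float:
        """Total ground-truth lesion volume (voxel-center membership)."""
        return sum(m.voxel_count for m in self.lesion_masks) * self.volume.voxel_volume_cm3


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    spacing: np.ndarray,
    spec: LesionSpec,
) -> np.ndarray:
    """Voxel-center membership of an axis-aligned ellipsoid."""
    coords = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    dist2 = np.zeros(grid_shape)
    for ax, (c, r) in enumerate(zip(spec.center_mm, spec.radii_mm)):
        shape = [1, 1, 1]
        shape[ax] = grid_shape[ax]
        dist2 = dist2 + (((coords[ax] - c) / r) ** 2).reshape(shape)
    return dist2 <= 1.0


def _check_inside_grid(spec: LesionSpec, grid_shape, spacing) -> None:
    extent_mm = [(n - 1) * s for n, s in zip(grid_shape, spacing)]
    for ax in range(3):
        lo = spec.center_mm[ax] - spec.radii_mm[ax]
        hi = spec.center_mm[ax] + spec.radii_mm[ax]
        if lo < 0 or hi > extent_mm[ax]:
            raise ValueError(
                f"structure at {spec.center_mm} with radii {spec.radii_mm} mm "
                f"extends beyond the grid along axis {ax}"
            )


def generate_phantom(spec: PhantomSpec) -> tuple[SuvVolume, list[Voi], Voi]:
    """Render one phantom: paint ellipsoids, blur, add noise, clip at 0.

    Ground-truth lesion masks are the *unblurred* voxel-center memberships.
    Lesion ellipsoids must be pairwise non-overlapping (the ground truth
    would be ambiguous otherwise) and fully inside the grid. Deterministic
    given the spec's seed.
    """
    spacing = np.asarray(spec.spacing_mm, dtype=np.float64)
    values = np.full(spec.grid_shape, float(spec.background_suv))

    occupancy = np.zeros(spec.grid_shape, dtype=np.int32)
    lesion_masks: list[Voi] = []
    for lesion in spec.lesions:
        _check_inside_grid(lesion, spec.grid_shape, spacing)
        m = _ellipsoid_mask(spec.grid_shape, spacing, lesion)
        occupancy += m
        lesion_masks.append(Voi(mask=m))
        values[m] = lesion.uptake_suv
    if np.any(occupancy > 1):
        raise ValueError("lesion ellipsoids overlap; ground truth would be ambiguous")

    physio = np.zeros(spec.grid_shape, dtype=bool)
    for organ in spec.physiological:
        _check_inside_grid(organ, spec.grid_shape, spacing)
        m = _ellipsoid_mask(spec.grid_shape, spacing, organ)
        if np.any(m & (occupancy > 0)):
            raise ValueError("physiological structure overlaps a lesion")
        physio |= m
        values[m] = organ.uptake_suv

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spacing
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd_suv > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd_suv, size=values.shape)
    values = np.clip(values, 0.0, None)

    vol = SuvVolume(values=values, spacing_mm=spacing)
    return vol, lesion_masks, Voi(mask=physio)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortSampler:
    """Distributions from which per-subject phantom specs are drawn.

    Defaults emulate localized (stage I–II) lymphoma on a clinical PET
    reconstruction: 1–4 avid nodal lesions of 6–18 mm semi-axes with uptake
    4–15 SUV over a 0.5–1.0 SUV background, one cardiac-analogue hot
    structure at 3–8 SUV near the lesion column, 6.0 mm PSF and 0.15 SUV
    noise on a 3 mm isotropic grid.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 40)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_lesions_range: tuple[int, int] = (1, 4)
    lesion_radius_mm_range: tuple[float, float] = (6.0, 18.0)
    lesion_uptake_suv_range: tuple[float, float] = (4.0, 15.0)
    background_suv_range: tuple[float, float] = (0.5, 1.0)
    physio_uptake_suv_range: tuple[float, float] = (3.0, 8.0)
    physio_radius_mm_range: tuple[float, float] = (12.0, 18.0)
    psf_fwhm_mm: float = 6.0
    noise_sd_suv: float = 0.15

    def sample_spec(self, rng: np.random.Generator, seed: int) -> PhantomSpec:
        extent = [(n - 1) * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        cx, cy = extent[0] / 2.0, extent[1] / 2.0
        n_lesions = int(rng.integers(self.n_lesions_range[0], self.n_lesions_range[1] + 1))

        # The cardiac analogue sits mid-grid; lesions are stacked along the
        # axial axis around it, as mediastinal nodal disease sits around the
        # heart. A single-slice prism contour drawn on a lesion slice then
        # genuinely risks sweeping the organ in at another depth.
        physio_r = rng.uniform(*self.physio_radius_mm_range, size=3)
        physio = LesionSpec(
            center_mm=(cx, cy, extent[2] / 2.0),
            radii_mm=tuple(physio_r),
            uptake_suv=float(rng.uniform(*self.physio_uptake_suv_range)),
        )

        lesions: list[LesionSpec] = []
        placed = [physio]
        attempts = 0
        while len(lesions) < n_lesions and attempts < 500:
            attempts += 1
            radii = rng.uniform(*self.lesion_radius_mm_range, size=3)
            margin = radii.max() + 2.0
            center = (
                float(rng.uniform(cx - 25.0, cx + 25.0)),
                float(rng.uniform(cy - 25.0, cy + 25.0)),
                float(rng.uniform(margin, extent[2] - margin)),
            )
            cand = LesionSpec(
                center_mm=center,
                radii_mm=tuple(radii),
                uptake_suv=float(rng.uniform(*self.lesion_uptake_suv_range)),
            )
            if any(_ellipsoids_too_close(cand, other) for other in placed):
                continue
            try:
                _check_inside_grid(cand, self.grid_shape, np.asarray(self.spacing_mm))
            except ValueError:
                continue
            lesions.append(cand)
            placed.append(cand)
        if not lesions:
            raise RuntimeError("could not place any lesion; sampler ranges too tight")

        return PhantomSpec(
            grid_shape=self.grid_shape,
            spacing_mm=self.spacing_mm,
            background_suv=float(rng.uniform(*self.background_suv_range)),
            lesions=tuple(lesions),
            physiological=(physio,),
            psf_fwhm_mm=self.psf_fwhm_mm,
            noise_sd_suv=self.noise_sd_suv,
            seed=seed,
        )


def _ellipsoids_too_close(a: LesionSpec, b: LesionSpec) -> bool:
    # conservative: bounding spheres with a 2 mm guard band
    d = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
    return d < max(a.radii_mm) + max(b.radii_mm) + 2.0


@dataclass(frozen=True)
class StepHazard:
    """Event rate jumps from ``low`` to ``high`` where true volume > v_star."""

    v_star_cm3: float
    low_rate_per_month: float = 0.002
    high_rate_per_month: float = 0.08

    def rate(self, volume_cm3: float) -> float:
        return self.high_rate_per_month if volume_cm3 > self.v_star_cm3 else self.low_rate_per_month


def generate_cohort(
    n: int,
    sampler: CohortSampler | None = None,
    hazard_scale: float = 1.0e-3,
    seed: int = 0,
    hazard: StepHazard | None = None,
) -> tuple[list[Phantom], list[OutcomeRecord]]:
    """Draw ``n`` phantoms and matched progression-free-survival outcomes.

    Event times are exponential with per-subject rate
    ``hazard_scale × true_volume_cm3`` per month (or a :class:`StepHazard`
    if given), so the hazard increases monotonically with tumor burden.
    Censoring times are uniform over 3–104 months; the recorded time is the
    smaller of the two. ``hazard_scale = 0`` yields an all-censored cohort.
    Fully reproducible given the seed.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    sampler = sampler or CohortSampler()
    root = np.random.SeedSequence(seed)
    spec_seq, outcome_seq = root.spawn(2)
    spec_rng = np.random.default_rng(spec_seq)
    outcome_rng = np.random.default_rng(outcome_seq)

    phantoms: list[Phantom] = []
    records: list[OutcomeRecord] = []
    phantom_seeds = spec_rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        subject_id = f"S{i:03d}"
        spec = sampler.sample_spec(spec_rng, seed=int(phantom_seeds[i]))
        vol, lesion_masks, physio_mask = generate_phantom(spec)
        phantom = Phantom(
            subject_id=subject_id,
            spec=spec,
            volume=vol,
            lesion_masks=tuple(lesion_masks),
            physio_mask=physio_mask,
        )
        phantoms.append(phantom)

        v = phantom.true_volume_cm3
        rate = hazard.rate(v) if hazard is not None else hazard_scale * v
        if rate > 0:
            t_event = float(outcome_rng.exponential(1.0 / rate))
        else:
            t_event = np.inf
        t_cens = float(outcome_rng.uniform(*FOLLOW_UP_MONTHS))
        event = t_event <= t_cens
        records.append(
            OutcomeRecord(
                subject_id=subject_id,
                time_months=max(t_event if event else t_cens, 1e-6),
                event=bool(event),
            )
        )
    return phantoms, records


# ---------------------------------------------------------------------------
# On-disk cohort layout


def write_cohort(
    phantoms: list[Phantom],
    records: list[OutcomeRecord],
    out_dir: str | Path,
) -> Path:
    """Write volumes/masks as NIfTI, outcomes as CSV, manifest as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ph in phantoms:
        sub = out / ph.subject_id
        sub.mkdir(exist_ok=True)
        write_suv_volume(ph.volume, sub / "suv.nii.gz")
        for j, m in enumerate(ph.lesion_masks):
            write_mask(m, ph.volume, sub / f"lesion_{j:02d}.nii.gz")
        write_mask(ph.physio_mask, ph.volume, sub / "physio.nii.gz")
        manifest.append({"subject_id": ph.subject_id, "spec": ph.spec.to_dict()})
    pd.DataFrame(
        [
            {"subject_id": r.subject_id, "time_months": r.time_months, "event": int(r.event)}
            for r in records
        ]
    ).to_csv(out / "outcomes.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
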