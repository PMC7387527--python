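# Methods

## The measurement model

Everything in `tmtvkit` operates on a 3D grid of standardized uptake values
(SUV, g/mL) with known voxel spacing. A delineation is the composition of
two operators:

1. **VOI construction** — a boolean mask delimiting where segmentation is
   allowed. Three strategies are implemented, mirroring clinical contouring
   workflows: a single planar ROI extruded as a prism between two limiting
   axial slices; a stack of slice-by-slice edited ROIs; and independent
   per-lesion ROIs combined by disjoint union.
2. **Threshold segmentation** — the VOI voxels whose SUV lies strictly
   above a cutoff: an absolute SUV (default 2.5) or a fraction of the VOI's
   own SUVmax (defaults 0.41 and 0.50). The strict inequality implements
   the convention of selecting voxels *over* the threshold; it is isolated
   in a single predicate so the opposite convention is a one-line change.
   For relative cutoffs, SUVmax is taken over the VOI, not the whole
   volume. No connected-component filtering is applied: excluding
   physiological uptake is the VOI's job, and any post-hoc cleanup would
   change the quantity being studied.

From the segmented mask: TMTV = voxel count × voxel volume (cm³); SUVmean
and SUVmax over the mask; TLG = SUVmean × TMTV (an exact identity of the
result object, tested at 1e-9 relative tolerance); SUVpeak = the maximum,
over candidate centers, of the mean SUV within a 1.0 cm³ sphere (radius
≈ 6.2 mm) of voxel centers, clipped to the grid at edges. The sphere mean
is computed by convolving the volume and an all-ones volume with the
spherical kernel and dividing, which is exactly the clipped brute-force
scan. The candidate-center scope is configurable: `peak_scope="voi"` scans
the whole VOI, making SUVpeak threshold-invariant; `peak_scope="mask"`
scans only segmented voxels, making SUVpeak threshold-dependent. Both
behaviors occur in clinical tools, so the choice is explicit and recorded
in every result.

Multiple-lesion delineation segments each lesion VOI independently and
pools: TMTV adds, SUVmean is the volume-weighted mean over the pooled mask,
SUVmax/SUVpeak are taken over the union. For relative cutoffs the SUVmax
scope is `per_lesion` (default) or `global`; the choice is surfaced in
every report because neither convention is universal. A lesion whose
segmentation comes out empty contributes zero with a warning — a cohort run
should survive one cold lesion — whereas a single-VOI delineation that
comes out empty is an error, since there is nothing left to report.

### Coordinate and membership conventions

Voxel indices are 0-based; the center of voxel (i, j, k) is at
`origin + (i, j, k)·spacing` in world mm; axis 2 is axial. Polygon ROI
membership is a strict voxel-center-in-interior test (boundary ties
excluded), delegated to exact geometric predicates. Masks are written to
NIfTI-1 as 0/1 uint8; volumes as float32, RAS, spacing in the affine.

## The phantom generator

The generator emulates the statistical structure of a localized-lymphoma
PET cohort, not the physics of acquisition. Each subject is rendered by
painting ellipsoids (plateau SUV inside, background outside), convolving
with an isotropic Gaussian point-spread function (σ = FWHM/2.355 per axis,
in voxel units), adding zero-mean Gaussian noise in SUV space, and clipping
at zero (SUV is nonnegative). Ground truth is the *unblurred* voxel-center
ellipsoid membership — no partial-volume weighting — so the only gap
between ground truth and the analytic ellipsoid volume is voxelization,
which the tests budget as one boundary shell of voxels. Overlapping lesion
ellipsoids are rejected (ground truth would be ambiguous), as are
structures extending beyond the grid.

Defaults, chosen once as a realistic stage I–II nodal-disease analogue:

| parameter | default | rationale |
|---|---|---|
| grid / spacing | 48×48×40 at 3 mm | torso section at clinical PET resolution |
| lesions per subject | 1–4 | localized disease |
| lesion semi-axes | U(6, 18) mm | sub-cm nodes to ~25 cm³ masses |
| lesion uptake | U(4, 15) SUV | clinically avid FDG lesions |
| background | U(0.5, 1.0) SUV | mediastinal blood-pool range |
| physiological structure | one ellipsoid, U(12, 18) mm, U(3, 8) SUV | cardiac analogue near the nodal column |
| PSF FWHM | 6.0 mm | typical iterative reconstruction filter (4.8 mm also exercised) |
| noise SD | 0.15 SUV | visually plausible reconstruction noise |

The cardiac analogue sits mid-grid with the lesions stacked around it along
the axial axis, so a single-slice prism contour genuinely risks sweeping it
in at another depth — the misdetection mode the strategy comparison exists
to measure. The emulated readers (`tmtvkit.contour`) dilate the true
contours by a 2-voxel margin, as a human draws generously around visible
uptake; the slice-edited and per-lesion readers additionally erase
physiological voxels, the prism reader cannot.

Outcomes: progression-free-survival times are exponential with per-subject
rate `hazard_scale × true volume` per month (default 1e-3, giving ~40–60%
events), or a step hazard (low/high rate around a volume threshold) for
cutoff-recovery experiments; censoring is uniform over a 3–104 month
follow-up window. Everything derives from one root seed via
`numpy.random.SeedSequence`, so cohorts are bit-reproducible and any stage
can be rerun in isolation.

**What the phantoms do not model:** count-space (Poisson) noise and
reconstruction artifacts, scatter/attenuation, respiratory motion,
heterogeneous intralesional uptake, non-ellipsoidal lesion shapes, and
reader variability. Passing tests therefore demonstrate the *relative*
behavior of thresholds and strategies under blur and noise — ordering,
correlation structure, bias direction — not absolute clinical accuracy.

## Partial-volume behavior of the absolute cutoff

For a blurred step from background *b* to plateau *u*, the SUV at the true
boundary is (u+b)/2. The 2.5-SUV isocontour therefore lies **outside** the
lesion (overestimation) when (u+b)/2 > 2.5, i.e. for avid lesions with
u ≳ 5–6, and **inside** it (underestimation) for fainter lesions — a
crossover the unit tests pin down numerically. Relative isocontours behave
oppositely: 41%/50% of a high SUVmax sits far above the blurred edge and
underestimates. On cohorts drawn from the default uptake range this yields
the characteristic ordering mean TMTV₂.₅ > TMTV₄₁% > TMTV₅₀%, the higher
between-strategy correlation of TMTV₂.₅, and the larger prognostic cutoff
it implies.

## Statistical components

**Agreement.** TMTV/TLG distributions are right-skewed, so paired analyses
default to the natural-log scale (the log base scales Bland–Altman bias but
leaves t, p and r unchanged; `scale="raw"` is available). Bland–Altman
limits are bias ± 1.96·SD of the paired differences; pairs outside the
limits are flagged as outliers and **retained** — flags are annotations,
never exclusions. Degenerate cases are explicit: identical arms give
t = 0, p = 1; zero-variance differences with nonzero mean give p = 0 with a
warning. Pearson r is emitted on both scales (log is the default reading).
No multiple-testing correction is applied; the tidy report carries the
comparison count for downstream correction.

**Prognosis.** ROC candidate cutoffs are the midpoints between consecutive
distinct sorted scores plus ±∞ sentinels; a subject is called positive when
score > cutoff (matching the voxel-selection convention); AUC is the
trapezoid area, which equals the tie-corrected rank-sum statistic (asserted
against independent oracles in the tests). The Youden index
J = sensitivity + specificity − 1 picks the dichotomizing cutoff; ties
break toward the smallest cutoff (the more sensitive split), and the
tie-break is recorded in every output. The binary ROC label is "event
observed during follow-up"; an optional horizon can exclude early-censored
subjects from the ROC (never from the survival analysis). Kaplan–Meier
estimation and the two-group log-rank test use the standard product-limit
conventions (subjects censored at an event time remain at risk at that
time).

A known property of this design, inherited from its clinical counterpart:
when the Youden cutoff is computed on a biased measurement (TMTV₂.₅), it
recovers the true hazard-step volume *on the measurement's own scale* —
the recovered cutoff is the TMTV image of the true threshold volume, not
the volume itself. The cutoff-recovery tests therefore map cutoffs back
through the cohort's measured TMTV-vs-true-volume relation.

## Problem sizes

Test and acceptance runs use deliberately compact configurations — 12×12×6
random volumes for exact segmentation oracles, 32×32×28 grids for cohort
statistics, 50-subject studies for the end-to-end correlation structure,
20 seeds for cutoff recovery — sizes at which every oracle can be exhaustive
and full runs complete in seconds to a few minutes on one core. The
defaults scale up by changing `CohortSampler` and `StudyConfig` fields
only.

## Known limitations

- Ellipsoidal, homogeneous lesions make relative isocontours behave more
  regularly than on necrotic or heterogeneous tumors.
- The emulated readers are deterministic; inter-reader variability is out
  of scope, so agreement statistics isolate methodology only.
- Adaptive/iterative and background-ratio thresholds are intentionally not
  implemented.
- The exponential outcome model has no covariates beyond tumor volume;
  it exists to give the prognostic machinery a known signal, not to model
  lymphoma biology.
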