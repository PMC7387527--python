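# tmtvkit

Total metabolic tumor volume (TMTV) is a leading quantitative biomarker on
baseline [¹⁸F]FDG-PET in lymphoma: the total volume, in cm³, of voxels
classified as tumor. In routine practice the classification is a simple SUV
threshold applied inside a reader-drawn volume of interest (VOI) — either an
absolute cutoff (SUV > 2.5) or a relative isocontour (SUV > 41% or 50% of
the region's SUVmax) — and the measured TMTV depends materially on which
cutoff and which contouring workflow is used.

`tmtvkit` is a Python library for studying exactly that dependence. It is
aimed at medical physicists and imaging scientists who want to quantify,
on controlled synthetic data, how threshold choice and VOI strategy
propagate into TMTV, SUV metrics, total lesion glycolysis (TLG = SUVmean ×
TMTV), inter-method agreement, and downstream prognostic cutoffs. It
provides:

- **`tmtvkit.phantom`** — a seeded generator of torso-like SUV phantoms:
  ellipsoidal avid lesions and a physiological hot structure over a low
  background, Gaussian reconstruction blur (point-spread FWHM, e.g. 6.0 or
  4.8 mm), additive SUV noise, exact ground-truth masks, and matched
  progression-free-survival outcomes whose hazard rises with true tumor
  burden.
- **`tmtvkit.volume`** — the `SuvVolume`/`Voi` data model, NIfTI I/O, and
  three VOI constructions: a single planar ROI extruded as a prism between
  limiting slices, slice-by-slice edited contours, and per-lesion ROIs.
- **`tmtvkit.delineation`** — threshold segmentation (strict SUV > cutoff;
  absolute, or relative to the VOI's SUVmax) and metric extraction: TMTV,
  SUVmean, SUVmax, SUVpeak (mean in a 1 cm³ sphere, EANM-style), TLG.
- **`tmtvkit.agreement`** — paired comparisons on the natural-log scale:
  Bland–Altman bias and 1.96·SD limits of agreement with outlier flagging
  (flagged pairs are kept), Pearson r, paired two-tailed t test.
- **`tmtvkit.prognosis`** — ROC with trapezoid AUC, Youden-index TMTV
  cutoff, cohort split, Kaplan–Meier curves and the log-rank test.
- **`tmtvkit.pipeline`** — `run_study()`: cohort → full (strategy ×
  threshold) delineation grid → pairwise agreement table → per-arm
  prognosis, reproducible from one seed.

## Worked example

`examples/02_threshold_delineation.py` segments a blurred 10 mm-radius
sphere (plateau 8 SUV, background 0.5, 6.0 mm FWHM) under all three
cutoffs:

```
true volume 4.42 cm3
  cutoff  SUV used  TMTV cm3  SUVmean  SUVmax  SUVpeak      TLG
 abs:2.5      2.50      5.76     5.15    7.98     7.51    29.64
rel:0.41      3.27      4.99     5.51    7.98     7.51    27.52
rel:0.50      3.99      3.84     6.11    7.98     7.51    23.47
```

The absolute 2.5 cutoff overestimates the true volume (the blurred lesion
edge, at (uptake+background)/2 ≈ 4.25 SUV, lies above 2.5), the 50%
isocontour underestimates it, and SUVmax/SUVpeak are threshold-invariant.
`examples/03_voi_strategies.py` shows the complementary failure mode: a
single-slice prism contour sweeps a hot organ lying between two lesions
into the VOI and inflates TMTV₂.₅ by roughly the organ volume, while
slice-edited and per-lesion contours avoid it. On a full 50-phantom study
(`examples/06_full_study.py`) this yields the characteristic pattern:
between-strategy correlation is highest for the absolute cutoff (r ≈ 0.98
vs ≈ 0.87/0.81 for 41%/50%) — reproducibility bought at the price of
systematic overestimation — while within a strategy the two relative
isocontours track each other closely (r > 0.97).

Each script in `examples/` is a short narrative of one capability; all run
in seconds.

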