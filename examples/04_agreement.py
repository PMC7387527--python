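"""Bland–Altman agreement between two delineation arms on a small cohort.

Twelve phantoms are contoured with the single-slice prism and the
per-lesion readers; TMTV under the 2.5 SUV cutoff is compared on the log
scale. The bias is the mean log ratio (prism inflation from swept-in
physiology), the limits of agreement are bias +/- 1.96 SD, and any pair
outside them is flagged — but kept in the analysis.
"""

import numpy as np

from tmtvkit import (
    PairedSample, ThresholdSpec, bland_altman, delineate, delineate_multiple,
    generate_cohort, log_transform, paired_t_test, pearson_r,
)
from tmtvkit.contour import multiple_roi_lesions, prism_single_voi

phantoms, _ = generate_cohort(12, seed=3)
t = ThresholdSpec.parse("abs:2.5")
prism = [delineate(p.volume, prism_single_voi(p), t).tmtv_cm3 for p in phantoms]
multi = [delineate_multiple(p.volume, multiple_roi_lesions(p), t).tmtv_cm3 for p in phantoms]

s = PairedSample(
    labels=tuple(p.subject_id for p in phantoms),
    a=np.array(prism), b=np.array(multi), quantity="tmtv",
)
report = bland_altman(s, scale="log")
t_stat, p = paired_t_test(log_transform(s))
print(f"n = {s.n} pairs, log scale")
print(f"bias {report.bias:+.3f}  (prism/multiple volume ratio "
      f"{np.exp(report.bias):.2f}x)")
print(f"limits of agreement [{report.loa_low:+.3f}, {report.loa_high:+.3f}]")
print(f"outliers flagged: {report.n_outliers} (retained in the analysis)")
print(f"Pearson r (log) {pearson_r(log_transform(s)):.3f};  "
      f"paired t = {t_stat:.2f}, p = {p:.3g}")
# A positive bias with high r means the prism systematically measures more
# volume while preserving the subjects' ranking.
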