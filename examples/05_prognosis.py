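"""Prognostic value of TMTV: ROC cutoff, survival split, log-rank.

A 60-subject cohort is generated with a hazard that steps up for tumors
larger than 15 cm3. TMTV under the 2.5 SUV cutoff is scored against the
observed progression events: the ROC AUC summarizes discrimination, the
Youden index picks the dichotomizing cutoff, and the Kaplan–Meier curves of
the resulting high/low groups are compared with the log-rank test.
"""

import numpy as np

from tmtvkit import (
    StepHazard, ThresholdSpec, delineate_multiple, generate_cohort,
    km_estimate, log_rank, roc_with_youden, split_by_cutoff,
)
from tmtvkit.contour import multiple_roi_lesions

phantoms, records = generate_cohort(
    60, hazard_scale=0.0, seed=7, hazard=StepHazard(v_star_cm3=15.0)
)
t = ThresholdSpec.parse("abs:2.5")
tmtv = np.array(
    [delineate_multiple(p.volume, multiple_roi_lesions(p), t).tmtv_cm3 for p in phantoms]
)
events = [r.event for r in records]

roc = roc_with_youden(tmtv, events)
print(f"AUC {roc.auc:.3f}; Youden cutoff {roc.youden_cutoff:.1f} cm3 "
      f"(J = {roc.youden_value:.2f})")

high, low = split_by_cutoff(records, tmtv, roc.youden_cutoff)
chi2, p = log_rank(high, low)
km_hi, km_lo = km_estimate(high), km_estimate(low)
print(f"high-TMTV group n={len(high)} ({km_hi.n_events} events), "
      f"low-TMTV group n={len(low)} ({km_lo.n_events} events)")
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.4g}")
print(f"S(24 months): high {km_hi.survival_at(24):.2f} vs low {km_lo.survival_at(24):.2f}")
# The cutoff lands near the TMTV image of the 15 cm3 hazard step (inflated
# by the 2.5-cutoff's overestimation of blurred avid lesions), and the
# high-TMTV arm shows clearly worse progression-free survival.
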