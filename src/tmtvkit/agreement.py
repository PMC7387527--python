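"""Paired agreement statistics: log transform, t test, Pearson, Bland–Altman.

TMTV and TLG distributions are right-skewed, so paired comparisons between
two delineation arms are run on natural-log-transformed values by default
(the base changes Bland–Altman bias values but not t, p or r). Bland–Altman
limits of agreement are bias ± 1.96·SD of the paired differences; pairs
outside the limits are flagged as outliers but never removed from the
analysis. No multiple-testing correction is applied — the tidy report
carries the comparison count so users can correct downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "BlandAltmanReport",
    "log_transform",
    "paired_t_test",
    "pearson_r",
    "bland_altman",
]

LOA_MULTIPLIER = 1.96  # normal-approximation limits of agreement


@dataclass(frozen=True)
class PairedSample:
    """Two same-length measurement lists over the same subjects, in order."""

    labels: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray
    quantity: str = "tmtv"

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        labels = tuple(str(x) for x in self.labels)
        if not (len(labels) == len(a) == len(b)):
            raise ValueError(
                f"labels/a/b lengths differ: {len(labels)}, {len(a)}, {len(b)}"
            )
        if len(a) < 3:
            raise ValueError("paired analysis needs at least 3 pairs")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class BlandAltmanReport:
    """Bias, spread and limits of agreement for one paired comparison."""

    scale: str  # "log" | "raw"
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    outlier_flags: tuple[bool, ...]
    means: np.ndarray
    diffs: np.ndarray

    @property
    def n_outliers(self) -> int:
        return int(sum(self.outlier_flags))

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n_outliers": self.n_outliers,
        }


def log_transform(s: PairedSample) -> PairedSample:
    """Natural log, elementwise; every value must be strictly positive."""
    for side, vals in (("a", s.a), ("b", s.b)):
        bad = np.nonzero(vals <= 0)[0]
        if bad.size:
            raise ValueError(
                f"log transform needs positive values; {s.quantity}.{side} is "
                f"{vals[bad[0]]:g} for subject {s.labels[bad[0]]!r}"
            )
    return replace(s, a=np.log(s.a), b=np.log(s.b))


def paired_t_test(s: PairedSample) -> tuple[float, float]:
    """Two-tailed paired Student t test on a − b.

    Degenerate spreads are resolved explicitly: all differences exactly zero
    gives (0, 1); zero spread around a nonzero mean gives p = 0 with a
    warning, since the test statistic diverges.
    """
    d = s.a - s.b
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        warnings.warn(
            "paired differences have zero variance but nonzero mean; "
            "t statistic is infinite",
            stacklevel=2,
        )
        return float(np.sign(d.mean()) * np.inf), 0.0
    t_stat, p = stats.ttest_rel(s.a, s.b)
    return float(t_stat), float(p)


def pearson_r(s: PairedSample) -> float:
    """Product-moment correlation between the two arms."""
    if s.a.std() == 0.0 or s.b.std() == 0.0:
        raise ValueError("Pearson correlation undefined: an arm has zero variance")
    r, _ = stats.pearsonr(s.a, s.b)
    return float(r)


def bland_altman(s: PairedSample, scale: str = "log") -> BlandAltmanReport:
    """Bland–Altman agreement of a vs b on the chosen scale.

    Differences (a − b) are taken against pair means; limits of agreement
    are bias ± 1.96·SD. A pair whose difference falls outside the limits is
    flagged, and retained: flags are annotations, not exclusions.
    """
    if scale not in ("log", "raw"):
        raise ValueError("scale must be 'log' or 'raw'")
    if scale == "log":
        s = log_transform(s)
    diffs = s.a - s.b
    means = (s.a + s.b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low = bias - LOA_MULTIPLIER * sd
    loa_high = bias + LOA_MULTIPLIER * sd
    flags = tuple(bool(d < loa_low or d > loa_high) for d in diffs)
    return BlandAltmanReport(
        scale=scale,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        outlier_flags=flags,
        means=means,
        diffs=diffs,
    )
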