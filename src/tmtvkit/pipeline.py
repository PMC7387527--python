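"""Full study orchestration: cohort → delineation grid → agreement → prognosis.

``run_study`` reproduces the shape of a delineation-comparison study on a
synthetic cohort: every subject is contoured under each requested VOI
strategy, segmented under each threshold, and the resulting per-subject
metric table is compared pairwise (within-strategy across thresholds and
between strategies at fixed threshold) with Bland–Altman/Pearson/t
statistics. Each (strategy, threshold) arm then gets a prognostic work-up:
ROC with Youden TMTV cutoff, cohort split, Kaplan–Meier curves and log-rank.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
so a run is idempotent; every tabular output carries the config hash in a
header comment, and the manifest records config, seed and package version.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import (
    PairedSample,
    bland_altman,
    log_transform,
    paired_t_test,
    pearson_r,
)
from .contour import STRATEGIES, multiple_roi_lesions
from .delineation import ThresholdSpec, delineate, delineate_multiple
from .phantom import CohortSampler, OutcomeRecord, Phantom, generate_cohort
from .prognosis import km_estimate, log_rank, roc_with_youden, split_by_cutoff

__all__ = ["StudyConfig", "StudyReport", "run_study"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (
    ThresholdSpec("absolute", 2.5),
    ThresholdSpec("relative", 0.41),
    ThresholdSpec("relative", 0.50),
)

AGREEMENT_QUANTITIES = ("tmtv_cm3", "tlg_cm3", "suv_mean", "suv_max", "suv_peak")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to rerun a study byte-identically."""

    n_subjects: int = 50
    seed: int = 0
    strategies: tuple[str, ...] = ("prism_single", "slicewise_single", "multiple_roi")
    thresholds: tuple[ThresholdSpec, ...] = DEFAULT_THRESHOLDS
    peak_scope: str = "voi"
    suvmax_scope: str = "per_lesion"
    agreement_scale: str = "log"
    hazard_scale: float = 1.0e-3
    sampler: CohortSampler = field(default_factory=CohortSampler)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.strategies or not self.thresholds:
            raise ValueError("need at least one strategy and one threshold")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = [f"{t.kind}:{t.value}" for t in self.thresholds]
        return d

    @property
    def config_hash(self) -> str:
        # the hash identifies the scientific configuration; where the report
        # lands on disk is not part of it
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    """In-memory bundle of everything a study run produced."""

    config: StudyConfig
    metrics: pd.DataFrame
    agreement: pd.DataFrame
    prognosis: dict
    failures: list[dict]
    manifest: dict


def _arm_label(strategy: str, t: ThresholdSpec) -> str:
    return f"{strategy}:{t.label}"


def _delineate_subject(
    phantom: Phantom, strategy: str, t: ThresholdSpec, cfg: StudyConfig
):
    if strategy == "multiple_roi":
        ls = multiple_roi_lesions(phantom)
        return delineate_multiple(
            phantom.volume, ls, t,
            suvmax_scope=cfg.suvmax_scope, peak_scope=cfg.peak_scope,
        )
    voi = STRATEGIES[strategy](phantom)
    return delineate(phantom.volume, voi, t, peak_scope=cfg.peak_scope)


def compute_metric_table(
    phantoms: list[Phantom], cfg: StudyConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """One row per (subject, strategy, threshold); failures logged, not fatal."""
    rows = []
    failures: list[dict] = []
    for phantom in phantoms:
        for strategy in cfg.strategies:
            for t in cfg.thresholds:
                try:
                    res = _delineate_subject(phantom, strategy, t, cfg)
                except Exception as exc:  # pragma: no cover - defensive
                    logger.error(
                        "subject=%s strategy=%s threshold=%s failed: %s",
                        phantom.subject_id, strategy, t.label, exc,
                    )
                    failures.append(
                        {
                            "subject_id": phantom.subject_id,
                            "strategy": strategy,
                            "threshold": t.label,
                            "error": str(exc),
                        }
                    )
                    continue
                logger.info(
                    "subject=%s strategy=%s threshold=%s tmtv=%.3f cutoff=%.3f",
                    phantom.subject_id, strategy, t.label,
                    res.tmtv_cm3, res.threshold_used_suv,
                )
                rows.append(
                    {
                        "subject_id": phantom.subject_id,
                        "strategy": strategy,
                        "threshold": t.label,
                        "true_volume_cm3": phantom.true_volume_cm3,
                        "suvmax_scope": cfg.suvmax_scope,
                        "peak_scope": cfg.peak_scope,
                        **res.to_dict(),
                    }
                )
    return pd.DataFrame(rows), failures


def _paired_from_table(
    table: pd.DataFrame, arm_a: tuple[str, str], arm_b: tuple[str, str], quantity: str
) -> PairedSample | None:
    sel_a = table[(table.strategy == arm_a[0]) & (table.threshold == arm_a[1])]
    sel_b = table[(table.strategy == arm_b[0]) & (table.threshold == arm_b[1])]
    merged = sel_a.merge(sel_b, on="subject_id", suffixes=("_a", "_b"))
    merged = merged[(merged[f"{quantity}_a"] > 0) & (merged[f"{quantity}_b"] > 0)]
    if len(merged) < 3:
        return None
    return PairedSample(
        labels=tuple(merged.subject_id),
        a=merged[f"{quantity}_a"].to_numpy(),
        b=merged[f"{quantity}_b"].to_numpy(),
        quantity=quantity,
    )


def agreement_pairs(cfg: StudyConfig) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """The study's comparison grid: threshold pairs within each strategy,
    strategy pairs at each threshold."""
    pairs = []
    tlabels = [t.label for t in cfg.thresholds]
    for strategy in cfg.strategies:
        for ta, tb in itertools.combinations(tlabels, 2):
            pairs.append(((strategy, ta), (strategy, tb)))
    for sa, sb in itertools.combinations(cfg.strategies, 2):
        for t in tlabels:
            pairs.append(((sa, t), (sb, t)))
    return pairs


def compute_agreement_table(table: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    rows = []
    for arm_a, arm_b in agreement_pairs(cfg):
        for quantity in AGREEMENT_QUANTITIES:
            s = _paired_from_table(table, arm_a, arm_b, quantity)
            if s is None:
                continue
            report = bland_altman(s, scale=cfg.agreement_scale)
            s_for_tests = log_transform(s) if cfg.agreement_scale == "log" else s
            t_stat, p = paired_t_test(s_for_tests)
            row = {
                "quantity": quantity,
                "arm_a": ":".join(arm_a),
                "arm_b": ":".join(arm_b),
                "n": s.n,
                "scale": cfg.agreement_scale,
                "bias": report.bias,
                "sd_diff": report.sd_diff,
                "loa_low": report.loa_low,
                "loa_high": report.loa_high,
                "n_outliers": report.n_outliers,
                "r_log": pearson_r(log_transform(s)),
                "r_raw": pearson_r(s),
                "t_stat": t_stat,
                "p_value": p,
            }
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["n_comparisons"] = len(df)
    return df


def compute_prognosis(
    table: pd.DataFrame, records: list[OutcomeRecord], cfg: StudyConfig
) -> dict:
    """ROC/Youden/KM/log-rank per (strategy, threshold) arm, on TMTV."""
    by_id = {r.subject_id: r for r in records}
    out: dict = {}
    for strategy in cfg.strategies:
        for t in cfg.thresholds:
            sel = table[(table.strategy == strategy) & (table.threshold == t.label)]
            recs = [by_id[s] for s in sel.subject_id]
            scores = sel.tmtv_cm3.to_numpy()
            labels = [r.event for r in recs]
            arm = _arm_label(strategy, t)
            if len(set(labels)) < 2:
                out[arm] = {"error": "single-class outcome; ROC undefined"}
                continue
            roc = roc_with_youden(scores, labels)
            high, low = split_by_cutoff(recs, scores, roc.youden_cutoff)
            entry = {
                **roc.to_dict(),
                "youden_tie_break": "smallest_cutoff",
                "n_high": len(high),
                "n_low": len(low),
                "seed": cfg.seed,
            }
            if high and low:
                chi2, p = log_rank(high, low)
                km_high, km_low = km_estimate(high), km_estimate(low)
                entry.update(
                    {
                        "logrank_chi2": chi2,
                        "logrank_p": p,
                        "km_high": {
                            "event_times": km_high.event_times.tolist(),
                            "survival": km_high.survival.tolist(),
                        },
                        "km_low": {
                            "event_times": km_low.event_times.tolist(),
                            "survival": km_low.survival.tolist(),
                        },
                    }
                )
            out[arm] = entry
    return out


def _write_csv(df: pd.DataFrame, path: Path, cfg: StudyConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the full study analogue and (optionally) write the report bundle."""
    phantoms, records = generate_cohort(
        cfg.n_subjects,
        sampler=cfg.sampler,
        hazard_scale=cfg.hazard_scale,
        seed=cfg.seed,
    )
    metrics, failures = compute_metric_table(phantoms, cfg)
    need_pairs = len(cfg.strategies) * len(cfg.thresholds) >= 2
    agreement = (
        compute_agreement_table(metrics, cfg) if need_pairs else pd.DataFrame()
    )
    prognosis = compute_prognosis(metrics, records, cfg)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "tmtvkit_version": __version__,
        "n_failures": len(failures),
        "failures": failures,
    }
    report = StudyReport(
        config=cfg,
        metrics=metrics,
        agreement=agreement,
        prognosis=prognosis,
        failures=failures,
        manifest=manifest,
    )
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(metrics, out / "metrics.csv", cfg)
        _write_csv(agreement, out / "agreement.csv", cfg)
        (out / "prognosis.json").write_text(json.dumps(prognosis, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        outcome_df = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "time_months": r.time_months,
                    "event": int(r.event),
                }
                for r in records
            ]
        )
        _write_csv(outcome_df, out / "outcomes.csv", cfg)
    return report
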