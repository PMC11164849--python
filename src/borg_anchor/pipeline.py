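"""End-to-end orchestration: simulate/read -> screen -> thresholds ->
anchor RPE -> summaries -> four ordinal models -> report.

Every record that drops out anywhere is counted with its reason, and the
per-anchor accounting is asserted on every run: kept records = modelled
records + records skipped before splining + records whose anchor was
missing.  Reports are deterministic in (config, seed) and carry a config
hash so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort_io import (
    CPXRecord,
    ExclusionReport,
    ImplausibilityRules,
    apply_exclusions,
    read_cohort,
    write_cohort,
)
from .errors import ConfigError
from .interpolation import AnchorRPE, anchors_for_record
from .ordinal import (
    COVARIATES,
    ModelSpec,
    OrdinalFit,
    find_crossovers,
    fit_cumulative_logit,
    odds_ratio_table,
)
from .synthetic import GeneratorConfig, generate_cohort
from .thresholds import ThresholdResult, compute_thresholds

logger = logging.getLogger(__name__)

ANCHOR_NAMES = ("2mmol", "3mmol", "4mmol", "lt2")
_ANCHOR_FIELD = {"2mmol": "rpe_2", "3mmol": "rpe_3", "4mmol": "rpe_4", "lt2": "rpe_lt2"}

__all__ = [
    "PipelineConfig",
    "AnchorSummary",
    "PipelineReport",
    "summarize_anchor",
    "build_model_frame",
    "run_pipeline",
    "ANCHOR_NAMES",
]


@dataclass(frozen=True)
class PipelineConfig:
    """What to run: either a generator config or an input cohort CSV."""

    seed: int = 0
    generator: GeneratorConfig | None = None
    input_path: str | None = None
    out_dir: str | None = None
    delta: float = 0.2
    baseline_mode: str = "min"
    rounding: str = "half-up"
    quartile_method: str = "linear"
    fit_models: bool = True
    compute_profiles: bool = False
    age_grid: tuple[float, float, float] = (15.0, 90.0, 1.0)
    vo2max_grid: tuple[float, float, float] = (15.0, 70.0, 1.0)
    n_stages_grid: tuple[float, float, float] = (3.0, 13.0, 1.0)

    def validate(self) -> None:
        if (self.generator is None) == (self.input_path is None):
            raise ConfigError("exactly one of generator / input_path must be set")


@dataclass
class AnchorSummary:
    """Median, quartiles and histogram of present ordinal RPE values."""

    n: int
    median: float | None
    q1: float | None
    q3: float | None
    histogram: dict[int, int]


def summarize_anchor(values, quartile_method: str = "linear") -> AnchorSummary:
    """Summary of a list of ordinal Borg values (6-20).

    Quartiles use linear interpolation between order statistics by
    default (``quartile_method`` accepts any numpy percentile method,
    e.g. ``"inverted_cdf"`` for discrete quartiles).
    """
    values = [int(v) for v in values]
    hist = {level: 0 for level in range(6, 21)}
    for v in values:
        hist[v] += 1
    if not values:
        return AnchorSummary(n=0, median=None, q1=None, q3=None, histogram=hist)
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method=quartile_method)
    return AnchorSummary(n=len(values), median=float(med), q1=float(q1), q3=float(q3), histogram=hist)


def build_model_frame(
    records: list[CPXRecord],
    anchors: dict[str, AnchorRPE],
) -> pd.DataFrame:
    """Covariates plus per-anchor ordinal outcomes, one row per record.

    Missing anchors become NaN and are dropped per-model as complete-case
    exclusions.  Covariate coding: male = 1/0, treadmill = 1/0, age in
    years, VO2max in ml/kg/min, n_stages = completed stage count.
    """
    columns = [
        "participant_id", "male", "treadmill", "age", "vo2max", "n_stages",
        "rpe_2", "rpe_3", "rpe_4", "rpe_lt2",
    ]
    if not records:
        return pd.DataFrame(columns=columns)
    rows = []
    for rec in records:
        a = anchors.get(rec.participant_id)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "male": 1.0 if rec.sex == "male" else 0.0,
                "treadmill": 1.0 if rec.ergometry == "treadmill" else 0.0,
                "age": rec.age,
                "vo2max": rec.vo2max,
                "n_stages": float(rec.n_stages),
                "rpe_2": np.nan if a is None or a.rpe_2 is None else a.rpe_2,
                "rpe_3": np.nan if a is None or a.rpe_3 is None else a.rpe_3,
                "rpe_4": np.nan if a is None or a.rpe_4 is None else a.rpe_4,
                "rpe_lt2": np.nan if a is None or a.rpe_lt2 is None else a.rpe_lt2,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineReport:
    """Everything one run computed, JSON-serialisable via ``to_dict``."""

    exclusions: ExclusionReport
    n_analyzed: int
    n_spline_skipped: int
    n_lt1_missing: int
    mean_lt2_bla: float | None
    anchor_summaries: dict[str, AnchorSummary]
    anchor_missing: dict[str, int]
    or_tables: dict[str, pd.DataFrame | None]
    fit_failures: dict[str, str]
    n_used: dict[str, int]
    covariate_means: dict[str, float]
    crossovers: dict[str, list] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _num(x, nd=6):
            return None if x is None else round(float(x), nd)

        return {
            "metadata": self.metadata,
            "exclusions": {
                "n_input": self.exclusions.n_input,
                "n_kept": self.exclusions.n_kept,
                "counts": dict(self.exclusions.counts),
            },
            "n_analyzed": self.n_analyzed,
            "n_spline_skipped": self.n_spline_skipped,
            "n_lt1_missing": self.n_lt1_missing,
            "mean_lt2_bla": _num(self.mean_lt2_bla),
            "covariate_means": {k: _num(v) for k, v in self.covariate_means.items()},
            "anchors": {
                name: {
                    "n": s.n,
                    "missing": self.anchor_missing.get(name, 0),
                    "median": _num(s.median),
                    "q1": _num(s.q1),
                    "q3": _num(s.q3),
                    "histogram": {str(k): v for k, v in s.histogram.items()},
                }
                for name, s in self.anchor_summaries.items()
            },
            "models": {
                name: (
                    None
                    if table is None
                    else {
                        "n_used": self.n_used.get(name, 0),
                        "odds_ratios": {
                            cov: {
                                "or": _num(row["or"]),
                                "ci_low": _num(row["ci_low"]),
                                "ci_high": _num(row["ci_high"]),
                            }
                            for cov, row in table.iterrows()
                        },
                    }
                )
                for name, table in self.or_tables.items()
            },
            "fit_failures": dict(self.fit_failures),
            "crossovers": self.crossovers,
        }


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _grid(spec) -> np.ndarray:
    lo, hi, step = spec
    return np.arange(lo, hi + step / 2.0, step)


def _profiles_for_fit(cfg: PipelineConfig, fit: OrdinalFit, means: dict[str, float]) -> list:
    """Crossovers of the most-probable RPE along age, VO2max and stage
    count, for each sex x ergometry cell, with the non-varying continuous
    covariates at their cohort means."""
    grids = {
        "age": _grid(cfg.age_grid),
        "vo2max": _grid(cfg.vo2max_grid),
        "n_stages": _grid(cfg.n_stages_grid),
    }
    listings = []
    for vary, grid in grids.items():
        for male in (0.0, 1.0):
            for treadmill in (0.0, 1.0):
                fixed = {
                    "male": male,
                    "treadmill": treadmill,
                    "age": means["age"],
                    "vo2max": means["vo2max"],
                    "n_stages": means["n_stages"],
                }
                fixed.pop(vary)
                profile = find_crossovers(fit, vary, grid, fixed)
                listings.append(
                    {
                        "vary": vary,
                        "male": male,
                        "treadmill": treadmill,
                        "crossovers": [
                            {"at": round(at, 4), "from": int(lo), "to": int(hi)}
                            for at, lo, hi in profile.crossovers
                        ],
                    }
                )
    return listings


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    cfg.validate()

    if cfg.generator is not None:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        cohort, _truth = generate_cohort(gen)
    else:
        cohort = read_cohort(cfg.input_path)

    kept, exclusions = apply_exclusions(cohort, ImplausibilityRules())

    thresholds: dict[str, ThresholdResult] = {}
    anchors: dict[str, AnchorRPE] = {}
    n_spline_skipped = 0
    n_lt1_missing = 0
    lt2_values = []
    for rec in kept:
        th = compute_thresholds(rec, delta=cfg.delta, baseline_mode=cfg.baseline_mode)
        thresholds[rec.participant_id] = th
        if th.lt2_bla is None:
            n_lt1_missing += 1
        else:
            lt2_values.append(th.lt2_bla)
        anchor = anchors_for_record(rec, th, rounding=cfg.rounding)
        if anchor is None:
            n_spline_skipped += 1
            logger.info("record %s skipped: fewer than 3 pairs after the monotone filter",
                        rec.participant_id)
        else:
            anchors[rec.participant_id] = anchor

    frame = build_model_frame(kept, anchors)
    n_analyzed = len(kept)

    summaries: dict[str, AnchorSummary] = {}
    missing_counts: dict[str, int] = {}
    for name in ANCHOR_NAMES:
        col = frame[_ANCHOR_FIELD[name]]
        present = col.dropna().astype(int).tolist()
        summaries[name] = summarize_anchor(present, cfg.quartile_method)
        missing_counts[name] = int(col.isna().sum()) - n_spline_skipped
        # conservation: kept = modelled + skipped-before-splining + missing anchor
        assert n_analyzed == summaries[name].n + n_spline_skipped + missing_counts[name]

    means = {
        "age": float(frame["age"].mean()) if len(frame) else float("nan"),
        "vo2max": float(frame["vo2max"].mean()) if len(frame) else float("nan"),
        "n_stages": float(frame["n_stages"].mean()) if len(frame) else float("nan"),
    }

    or_tables: dict[str, pd.DataFrame | None] = {}
    fit_failures: dict[str, str] = {}
    n_used: dict[str, int] = {}
    crossovers: dict[str, list] = {}
    if cfg.fit_models:
        for name in ANCHOR_NAMES:
            spec = ModelSpec(outcome=_ANCHOR_FIELD[name], covariates=COVARIATES)
            fit = fit_cumulative_logit(spec, frame)
            n_used[name] = fit.n_used
            if fit.converged:
                or_tables[name] = odds_ratio_table(fit)
                if cfg.compute_profiles:
                    crossovers[name] = _profiles_for_fit(cfg, fit, means)
            else:
                or_tables[name] = None
                fit_failures[name] = fit.failure or "unknown failure"
    else:
        for name in ANCHOR_NAMES:
            or_tables[name] = None

    report = PipelineReport(
        exclusions=exclusions,
        n_analyzed=n_analyzed,
        n_spline_skipped=n_spline_skipped,
        n_lt1_missing=n_lt1_missing,
        mean_lt2_bla=float(np.mean(lt2_values)) if lt2_values else None,
        anchor_summaries=summaries,
        anchor_missing=missing_counts,
        or_tables=or_tables,
        fit_failures=fit_failures,
        n_used=n_used,
        covariate_means=means,
        crossovers=crossovers,
        metadata={
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "package_version": __version__,
        },
    )

    if cfg.out_dir is not None:
        _write_outputs(cfg, cohort, kept, thresholds, anchors, report)
    return report


def _write_outputs(cfg, cohort, kept, thresholds, anchors, report):
    os.makedirs(cfg.out_dir, exist_ok=True)
    join = lambda name: os.path.join(cfg.out_dir, name)  # noqa: E731

    write_cohort(cohort, join("cohort.csv"))
    pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "baseline_bla": t.baseline_bla,
                "lt1_stage": t.lt1_stage,
                "lt1_bla": t.lt1_bla,
                "lt2_bla": t.lt2_bla,
                "delta": t.delta,
            }
            for t in thresholds.values()
        ]
    ).to_csv(join("thresholds.csv"), index=False)
    pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "rpe_2": a.rpe_2,
                "rpe_3": a.rpe_3,
                "rpe_4": a.rpe_4,
                "rpe_lt2": a.rpe_lt2,
                "flags": ";".join(f"{k}={v}" for k, v in sorted(a.flags.items())),
            }
            for a in anchors.values()
        ]
    ).to_csv(join("anchors.csv"), index=False)
    for name, table in report.or_tables.items():
        if table is not None:
            table.to_csv(join(f"or_table_{name}.csv"))
    with open(join("report.json"), "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
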