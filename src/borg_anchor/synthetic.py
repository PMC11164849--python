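"""Synthetic CPX cohorts with the statistical structure the pipeline assumes.

The generator emulates an outpatient exercise-testing population: graded
bicycle protocols (start 10-100 W, increments 10-50 W, 3-min stages) and
treadmill protocols (start 3-10 km/h, increments 1-2 km/h), covariate
distributions matching a large mixed clinical cohort (63% male, age
37 ± 17 y, VO2max 31 ± 11 ml/kg/min on the bicycle and 49 ± 7 on the
treadmill), a curvilinear lactate accumulation

    bLa(p) = b0 + A * (exp(k * p) - 1),    p = stage load / maximal load,

with baseline b0 ≈ 1 mmol/l plus floor-clipped Gaussian measurement
noise, and ordinal stage RPE drawn from a latent cumulative-logit model

    P(RPE <= j) = logistic(zeta_j - eta),
    eta = gamma0 + gamma1 * p + x' beta_true,

with the logistic disturbance shared within a test (a perceptual trait),
so the reported sequence is non-decreasing in an incremental test.  The
cutpoints sit at half-integers of the Borg scale, so eta reads directly
as a latent Borg value.  gamma0/gamma1 were calibrated once (see
scripts/calibrate_generator.py) so that the full pipeline reproduces
anchor medians 13/15/16/15 at 2/3/4 mmol/l and LT2 and a mean LT2
concentration near 3 mmol/l, and are frozen here.

A configurable fraction of records carries injected defects (re-tests,
missing values, short tests, implausible values) so the exclusion filters
have something to do.  Ground truth per record is emitted alongside the
cohort and is never consumed by the pipeline.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .cohort_io import CPXRecord, StageMeasurement
from .errors import ConfigError, DomainError

__all__ = [
    "GeneratorConfig",
    "RecordTruth",
    "CohortTruth",
    "ANCHOR_TRUE_ORS",
    "DEFAULT_TRUE_BETAS",
    "default_config",
    "with_true_betas",
    "mean_linear_predictor",
    "generate_cohort",
    "latent_rpe_curve",
    "load_generator_config",
]

# Published per-anchor odds-ratio sets for the five covariates.  The
# 2 mmol/l set is complete; for 4 mmol/l and LT2 only the quoted effects
# are known and the remaining covariates default to OR 1.0.
ANCHOR_TRUE_ORS: dict[str, dict[str, float]] = {
    "2mmol": {"male": 0.65, "treadmill": 0.754, "age": 1.015, "vo2max": 1.023, "n_stages": 1.345},
    "3mmol": {"male": 0.762, "treadmill": 0.851, "age": 1.006, "vo2max": 1.012, "n_stages": 1.290},
    "4mmol": {"male": 1.0, "treadmill": 1.0, "age": 1.0, "vo2max": 1.0, "n_stages": 1.229},
    "lt2": {"male": 1.0, "treadmill": 0.615, "age": 1.0, "vo2max": 1.0, "n_stages": 1.155},
}

DEFAULT_TRUE_BETAS: dict[str, float] = {
    name: math.log(odds) for name, odds in ANCHOR_TRUE_ORS["2mmol"].items()
}

_BASE_DATE = dt.date(2015, 1, 1)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator; defaults are the frozen study
    conditions (covariate distributions of the emulated clinical cohort,
    calibrated latent-RPE curve, 3-min stages)."""

    n: int = 2000
    seed: int = 0

    # cohort composition
    p_male: float = 0.626
    p_bicycle: float = 0.582
    age_mean: float = 36.65
    age_sd: float = 16.68
    age_min: float = 10.0
    age_max: float = 95.0
    vo2max_mean_bicycle: float = 31.40
    vo2max_sd_bicycle: float = 10.76
    vo2max_mean_treadmill: float = 48.72
    vo2max_sd_treadmill: float = 6.99
    vo2max_min: float = 12.0
    vo2max_max: float = 75.0
    height_mean_male: float = 179.42
    height_sd_male: float = 10.62
    height_mean_female: float = 167.26
    height_sd_female: float = 8.25
    weight_mean_male: float = 79.52
    weight_sd_male: float = 16.61
    weight_mean_female: float = 64.54
    weight_sd_female: float = 13.02

    # lactate curve bLa(p) = b0 + A (exp(k p) - 1)
    bla_baseline_mean: float = 1.0
    bla_baseline_sd: float = 0.10
    bla_curve_amp: float = 0.02
    bla_curve_amp_cv: float = 0.10
    bla_curve_rate: float = 6.0
    bla_curve_rate_cv: float = 0.03
    bla_noise_sd: float = 0.08
    bla_floor: float = 0.3

    # latent RPE model (cutpoints at Borg half-integers)
    gamma0: float = -1.504
    gamma1: float = 17.0
    true_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    true_cutpoints: tuple[float, ...] = tuple(j + 0.5 for j in range(6, 20))

    # protocol
    stage_duration_min: float = 3.0
    bicycle_start_min: float = 10.0
    bicycle_start_max: float = 100.0
    bicycle_inc_min: float = 10.0
    bicycle_inc_max: float = 50.0
    treadmill_start_min: float = 3.0
    treadmill_start_max: float = 10.0
    target_stages_min: int = 6
    target_stages_max: int = 11
    max_stages: int = 14
    n_stages_nominal: float = 9.0  # used only for latent recentering

    # defect injection (exercises the exclusion filters)
    retest_rate: float = 0.05
    missing_bla_rate: float = 0.01
    missing_rpe_rate: float = 0.01
    short_test_rate: float = 0.005
    implausible_rate: float = 0.002
    other_ergometry_rate: float = 0.0

    # LT1 rule used for the emitted ground truth
    lt1_delta: float = 0.2

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        for name in ("p_male", "p_bicycle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "age_sd", "vo2max_sd_bicycle", "vo2max_sd_treadmill",
            "height_sd_male", "height_sd_female", "weight_sd_male", "weight_sd_female",
            "bla_baseline_sd", "bla_curve_amp_cv", "bla_curve_rate_cv", "bla_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "retest_rate", "missing_bla_rate", "missing_rpe_rate",
            "short_test_rate", "implausible_rate", "other_ergometry_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.stage_duration_min != 3.0:
            raise ConfigError("stage_duration_min is fixed at 3 minutes")
        cuts = np.asarray(self.true_cutpoints)
        if len(cuts) < 1 or np.any(np.diff(cuts) <= 0):
            raise ConfigError("true_cutpoints must be strictly increasing")
        unknown = set(self.true_betas) - {"male", "treadmill", "age", "vo2max", "n_stages"}
        if unknown:
            raise ConfigError(f"true_betas has unknown covariate(s): {sorted(unknown)}")
        if self.bla_curve_amp <= 0 or self.bla_curve_rate <= 0:
            raise ConfigError("bla_curve_amp and bla_curve_rate must be > 0")


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def mean_linear_predictor(cfg: GeneratorConfig, betas: dict[str, float]) -> float:
    """Population-mean x'beta under the config's covariate distribution
    (nominal stage count; pre-truncation means — used for recentering)."""
    mean_vo2 = (
        cfg.p_bicycle * cfg.vo2max_mean_bicycle
        + (1.0 - cfg.p_bicycle) * cfg.vo2max_mean_treadmill
    )
    return (
        betas.get("male", 0.0) * cfg.p_male
        + betas.get("treadmill", 0.0) * (1.0 - cfg.p_bicycle)
        + betas.get("age", 0.0) * cfg.age_mean
        + betas.get("vo2max", 0.0) * mean_vo2
        + betas.get("n_stages", 0.0) * cfg.n_stages_nominal
    )


def with_true_betas(
    cfg: GeneratorConfig, betas: dict[str, float], recenter: bool = True
) -> GeneratorConfig:
    """Config with replaced latent coefficients.

    With ``recenter`` (default) gamma0 is shifted so the population-mean
    latent exertion is unchanged; the calibrated anchor medians then stay
    roughly in place when covariate effects are swapped.
    """
    new = dict(betas)
    gamma0 = cfg.gamma0
    if recenter:
        gamma0 += mean_linear_predictor(cfg, cfg.true_betas) - mean_linear_predictor(cfg, new)
    out = replace(cfg, true_betas=new, gamma0=gamma0)
    out.validate()
    return out


@dataclass
class RecordTruth:
    """Ground truth for one generated record (never read by the pipeline)."""

    participant_id: str
    test_date: dt.date
    b0: float
    amp: float
    rate: float
    eta_intercept: float  # gamma0 + x' beta_true
    eta_slope: float  # gamma1
    latent_trait: float  # the record's shared logistic disturbance
    n_stages: int
    lt1_stage: int | None
    lt1_bla: float | None
    lt2_bla: float | None
    defect: str | None


@dataclass
class CohortTruth:
    """Per-record truths plus the latent parameters actually used."""

    records: list[RecordTruth]
    true_betas: dict[str, float]
    true_cutpoints: tuple[float, ...]
    gamma0: float
    gamma1: float
    lt1_delta: float

    def to_json(self, path) -> None:
        payload = {
            "true_betas": self.true_betas,
            "true_cutpoints": list(self.true_cutpoints),
            "gamma0": self.gamma0,
            "gamma1": self.gamma1,
            "lt1_delta": self.lt1_delta,
            "records": [
                {**asdict(r), "test_date": r.test_date.isoformat()} for r in self.records
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def latent_rpe_curve(record_truth: RecordTruth, p: float) -> float:
    """Latent exertion (Borg-scale units) at relative intensity p in [0, 1];
    strictly increasing in p."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"relative intensity must lie in [0, 1], got {p}")
    return record_truth.eta_intercept + record_truth.eta_slope * p


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0.0:
        return min(max(mean, lo), hi)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return min(max(mean, lo), hi)


def _round_to(value, step):
    return round(value / step) * step


def _protocol(rng, cfg: GeneratorConfig, ergometry, weight, vo2max):
    """Sampled graded protocol: load grid and maximal capacity.

    Maximal load is an affine function of VO2max and body mass with the
    standard steady-state cost constants (cycling: ~11 W per ml/kg/min
    above the 7 ml/kg/min unloaded cost, scaled by mass; running: 0.2
    ml/kg/min per m/min above rest), jittered by ~5%.  The capacity is
    snapped onto the protocol's load grid so exhaustion falls on the last
    stage.
    """
    n_target = int(rng.integers(cfg.target_stages_min, cfg.target_stages_max + 1))
    jitter = math.exp(rng.normal(0.0, 0.05))
    if ergometry == "bicycle":
        capacity = max(weight * (vo2max - 7.0) / 11.0 * jitter, 60.0)  # watts
        start = min(
            max(_round_to(0.2 * capacity, 10.0), cfg.bicycle_start_min),
            cfg.bicycle_start_max,
        )
        inc = min(
            max(_round_to((capacity - start) / max(n_target - 1, 1), 5.0), cfg.bicycle_inc_min),
            cfg.bicycle_inc_max,
        )
    else:
        capacity = max(0.3 * (vo2max - 3.5) * jitter, 6.0)  # km/h
        start = min(
            max(round(0.3 * capacity), cfg.treadmill_start_min), cfg.treadmill_start_max
        )
        inc = 1.0 if (capacity - start) / max(n_target - 1, 1) < 1.5 else 2.0
    n_stages = int((capacity - start) // inc) + 1
    n_stages = min(max(n_stages, 3), cfg.max_stages)
    loads = start + inc * np.arange(n_stages)
    return loads, float(loads[-1])


def _sample_stage_rpe(rng, eta: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """Ordinal Borg draws along one test's stages.

    The logistic disturbance is drawn once per record and shared across
    its stages — a persistent within-test perceptual trait.  Each stage's
    marginal distribution is then exactly the cumulative-logit model at
    that stage's latent exertion, and because the latent exertion rises
    strictly with intensity the reported RPE sequence is non-decreasing
    by construction (no post-hoc monotonisation that would distort the
    margins differently for dense and sparse protocols).
    """
    trait = float(rng.logistic(loc=0.0, scale=1.0))
    u = eta + trait
    return 6 + (u[:, None] > cutpoints[None, :]).sum(axis=1), trait


def _true_thresholds(bla_true, b0, delta):
    """Noise-free LT1/LT2 on the stage grid (curve is monotone, so the
    first rise is automatically sustained)."""
    for i, value in enumerate(bla_true):
        if value > b0 + delta:
            return i + 1, float(value), float(value) + 1.5
    return None, None, None


def generate_cohort(config: GeneratorConfig) -> tuple[list[CPXRecord], CohortTruth]:
    """Generate ``config.n`` records plus ground truth, deterministically
    in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cutpoints = np.asarray(config.true_cutpoints, dtype=float)
    betas = config.true_betas

    cohort: list[CPXRecord] = []
    truths: list[RecordTruth] = []

    defect_edges = np.cumsum(
        [
            config.retest_rate,
            config.missing_bla_rate,
            config.missing_rpe_rate,
            config.short_test_rate,
            config.implausible_rate,
            config.other_ergometry_rate,
        ]
    )
    defect_names = ("retest", "missing_bla", "missing_rpe", "short", "implausible", "other_ergometry")

    for i in range(config.n):
        male = rng.random() < config.p_male
        ergometry = "bicycle" if rng.random() < config.p_bicycle else "treadmill"
        age = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_min, config.age_max)
        if male:
            height = _truncated_normal(rng, config.height_mean_male, config.height_sd_male, 140.0, 215.0)
            weight = _truncated_normal(rng, config.weight_mean_male, config.weight_sd_male, 35.0, 160.0)
        else:
            height = _truncated_normal(rng, config.height_mean_female, config.height_sd_female, 135.0, 205.0)
            weight = _truncated_normal(rng, config.weight_mean_female, config.weight_sd_female, 30.0, 150.0)
        if ergometry == "bicycle":
            vo2max = _truncated_normal(
                rng, config.vo2max_mean_bicycle, config.vo2max_sd_bicycle,
                config.vo2max_min, config.vo2max_max,
            )
        else:
            vo2max = _truncated_normal(
                rng, config.vo2max_mean_treadmill, config.vo2max_sd_treadmill,
                config.vo2max_min, config.vo2max_max,
            )

        loads, capacity = _protocol(rng, config, ergometry, weight, vo2max)
        n_stages = len(loads)
        p = loads / capacity

        b0 = _truncated_normal(rng, config.bla_baseline_mean, config.bla_baseline_sd, 0.4, 2.5)
        amp = config.bla_curve_amp * math.exp(rng.normal(0.0, config.bla_curve_amp_cv))
        rate = config.bla_curve_rate * math.exp(rng.normal(0.0, config.bla_curve_rate_cv))
        bla_true = b0 + amp * (np.exp(rate * p) - 1.0)
        bla_obs = np.maximum(
            bla_true + rng.normal(0.0, config.bla_noise_sd, n_stages), config.bla_floor
        )
        resting = max(b0 + rng.normal(0.0, config.bla_noise_sd), config.bla_floor)

        xbeta = (
            betas.get("male", 0.0) * male
            + betas.get("treadmill", 0.0) * (ergometry == "treadmill")
            + betas.get("age", 0.0) * age
            + betas.get("vo2max", 0.0) * vo2max
            + betas.get("n_stages", 0.0) * n_stages
        )
        eta = config.gamma0 + config.gamma1 * p + xbeta
        rpe_draw, trait = _sample_stage_rpe(rng, eta, cutpoints)
        rpe = np.maximum.accumulate(rpe_draw)

        test_date = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 2900)))
        participant_id = f"P{i:06d}"

        defect_draw = rng.random()
        defect = None
        for name, edge in zip(defect_names, defect_edges):
            if defect_draw < edge:
                defect = name
                break

        stages = [
            StageMeasurement(
                stage_index=j + 1,
                load=float(loads[j]),
                duration_min=config.stage_duration_min,
                bla=float(bla_obs[j]),
                rpe=int(rpe[j]),
            )
            for j in range(n_stages)
        ]
        record = CPXRecord(
            participant_id=participant_id,
            test_date=test_date,
            age=round(age, 2),
            sex="male" if male else "female",
            ergometry=ergometry,
            height_cm=round(height, 1),
            weight_kg=round(weight, 1),
            vo2max=round(vo2max, 2),
            resting_bla=round(resting, 3),
            stages=[
                replace(st, bla=round(st.bla, 3)) for st in stages
            ],
        )

        if defect == "retest":
            if cohort:
                prev = cohort[-1]
                record.participant_id = prev.participant_id
                record.test_date = prev.test_date + dt.timedelta(days=int(rng.integers(30, 365)))
            else:
                defect = None  # no earlier participant to duplicate
        elif defect == "missing_bla":
            j = int(rng.integers(0, n_stages))
            record.stages[j] = replace(record.stages[j], bla=None)
        elif defect == "missing_rpe":
            j = int(rng.integers(0, n_stages))
            record.stages[j] = replace(record.stages[j], rpe=None)
        elif defect == "short":
            record.stages = record.stages[:2]
        elif defect == "implausible":
            j = int(rng.integers(0, n_stages))
            record.stages[j] = replace(record.stages[j], bla=30.0)
        elif defect == "other_ergometry":
            record.ergometry = "handcycle"

        # truth thresholds are computed on the recorded precision (3 decimals)
        # so that at zero noise the pipeline's detection reproduces them exactly
        lt1_stage, lt1_bla, lt2_bla = _true_thresholds(
            np.round(bla_true, 3), round(b0, 3), config.lt1_delta
        )
        truths.append(
            RecordTruth(
                participant_id=record.participant_id,
                test_date=record.test_date,
                b0=b0,
                amp=amp,
                rate=rate,
                eta_intercept=config.gamma0 + xbeta,
                eta_slope=config.gamma1,
                latent_trait=trait,
                n_stages=n_stages,
                lt1_stage=lt1_stage,
                lt1_bla=lt1_bla,
                lt2_bla=lt2_bla,
                defect=defect,
            )
        )
        cohort.append(record)

    truth = CohortTruth(
        records=truths,
        true_betas=dict(betas),
        true_cutpoints=tuple(config.true_cutpoints),
        gamma0=config.gamma0,
        gamma1=config.gamma1,
        lt1_delta=config.lt1_delta,
    )
    return cohort, truth


def load_generator_config(path, **overrides) -> GeneratorConfig:
    """Load a GeneratorConfig from a JSON or YAML file; keyword overrides
    (e.g. a CLI --seed) win over file values."""
    text = open(path, encoding="utf-8").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError("config file must hold a mapping")
    unknown = set(data) - set(GeneratorConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    data.update(overrides)
    if "true_cutpoints" in data:
        data["true_cutpoints"] = tuple(data["true_cutpoints"])
    cfg = GeneratorConfig(**data)
    cfg.validate()
    return cfg
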