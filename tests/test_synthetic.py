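"""Generator determinism, calibration structure and latent-model margins."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from borg_anchor.cohort_io import write_cohort
from borg_anchor.errors import ConfigError, DomainError
from borg_anchor.synthetic import (
    ANCHOR_TRUE_ORS,
    RecordTruth,
    default_config,
    generate_cohort,
    latent_rpe_curve,
    mean_linear_predictor,
    with_true_betas,
)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("p_male", 1.2),
            ("n", -1),
            ("bla_noise_sd", -0.1),
            ("retest_rate", 1.5),
            ("stage_duration_min", 2.0),
            ("true_cutpoints", (7.5, 7.5, 8.5)),
        ],
    )
    def test_invalid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            default_config(**{field: value})

    def test_unknown_beta_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown covariate"):
            default_config(true_betas={"speed": 0.2})


class TestGeneration:
    def test_empty_cohort_for_n_zero(self):
        cohort, truth = generate_cohort(default_config(n=0, seed=3))
        assert cohort == [] and truth.records == []

    def test_seeded_runs_are_byte_identical(self, tmp_path):
        cfg = default_config(n=150, seed=17)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(a, pa)
        write_cohort(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(default_config(n=50, seed=1))
        b, _ = generate_cohort(default_config(n=50, seed=2))
        assert a != b

    def test_male_fraction_near_population_share(self):
        cohort, _ = generate_cohort(default_config(n=6311, seed=1))
        frac = sum(r.sex == "male" for r in cohort) / len(cohort)
        assert abs(frac - 0.626) < 0.02

    def test_covariate_moments_match_sampling_distributions(self):
        """Empirical moments at n=10^4 within 3 Monte-Carlo SEs of the
        (truncated-normal) sampling distributions the config defines."""
        cfg = default_config(n=10_000, seed=8)
        cohort, _ = generate_cohort(cfg)
        n = len(cohort)

        p_bike = sum(r.ergometry == "bicycle" for r in cohort) / n
        se = math.sqrt(cfg.p_bicycle * (1 - cfg.p_bicycle) / n)
        assert abs(p_bike - cfg.p_bicycle) < 3 * se

        a, b = (cfg.age_min - cfg.age_mean) / cfg.age_sd, (cfg.age_max - cfg.age_mean) / cfg.age_sd
        dist = stats.truncnorm(a, b, loc=cfg.age_mean, scale=cfg.age_sd)
        ages = np.array([r.age for r in cohort])
        assert abs(ages.mean() - dist.mean()) < 3 * dist.std() / math.sqrt(n)

        for erg, mean, sd in (
            ("bicycle", cfg.vo2max_mean_bicycle, cfg.vo2max_sd_bicycle),
            ("treadmill", cfg.vo2max_mean_treadmill, cfg.vo2max_sd_treadmill),
        ):
            vals = np.array([r.vo2max for r in cohort if r.ergometry == erg])
            a, b = (cfg.vo2max_min - mean) / sd, (cfg.vo2max_max - mean) / sd
            dist = stats.truncnorm(a, b, loc=mean, scale=sd)
            assert abs(vals.mean() - dist.mean()) < 3 * dist.std() / math.sqrt(len(vals))

    def test_protocol_shapes(self, small_cohort):
        cohort, _ = small_cohort
        for rec in cohort:
            if rec.n_stages < 3:
                continue  # injected short-test defect
            loads = [st.load for st in rec.stages]
            assert all(b > a for a, b in zip(loads, loads[1:]))
            assert 3 <= rec.n_stages <= 14
            assert all(st.duration_min == 3.0 for st in rec.stages)

    def test_stage_rpe_non_decreasing_and_in_range(self, small_cohort):
        cohort, _ = small_cohort
        for rec in cohort:
            rpes = [st.rpe for st in rec.stages if st.rpe is not None]
            assert all(6 <= r <= 20 for r in rpes)
            assert all(b >= a for a, b in zip(rpes, rpes[1:]))

    def test_defect_rates_injected(self):
        cfg = default_config(n=2000, seed=9, other_ergometry_rate=0.01)
        _, truth = generate_cohort(cfg)
        kinds = [t.defect for t in truth.records if t.defect]
        assert {"retest", "missing_bla", "missing_rpe", "short"} <= set(kinds)


class TestLatentCurve:
    def _truth(self, **kw):
        base = dict(
            participant_id="T", test_date=None, b0=1.0, amp=0.02, rate=6.0,
            eta_intercept=2.4, eta_slope=16.4, latent_trait=0.0, n_stages=9,
            lt1_stage=3, lt1_bla=1.4, lt2_bla=2.9, defect=None,
        )
        base.update(kw)
        return RecordTruth(**base)

    def test_strictly_increasing_in_relative_intensity(self):
        t = self._truth()
        grid = np.linspace(0.0, 1.0, 21)
        vals = [latent_rpe_curve(t, p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_rest_lies_below_the_cutpoint_for_rpe_8(self):
        cfg = default_config()
        eta0 = cfg.gamma0 + mean_linear_predictor(cfg, cfg.true_betas)
        t = self._truth(eta_intercept=eta0, eta_slope=cfg.gamma1)
        assert latent_rpe_curve(t, 0.0) < cfg.true_cutpoints[2]  # boundary above RPE 8

    def test_exhaustion_implies_most_probable_rpe_at_least_18(self):
        cfg = default_config()
        eta0 = cfg.gamma0 + mean_linear_predictor(cfg, cfg.true_betas)
        t = self._truth(eta_intercept=eta0, eta_slope=cfg.gamma1)
        top = latent_rpe_curve(t, 1.0)
        # most-probable category for latent value v is round(v) under
        # half-integer cutpoints
        assert top >= 17.5

    def test_sex_difference_is_exactly_the_sex_coefficient(self):
        cfg = default_config()
        beta_male = cfg.true_betas["male"]
        female = self._truth(eta_intercept=2.4)
        male = self._truth(eta_intercept=2.4 + beta_male)
        for p in (0.1, 0.5, 0.9):
            diff = latent_rpe_curve(male, p) - latent_rpe_curve(female, p)
            assert diff == pytest.approx(beta_male)

    def test_intensity_outside_unit_interval_rejected(self):
        t = self._truth()
        with pytest.raises(DomainError):
            latent_rpe_curve(t, -0.01)
        with pytest.raises(DomainError):
            latent_rpe_curve(t, 1.01)


class TestLatentSampler:
    def test_stage_margins_match_cumulative_logit_probabilities(self):
        """Chi-square goodness of fit of single-stage draws (independent
        across records) against the model's category probabilities."""
        from scipy.special import expit

        from borg_anchor.synthetic import _sample_stage_rpe

        rng = np.random.default_rng(4)
        cfg = default_config()
        cuts = np.asarray(cfg.true_cutpoints)
        eta = 13.2
        draws = np.array(
            [_sample_stage_rpe(rng, np.array([eta]), cuts)[0][0] for _ in range(10_000)]
        )
        z = np.concatenate(([-np.inf], cuts - eta, [np.inf]))
        probs = np.diff(expit(z))
        observed = np.bincount(draws - 6, minlength=15)
        mask = probs * len(draws) >= 5
        stat, p = stats.chisquare(
            observed[mask], probs[mask] / probs[mask].sum() * observed[mask].sum()
        )
        assert p > 0.01

    def test_recentering_preserves_mean_latent_exertion(self):
        cfg = default_config()
        new = with_true_betas(cfg, {k: math.log(v) for k, v in ANCHOR_TRUE_ORS["lt2"].items()})
        before = cfg.gamma0 + mean_linear_predictor(cfg, cfg.true_betas)
        after = new.gamma0 + mean_linear_predictor(new, new.true_betas)
        assert after == pytest.approx(before)
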