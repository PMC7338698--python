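import dataclasses

import numpy as np
import pandas as pd
import pytest

from sdtmem.data import aggregate_counts, validate_trials
from sdtmem.models import DPSDParams, UVSDParams, category_probs
from sdtmem.synthetic import (
    ConstraintError,
    DesignSpec,
    EncodingSpec,
    default_cohort,
    experiment_designs,
    generate_experiment,
    per_million_to_zipf,
    sample_constrained_durations,
    sample_strengths,
    sample_zipf,
    schedule_digits,
    simulate_experiment,
    strengths_to_ratings,
    zipf_to_per_million,
)

CRIT = (-1.0, -0.3, 0.3, 1.0, 1.8)


class TestSampleStrengths:
    @pytest.mark.parametrize(
        "rho,sigma_b,sigma_y",
        [(0.0, 1.0, 0.8), (-1.0, 1.0, 1.0), (0.5, 1.0, 0.8)],
        ids=["independent", "perfect-negative", "positive"],
    )
    def test_variance_identity(self, rho, sigma_b, sigma_y):
        # Var(old) = sigma_B^2 + sigma_Y^2 + 2 rho sigma_Y sigma_B
        spec = EncodingSpec(0.0, sigma_b, 1.0, sigma_y, rho)
        old, new = sample_strengths(spec, 10**6, 10**5, seed=9)
        expected = sigma_b**2 + sigma_y**2 + 2 * rho * sigma_y * sigma_b
        assert old.var(ddof=1) == pytest.approx(expected, abs=0.02)
        assert new.var(ddof=1) == pytest.approx(sigma_b**2, abs=0.02)

    def test_correlation_between_components_respected(self):
        spec = EncodingSpec(0.0, 1.0, 1.0, 0.8, 0.5)
        # with rho > 0 total variance exceeds the independent sum
        old, _ = sample_strengths(spec, 10**6, 10, seed=1)
        assert old.var() > 1.0 + 0.64 + 0.2

    def test_added_variance_strictly_increases_old_variance(self):
        variances = []
        for sigma_y in (0.0, 0.4, 0.8, 1.2):
            spec = EncodingSpec(0.0, 1.0, 1.0, sigma_y, 0.0)
            old, _ = sample_strengths(spec, 2 * 10**5, 10, seed=13)
            variances.append(old.var(ddof=1))
        assert all(a < b for a, b in zip(variances, variances[1:]))

    def test_reproducible_given_seed(self):
        a = sample_strengths(UVSDParams(1.0, 1.5, CRIT), 100, 100, seed=5)
        b = sample_strengths(UVSDParams(1.0, 1.5, CRIT), 100, 100, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestStrengthsToRatings:
    def test_boundary_assignment(self):
        trials = strengths_to_ratings([-5.0, -1.0, 0.0, 2.5], [0.5], CRIT)
        old = trials[trials.status == "old"]["rating"].tolist()
        assert old == [1, 1, 3, 6]  # strength == c1 falls in category 1

    def test_certain_recollection_rates_six(self):
        trials = strengths_to_ratings(
            np.full(50, -3.0), np.full(10, -3.0), CRIT, dpsd_R=1.0, seed=0
        )
        assert (trials[trials.status == "old"]["rating"] == 6).all()
        assert (trials[trials.status == "new"]["rating"] == 1).all()

    def test_large_n_frequencies_match_category_probs(self, dpsd_params):
        old, new = sample_strengths(dpsd_params, 10**6, 10**6, seed=2)
        trials = strengths_to_ratings(
            old, new, dpsd_params.criteria, dpsd_R=dpsd_params.R, seed=3
        )
        counts = aggregate_counts(trials)
        probs = category_probs(dpsd_params)
        emp = np.asarray(counts.n_old) / 10**6
        se = np.sqrt(probs.p_old * (1 - probs.p_old) / 10**6)
        assert (np.abs(emp - probs.p_old) < 3 * se + 1e-9).all()


class TestConstrainedDurations:
    def test_study_duration_schedule_meets_all_constraints(self):
        spec = experiment_designs(1)["variable"]
        x = sample_constrained_durations(spec, 130, seed=6)
        assert x.sum() == pytest.approx(3000.0 * 130, abs=1e-6)  # 390 s total
        assert x.min() >= 500.0 and x.max() <= 5500.0
        from scipy.stats import kstest
        from statsmodels.stats.diagnostic import normal_ad

        assert kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue > 0.05
        assert normal_ad(x)[1] > 0.05

    def test_distractor_interval_schedule_sums_to_455s(self):
        spec = experiment_designs(2)["variable"]
        x = sample_constrained_durations(spec, 130, seed=6)
        assert x.sum() == pytest.approx(3500.0 * 130, abs=1e-6)
        assert x.min() >= 1000.0 and x.max() <= 6000.0

    def test_degenerate_sd_zero(self):
        spec = DesignSpec(
            covariate="duration", duration_mean_ms=3000.0, duration_sd_ms=0.0,
            duration_lo_ms=500.0, duration_hi_ms=5500.0, sum_target_ms=390000.0,
        )
        with pytest.warns(UserWarning, match="sd=0"):
            x = sample_constrained_durations(spec, 130, seed=0)
        assert (x == 3000.0).all()

    def test_infeasible_sum_errors(self):
        spec = DesignSpec(
            covariate="duration", duration_mean_ms=3000.0, duration_sd_ms=1100.0,
            duration_lo_ms=500.0, duration_hi_ms=5500.0, sum_target_ms=10**9,
        )
        with pytest.raises(ConstraintError):
            sample_constrained_durations(spec, 130, seed=0)

    def test_bit_reproducible(self):
        spec = experiment_designs(1)["variable"]
        a = sample_constrained_durations(spec, 130, seed=42)
        b = sample_constrained_durations(spec, 130, seed=42)
        np.testing.assert_array_equal(a, b)


class TestScheduleDigits:
    def test_synchronized_fixed_condition_one_per_trial(self):
        counts = schedule_digits(np.full(130, 3500.0), 3500.0, 130)
        assert (counts == 1).all()

    def test_total_digits_conserved(self):
        intervals = sample_constrained_durations(
            experiment_designs(2)["variable"], 130, seed=3
        )
        counts = schedule_digits(intervals, 3500.0, 130)
        assert counts.sum() == 130  # sum constraint keeps all onsets in session

    def test_variable_intervals_spread_over_0_to_3(self):
        intervals = sample_constrained_durations(
            experiment_designs(2)["variable"], 130, seed=3
        )
        counts = schedule_digits(intervals, 3500.0, 130)
        assert counts.min() == 0 and counts.max() >= 2

    def test_onsets_beyond_session_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            counts = schedule_digits([1000.0, 1000.0, 5000.0], 1000.0, 2)
        assert counts.sum() == 2


class TestSampleZipf:
    def test_low_variance_condition(self):
        spec = experiment_designs(3)["low_variance"]
        z = sample_zipf(spec, 100, seed=8)
        assert z.min() >= 3.41 and z.max() <= 3.59
        assert z.mean() == pytest.approx(3.48, abs=0.02)

    def test_high_variance_condition(self):
        spec = experiment_designs(3)["high_variance"]
        z = sample_zipf(spec, 100, seed=8)
        assert z.min() >= 1.17 and z.max() <= 5.84
        assert z.std(ddof=1) == pytest.approx(1.0, abs=0.1)
        assert z.mean() == pytest.approx(3.5, abs=0.3)

    def test_zipf_conversion_round_trip(self):
        assert zipf_to_per_million(3.48) == pytest.approx(3.0, abs=0.03)
        assert per_million_to_zipf(1.0) == pytest.approx(3.0)
        assert per_million_to_zipf(zipf_to_per_million(4.2)) == pytest.approx(4.2)


class TestGenerateExperiment:
    def test_output_passes_validation_and_counts(self):
        trials = simulate_experiment(1, "uvsd", n_participants=3, seed=0)
        validate_trials(trials)
        assert set(trials["condition"]) == {"fixed", "variable"}
        assert len(trials) == 3 * 2 * 260
        old = trials[trials.status == "old"]
        assert old["duration_ms"].notna().all()

    def test_exp3_zipf_for_both_classes(self):
        trials = simulate_experiment(3, "uvsd", n_participants=2, seed=1)
        assert trials["zipf"].notna().all()
        low = trials[trials.condition == "low_variance"]["zipf"]
        assert low.between(3.41, 3.59).all()

    def test_evsd_limit_recovers_unit_sigma(self):
        # no added-strength variance -> UVSD fits should find sigma_o ~ 1
        from sdtmem.fitting import fit_model

        cohort = default_cohort("UVSD", 6)
        designs = {"only": DesignSpec(n_old=2000, n_new=2000)}
        trials = generate_experiment(
            cohort, designs, generator=EncodingSpec(mu_added=1.2, sigma_added=0.0),
            seed=5,
        )
        sigmas = []
        for p in trials["participant"].unique():
            counts = aggregate_counts(trials, p, "only")
            sigmas.append(fit_model(counts, "UVSD", n_starts=3, seed=0).params.sigma_o)
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.1)

    def test_null_link_gives_zero_mean_correlation(self):
        from scipy.stats import pearsonr

        designs = {
            "variable": dataclasses.replace(
                experiment_designs(1)["variable"], link=None
            )
        }
        trials = generate_experiment(default_cohort("UVSD", 30), designs, seed=2)
        rs = [
            pearsonr(g["duration_ms"], g["rating"])[0]
            for _, g in trials[trials.status == "old"].groupby("participant")
        ]
        # participants whose ratings saturate have undefined r; drop them
        assert np.nanmean(rs) == pytest.approx(0.0, abs=0.025)

    def test_duration_link_calibrated_to_weak_positive_correlation(self):
        from scipy.stats import pearsonr

        trials = simulate_experiment(1, "uvsd", n_participants=40, seed=3)
        old = trials[(trials.status == "old") & (trials.condition == "variable")]
        rs = [
            pearsonr(g["duration_ms"], g["rating"])[0]
            for _, g in old.groupby("participant")
        ]
        assert np.mean(rs) == pytest.approx(0.05, abs=0.03)

    def test_zipf_link_calibrated_to_weak_negative_correlation(self):
        from scipy.stats import pearsonr

        trials = simulate_experiment(3, "uvsd", n_participants=40, seed=3)
        old = trials[(trials.status == "old") & (trials.condition == "high_variance")]
        rs = [
            pearsonr(g["zipf"], g["rating"])[0] for _, g in old.groupby("participant")
        ]
        assert np.mean(rs) == pytest.approx(-0.10, abs=0.04)

    def test_bit_reproducible(self):
        a = simulate_experiment(2, "dpsd", n_participants=2, seed=11)
        b = simulate_experiment(2, "dpsd", n_participants=2, seed=11)
        pd.testing.assert_frame_equal(a, b)
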