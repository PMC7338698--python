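import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sdtmem.stats import (
    anova_2x2_within,
    analysis_pipeline,
    jzs_bf_paired,
    paired_t,
    pearson_r,
    wilcoxon_signed_rank,
)


class TestPairedT:
    def test_identical_inputs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x + 0.0 * x + np.array([0.1, -0.1, 0.1, -0.1]), bayes=False)
        assert abs(res.statistic) < 2.0  # sanity: small t for tiny noise

    def test_equal_vectors_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(x, x, bayes=False)

    def test_hand_computed_oracle(self):
        # differences (1, 2, 3): t = mean/SE = 2 / (1/sqrt(3)) = 3.464...
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], bayes=False)
        assert res.statistic == pytest.approx(2.0 * math.sqrt(3.0), abs=1e-12)
        assert res.df == 2
        assert res.effect_size == pytest.approx(2.0, abs=1e-12)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = paired_t(x, y, bayes=False)
        b = paired_t(y, x, bayes=False)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_ci_brackets_mean_difference(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1.0, 1.0, 20), rng.normal(0.0, 1.0, 20)
        res = paired_t(x, y, bayes=False)
        assert res.ci_low < res.mean_diff < res.ci_high

    def test_type_one_error_rate_near_nominal(self):
        # 2,000 null simulations at n = 40: rejection rate in [0.03, 0.07]
        rng = np.random.default_rng(101)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            d = rng.normal(size=40)
            if paired_t(d, np.zeros(40), bayes=False).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestWilcoxon:
    def test_all_positive_differences_max_v(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res.statistic == 15  # sum of ranks 1..5

    def test_symmetric_differences_large_p(self):
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0, 3.0, -3.0], np.zeros(6))
        assert res.p_value > 0.9

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_exact_p_against_sign_flip_enumeration(self):
        # n = 8 distinct differences: enumerate all 2^8 sign assignments
        diffs = np.array([0.5, -1.2, 2.1, 0.9, -0.3, 1.7, 2.8, -2.4])
        res = wilcoxon_signed_rank(diffs, np.zeros(8))
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        v_obs = ranks[diffs > 0].sum()
        total = ranks.sum()
        vs = []
        for signs in itertools.product([0, 1], repeat=8):
            vs.append(sum(r for r, s in zip(ranks, signs) if s))
        vs = np.array(vs)
        p_exact = min(
            1.0,
            2.0 * min((vs <= v_obs).mean(), (vs >= v_obs).mean()),
        )
        assert res.statistic == v_obs
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_agrees_in_sign_with_t_on_monotone_fixture(self):
        x = np.array([1.1, 2.3, 3.1, 4.4, 5.2, 6.8, 7.1, 8.9])
        y = x - np.abs(np.sin(x)) - 0.1
        t_res = paired_t(x, y, bayes=False)
        w_res = wilcoxon_signed_rank(x, y)
        assert t_res.statistic > 0
        assert w_res.statistic > len(x) * (len(x) + 1) / 4  # above null mean


class TestPearson:
    def test_perfect_linear(self):
        res = pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_fixture(self):
        res = pearson_r([-1, 1, -1, 1, -1, 1], [1, 1, -1, -1, 1, 1][:6])
        assert abs(res.r) < 0.5  # constructed near-zero

    def test_exactly_zero_constructed(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x**2  # even function: cov = 0
        res = pearson_r(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_covariance_formula_oracle(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_r(x, y)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r == pytest.approx(manual, abs=1e-12)
        assert res.df == 28
        assert res.ci_low < res.r < res.ci_high

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnova2x2Within:
    def test_identical_cells_all_f_zero(self):
        data = np.ones((8, 2, 2))
        table = anova_2x2_within(data)
        assert (table["F"] == 0).all()

    def test_additive_noiseless_interaction_zero(self):
        n = 10
        a = np.array([0.0, 1.0])
        b = np.array([0.0, 0.5])
        # binary-exact values so the additive structure cancels exactly
        data = np.zeros((n, 2, 2)) + a[None, :, None] + b[None, None, :]
        data += (np.arange(n) * 0.125)[:, None, None]  # subject offsets
        table = anova_2x2_within(data)
        assert table.iloc[2]["F"] == pytest.approx(0.0, abs=1e-18)

    def test_f_equals_squared_paired_t_on_marginals(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(14, 2, 2))
        table = anova_2x2_within(data)
        t_a = paired_t(data[:, 0, :].mean(axis=1), data[:, 1, :].mean(axis=1),
                       bayes=False)
        t_b = paired_t(data[:, :, 0].mean(axis=1), data[:, :, 1].mean(axis=1),
                       bayes=False)
        assert table.iloc[0]["F"] == pytest.approx(t_a.statistic**2, abs=1e-8)
        assert table.iloc[1]["F"] == pytest.approx(t_b.statistic**2, abs=1e-8)

    def test_against_repeated_measures_anova_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        data = rng.normal(size=(12, 2, 2))
        table = anova_2x2_within(data, factor_names=("A", "B"))
        rows = []
        for s in range(12):
            for i in range(2):
                for j in range(2):
                    rows.append({"subject": s, "A": i, "B": j, "y": data[s, i, j]})
        long = pd.DataFrame(rows)
        oracle = pg.rm_anova(
            data=long, dv="y", within=["A", "B"], subject="subject", detailed=True
        ).set_index("Source")
        assert table.loc["A", "F"] == pytest.approx(oracle.loc["A", "F"], rel=1e-6)
        assert table.loc["B", "F"] == pytest.approx(oracle.loc["B", "F"], rel=1e-6)
        assert table.loc["A x B", "F"] == pytest.approx(
            oracle.loc["A * B", "F"], rel=1e-6
        )
        assert table.loc["A", "p_value"] == pytest.approx(
            oracle.loc["A", "p_unc"], rel=1e-6
        )

    def test_missing_cells_rejected(self):
        data = np.ones((5, 2, 2))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            anova_2x2_within(data)


class TestJzsBayesFactor:
    def test_null_t_favors_null(self):
        for n in (10, 40, 100):
            assert jzs_bf_paired(t=0.0, n=n) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bf_paired(t=t, n=40) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_reported_magnitude_fixture(self):
        # t(39) = 3.54 was reported with BF = 29.10
        assert jzs_bf_paired(t=3.54, n=40) == pytest.approx(29.10, rel=0.10)

    def test_against_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        for t, n in [(0.5, 12), (2.2, 30), (3.54, 40), (-1.7, 25)]:
            mine = jzs_bf_paired(t=t, n=n)
            ref = float(pg.bayesfactor_ttest(t, n, paired=True))
            assert mine == pytest.approx(ref, rel=1e-3)

    def test_vector_interface_matches_t_interface(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0.5, 1, 20), rng.normal(0, 1, 20)
        res = paired_t(x, y)
        assert res.bf10 == pytest.approx(
            jzs_bf_paired(t=res.statistic, n=20), rel=1e-9
        )


@pytest.fixture(scope="module")
def fits_and_trials():
    from sdtmem.fitting import fit_trials
    from sdtmem.synthetic import simulate_experiment

    trials = simulate_experiment(1, "uvsd", n_participants=10, seed=21)
    fits = fit_trials(trials, n_starts=4, seed=0)
    return fits, trials


class TestAnalysisPipeline:
    def test_report_structure(self, fits_and_trials):
        fits, trials = fits_and_trials
        report = analysis_pipeline(fits, trials=trials, bayes=False)
        assert {"parameters", "contrasts", "correlations", "comparison",
                "hit_fa", "hit_fa_anova"} <= set(report)
        comp = report["comparison"]["fixed"]
        assert comp["pct_best"].sum() == pytest.approx(100.0)

    def test_outlier_exclusion_rule(self, fits_and_trials):
        fits, _ = fits_and_trials
        rigged = fits.copy()
        mask = (rigged["model"] == "MSD") & (rigged["participant"] == "p001")
        rigged.loc[mask & (rigged["condition"] == "fixed"), "d_A"] = 164.93
        report = analysis_pipeline(rigged, bayes=False)
        assert report["excluded_participants"] == ["p001"]
        # excluded listwise from the MSD correlation rows
        msd_rows = report["correlations"].query("model == 'MSD'")
        assert (msd_rows["df"] == 10 - 2 - 1).all()

    def test_null_cohort_contrasts_not_extreme(self, fits_and_trials):
        # same generating parameters in both conditions: the sigma_o
        # contrast should not be wildly significant
        fits, _ = fits_and_trials
        report = analysis_pipeline(fits, bayes=False)
        assert report["contrasts"]["UVSD.sigma_o"].p_value > 0.001
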