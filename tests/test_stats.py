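"""Repeated-measures ANOVA partitions, post-hoc tests, trend fits, study driver."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.anova import AnovaRM

from myowave.stats import (
    ConditionSpec,
    StudyConfig,
    bonferroni_posthoc,
    fit_trend,
    rm_anova_one_way,
    rm_anova_two_way,
    run_synthetic_study,
)


def brute_force_one_way(X):
    """Direct sums-of-squares partition via explicit loops."""
    n, k = X.shape
    gm = X.mean()
    ss_cond = sum(n * (X[:, j].mean() - gm) ** 2 for j in range(k))
    ss_subj = sum(k * (X[i].mean() - gm) ** 2 for i in range(n))
    ss_tot = ((X - gm) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestOneWay:
    def test_no_variance_gives_f_zero_p_one(self):
        res = rm_anova_one_way(np.full((4, 3), 5.0))
        eff = res.effect("condition")
        assert eff.F == 0.0
        assert eff.p == 1.0

    def test_matches_brute_force_partition(self):
        X = np.array([[3.0, 5.0, 4.0], [6.0, 8.0, 9.0], [2.0, 4.0, 3.0]])
        res = rm_anova_one_way(X)
        assert res.effect("condition").F == pytest.approx(
            brute_force_one_way(X), abs=1e-10)

    def test_matches_statsmodels_anovarm(self, rng):
        X = rng.normal(10, 2, size=(6, 4))
        res = rm_anova_one_way(X)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 4),
            "cond": np.tile(np.arange(4), 6),
            "y": X.ravel(),
        })
        sm = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        assert res.effect("condition").F == pytest.approx(
            sm.anova_table.loc["cond", "F Value"], rel=1e-8)
        assert res.effect("condition").p == pytest.approx(
            sm.anova_table.loc["cond", "Pr > F"], rel=1e-6)

    def test_subject_offsets_are_absorbed(self, rng):
        X = rng.normal(0, 1, size=(5, 3))
        offsets = rng.normal(0, 10, size=5)[:, None]
        a = rm_anova_one_way(X).effect("condition").F
        b = rm_anova_one_way(X + offsets).effect("condition").F
        assert a == pytest.approx(b, rel=1e-9)

    def test_two_level_f_equals_paired_t_squared(self, rng):
        from scipy.stats import ttest_rel
        X = rng.normal(0, 1, size=(8, 2))
        F = rm_anova_one_way(X).effect("condition").F
        t = ttest_rel(X[:, 0], X[:, 1]).statistic
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_missing_cells_rejected(self):
        X = np.ones((3, 3))
        X[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_one_way(X)


def brute_force_two_way(X):
    """Explicit-loop partition of the fully within-subject two-way design."""
    n, a, b = X.shape
    gm = X.mean()
    m_a = [X[:, i, :].mean() for i in range(a)]
    m_b = [X[:, :, j].mean() for j in range(b)]
    m_s = [X[i].mean() for i in range(n)]
    ss_a = n * b * sum((m - gm) ** 2 for m in m_a)
    ss_b = n * a * sum((m - gm) ** 2 for m in m_b)
    ss_sa = b * sum(
        (X[s, i, :].mean() - m_s[s] - m_a[i] + gm) ** 2
        for s in range(n) for i in range(a))
    ss_sb = a * sum(
        (X[s, :, j].mean() - m_s[s] - m_b[j] + gm) ** 2
        for s in range(n) for j in range(b))
    F_a = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))
    F_b = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (n - 1)))
    return F_a, F_b


class TestTwoWay:
    def test_constant_factor_gives_zero_f(self, rng):
        X = np.tile(rng.normal(0, 1, size=(4, 1, 3)), (1, 3, 1))
        res = rm_anova_two_way(X)
        assert res.effect("A").F == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_partition(self, rng):
        X = rng.normal(5, 2, size=(4, 2, 3))
        res = rm_anova_two_way(X)
        F_a, F_b = brute_force_two_way(X)
        assert res.effect("A").F == pytest.approx(F_a, abs=1e-10)
        assert res.effect("B").F == pytest.approx(F_b, abs=1e-10)

    def test_matches_statsmodels_anovarm(self, rng):
        n, a, b = 5, 3, 4
        X = rng.normal(0, 1, size=(n, a, b))
        res = rm_anova_two_way(X)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), a * b),
            "A": np.tile(np.repeat(np.arange(a), b), n),
            "B": np.tile(np.arange(b), n * a),
            "y": X.ravel(),
        })
        sm = AnovaRM(long, "y", "subject", within=["A", "B"]).fit().anova_table
        assert res.effect("A").F == pytest.approx(sm.loc["A", "F Value"],
                                                  rel=1e-8)
        assert res.effect("B").F == pytest.approx(sm.loc["B", "F Value"],
                                                  rel=1e-8)
        assert res.effect("AxB").F == pytest.approx(sm.loc["A:B", "F Value"],
                                                    rel=1e-8)

    def test_consistent_label_permutation_leaves_f_unchanged(self, rng):
        X = rng.normal(0, 1, size=(4, 2, 4))
        perm = [2, 0, 3, 1]
        a = rm_anova_two_way(X)
        b = rm_anova_two_way(X[:, :, perm])
        assert a.effect("B").F == pytest.approx(b.effect("B").F, rel=1e-10)


class TestBonferroni:
    def test_identical_levels_not_significant(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 2))
        table = bonferroni_posthoc(X)
        assert table.p_adjusted.iloc[0] == 1.0
        assert not table.significant.iloc[0]

    def test_seven_levels_give_21_comparisons(self, rng):
        table = bonferroni_posthoc(rng.normal(0, 1, size=(5, 7)))
        assert len(table) == 21

    def test_adjustment_matches_direct_recomputation(self, rng):
        from itertools import combinations
        from scipy.stats import ttest_rel
        X = rng.normal(0, 1, size=(6, 4))
        table = bonferroni_posthoc(X)
        pairs = list(combinations(range(4), 2))
        for row, (i, j) in zip(table.itertuples(), pairs):
            raw = ttest_rel(X[:, i], X[:, j]).pvalue
            assert row.p_raw == pytest.approx(raw, rel=1e-12)
            assert row.p_adjusted == pytest.approx(min(1.0, raw * len(pairs)))

    def test_zero_variance_nonzero_difference_flagged(self):
        X = np.column_stack([np.arange(4.0), np.arange(4.0) + 2.0])
        table = bonferroni_posthoc(X)
        assert table.degenerate.iloc[0]


class TestTrendFit:
    def test_exact_linear_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_trend(x, 2 * x + 1, 1)
        assert np.allclose(fit.coefficients, [1.0, 2.0], atol=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_quadratic_fit(self):
        x = np.linspace(5, 25, 7)
        y = 3.0 - 0.2 * x + 0.05 * x**2
        fit = fit_trend(x, y, 2)
        assert np.allclose(fit.coefficients, [3.0, -0.2, 0.05], atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(5, 25, 40)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, 40)
        fit = fit_trend(x, y, 2)
        V = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(V.T @ V, V.T @ y)
        assert np.allclose(fit.coefficients, beta, atol=1e-8)

    def test_quadratic_r2_at_least_linear_r2(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 10, 12)
            y = rng.normal(0, 1, 12)
            assert fit_trend(x, y, 2).r_squared >= \
                fit_trend(x, y, 1).r_squared - 1e-12

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_trend(np.ones(5), np.arange(5.0), 1)


def _tiny_config(seed=0, participants=1, conditions=1):
    conds = [
        ConditionSpec("c0", "running", 2.6, 13.0, 9.0, 1.2, 0.40),
        ConditionSpec("c1", "running", 2.9, 17.0, 13.0, 1.6, 0.40),
    ][:conditions]
    return StudyConfig(n_participants=participants, n_stances=1,
                       conditions=conds, training_conditions=(0,), seed=seed)


class TestStudyDriver:
    def test_degenerate_design_skips_anova_but_reports_metrics(self):
        report = run_synthetic_study(_tiny_config())
        assert report.anova_input is None
        assert any("ANOVA skipped" in line for line in report.log)
        assert len(report.input_frequency) == 1
        assert len(report.spectra) == 2 * 19  # both aponeuroses, 19 landmarks

    def test_identical_seeds_give_identical_reports(self):
        a = run_synthetic_study(_tiny_config(seed=3))
        b = run_synthetic_study(_tiny_config(seed=3))
        pd.testing.assert_frame_equal(a.input_frequency, b.input_frequency)
        pd.testing.assert_frame_equal(a.spectra, b.spectra)

    def test_report_written_to_disk(self, tmp_path):
        run_synthetic_study(_tiny_config(), out_dir=tmp_path)
        assert (tmp_path / "input_frequency.csv").exists()
        assert (tmp_path / "spectra_summary.csv").exists()
        assert (tmp_path / "run_log.txt").exists()
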