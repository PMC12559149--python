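"""Agreement metrics, within-subject tests, mixed model, power analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from torsionlab.stats import (
    fit_lmm,
    icc_agreement,
    mad,
    pearson_ci,
    rm_anova,
    rm_anova_power,
    rm_anova_sample_size,
    significance_code,
    tukey_hsd,
)

# ---------------------------------------------------------------------------
# from-scratch oracles


def icc21_oracle(x: np.ndarray) -> float:
    """ICC(2,1) from the raw mean-squares definition."""
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((x - grand) ** 2) - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def rm_anova_oracle(x: np.ndarray) -> tuple[float, float, float, float]:
    """Hand decomposition of the one-way within-subjects ANOVA."""
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((v - grand) ** 2 for v in x.ravel())
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    return ss_cond, ss_subj, ss_err, f


class TestMad:
    def test_identical_vectors(self):
        assert mad([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_small_example(self):
        assert mad([1, 2, 3], [2, 2, 1]) == pytest.approx(1.0)

    def test_single_pair(self):
        assert mad([10.0], [7.0]) == 3.0

    def test_incomplete_pairs_dropped(self):
        assert mad([1.0, np.nan, 3.0], [2.0, 5.0, 1.0]) == pytest.approx(1.5)
        with pytest.raises(ValueError, match="no complete pairs"):
            mad([np.nan], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        a = np.arange(10.0)
        r, p, ci = pearson_ci(a, 2 * a + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.arange(5.0)
        assert pearson_ci(a, -a)[0] == pytest.approx(-1.0)

    def test_small_example_matches_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        r, p, ci = pearson_ci(a, b)
        # direct product-moment computation
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(0.982, abs=5e-4)
        assert ci[0] < r < ci[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestIcc:
    def test_identical_raters(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_agreement(x)
        assert res.icc == pytest.approx(1.0)

    def test_constant_shift_penalised_and_matches_oracle(self):
        x = np.column_stack([np.arange(10.0, 20.0), np.arange(10.0, 20.0) + 5.0])
        res = icc_agreement(x)
        assert res.icc < 1.0
        assert res.icc == pytest.approx(icc21_oracle(x), abs=1e-9)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 12))
            k = int(rng.integers(2, 5))
            x = rng.integers(0, 10, size=(n, k)).astype(float)
            if np.allclose(x.var(axis=0).sum(), 0):
                continue
            res = icc_agreement(x)
            assert res.icc == pytest.approx(icc21_oracle(x), abs=1e-6)
            assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_matches_pingouin_reference(self, rng):
        import pingouin as pg

        x = rng.normal(10, 3, size=(8, 3))
        res = icc_agreement(x)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(8), 3),
                "raters": np.tile(np.arange(3), 8),
                "ratings": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        ref_row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(ref_row.ICC, abs=1e-9)
        assert res.p_value == pytest.approx(ref_row.pval, abs=1e-9)

    def test_incomplete_matrix_rejected(self):
        x = np.random.default_rng(0).normal(size=(6, 2))
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_agreement(x)


class TestRmAnova:
    def test_identical_conditions_give_f_zero(self, rng):
        col = rng.normal(size=6)
        x = np.column_stack([col, col, col])
        t = rm_anova(x)
        assert t.f_value == 0.0
        assert t.p_value == 1.0

    def test_small_integer_matrix_matches_hand_decomposition(self):
        x = np.array([[1, 2, 4], [2, 3, 5], [0, 2, 3], [1, 1, 4]], dtype=float)
        t = rm_anova(x)
        ss_cond, ss_subj, ss_err, f = rm_anova_oracle(x)
        assert t.ss_condition == pytest.approx(ss_cond, abs=1e-9)
        assert t.ss_subject == pytest.approx(ss_subj, abs=1e-9)
        assert t.ss_error == pytest.approx(ss_err, abs=1e-9)
        assert t.f_value == pytest.approx(f, abs=1e-9)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 10))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k))
            t = rm_anova(x)
            _, _, _, f = rm_anova_oracle(x)
            assert t.f_value == pytest.approx(f, abs=1e-6)

    def test_incomplete_rows_dropped_and_counted(self, rng):
        x = rng.normal(size=(6, 3))
        x[1, 2] = np.nan
        t = rm_anova(x)
        assert t.n_subjects_used == 5
        assert t.n_subjects_dropped == 1

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(np.array([[1.0, 2.0, 3.0]]))


class TestTukey:
    def test_two_groups_match_t_test(self, rng):
        g = [rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
        table = tukey_hsd(g)
        p_t = sps.ttest_ind(*g).pvalue
        assert table.p_adj.iloc[0] == pytest.approx(p_t, abs=1e-9)

    def test_equal_means_all_non_significant(self):
        g = [np.array([1.0, 2.0, 3.0, 4.0])] * 3
        table = tukey_hsd(g)
        assert (table.p_adj > 0.99).all()

    def test_three_groups_match_scipy(self, rng):
        for _ in range(20):
            g = [rng.normal(i * 0.4, 1.0, int(rng.integers(8, 15))) for i in range(3)]
            mine = tukey_hsd(g)
            ref = sps.tukey_hsd(*g)
            pairs = [(0, 1), (0, 2), (1, 2)]
            for row, (i, j) in zip(mine.itertuples(), pairs):
                assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_within_subjects_uses_interaction_error(self, rng):
        x = rng.normal(size=(8, 3)) + np.array([0.0, 0.5, 1.0])
        table = tukey_hsd(x, within_subjects=True)
        assert len(table) == 3
        assert (table.ci_lo <= table.mean_diff).all()
        assert (table.mean_diff <= table.ci_hi).all()


class TestLmm:
    def _simulate(self, rng, beta_severe=-0.22, sd_participant=0.05, sd_resid=0.05,
                  n_participants=20, n_records=24):
        sev = np.tile(np.repeat(["none", "mild", "moderate", "severe"], n_records // 4),
                      n_participants)
        joint = np.tile(["hip", "knee", "ankle"], n_participants * n_records // 3)
        pid = np.repeat(np.arange(n_participants), n_records)
        u = rng.normal(0, sd_participant, n_participants)
        beta = {"none": 0.0, "mild": -0.07, "moderate": -0.12, "severe": beta_severe}
        y = 0.9 + np.array([beta[s] for s in sev]) + u[pid] + rng.normal(0, sd_resid, len(pid))
        return pd.DataFrame(
            {"participant": pid, "severity": sev, "joint_level": joint, "dice": y}
        )

    def test_zero_participant_variance_matches_ols(self, rng):
        import statsmodels.formula.api as smf

        df = self._simulate(rng, sd_participant=0.0, n_participants=10, n_records=12)
        res = fit_lmm(df, reference_levels={"severity": "none", "joint_level": "hip"})
        ols = smf.ols(
            "dice ~ C(severity, Treatment(reference='none'))"
            " + C(joint_level, Treatment(reference='hip'))",
            df,
        ).fit()
        sev = res.coefficients.set_index("term").loc["severity[severe]", "estimate"]
        assert sev == pytest.approx(ols.params["C(severity, Treatment(reference='none'))[T.severe]"], abs=1e-6)

    def test_planted_severity_effect_recovered(self, rng):
        ests = []
        for _ in range(20):
            df = self._simulate(rng)
            res = fit_lmm(df, reference_levels={"severity": "none", "joint_level": "hip"})
            row = res.coefficients.set_index("term").loc["severity[severe]"]
            ests.append(row.estimate)
        assert np.mean(ests) == pytest.approx(-0.22, abs=0.02)

    def test_single_participant_rejected(self, rng):
        df = self._simulate(rng, n_participants=1)
        with pytest.raises(ValueError, match="participants"):
            fit_lmm(df)

    def test_aliased_factors_rejected(self, rng):
        df = self._simulate(rng, n_participants=6, n_records=12)
        df["copy_of_severity"] = df["severity"]
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm(df, fixed=("severity", "copy_of_severity"))


class TestSampleSize:
    def test_defining_property_holds(self):
        for m in (3, 4, 5):
            n = rm_anova_sample_size(0.25, 0.05, 0.80, 0.6, m)
            assert rm_anova_power(n, 0.25, 0.05, 0.6, m) >= 0.80
            assert rm_anova_power(n - 1, 0.25, 0.05, 0.6, m) < 0.80

    def test_monotone_in_corr_and_m(self):
        base = rm_anova_sample_size(0.25, 0.05, 0.80, 0.5, 4)
        assert rm_anova_sample_size(0.25, 0.05, 0.80, 0.7, 4) <= base
        assert rm_anova_sample_size(0.25, 0.05, 0.80, 0.5, 6) <= base

    def test_spot_values_match_power_curve_oracle(self):
        """Direct noncentral-F scan over n reproduces the returned minimum."""
        for m, corr in [(4, 0.5), (5, 0.6), (3, 0.6)]:
            returned = rm_anova_sample_size(0.25, 0.05, 0.80, corr, m)
            oracle = None
            for n in range(2, 101):
                lam = 0.25**2 * n * m / (1 - corr)
                df1, df2 = m - 1, (n - 1) * (m - 1)
                crit = sps.f.ppf(0.95, df1, df2)
                if sps.ncf.sf(crit, df1, df2, lam) >= 0.80:
                    oracle = n
                    break
            assert returned == oracle

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rm_anova_sample_size(0.0)
        with pytest.raises(ValueError):
            rm_anova_sample_size(0.25, corr=1.0)


def test_significance_codes():
    assert significance_code(0.2) == "ns"
    assert significance_code(0.04) == "*"
    assert significance_code(0.005) == "**"
    assert significance_code(0.0005) == "***"
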