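"""Statistical battery: worked examples, oracles, calibration properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from reprotime.stats import (
    gaussian_kde,
    one_sample_t,
    paired_t,
    pearson,
    rm_anova_gg,
)


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        vals = [1.0 + e for e in (0.01, -0.01, 0.02, -0.02)]
        res = one_sample_t(vals, 1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        res = one_sample_t([1.1, 1.0, 1.05, 0.95, 1.2], 1.0)
        assert res.statistic == pytest.approx(1.3950, abs=1e-4)
        assert res.df == 4
        assert 0 < res.p_value < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0], 1.0)

    def test_antisymmetric_about_mu0(self):
        vals = np.array([1.2, 0.9, 1.1, 1.3])
        t_pos = one_sample_t(vals, 1.0).statistic
        t_neg = one_sample_t(2.0 - vals, 1.0).statistic
        assert t_pos == pytest.approx(-t_neg)

    def test_matches_scipy(self, rng):
        vals = rng.normal(1.0, 0.1, size=20)
        res = one_sample_t(vals, 1.0)
        ref = sps.ttest_1samp(vals, 1.0)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestPairedT:
    def test_identical_samples_degenerate(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_worked_example(self):
        res = paired_t([0.1, -0.1, 0.2, 0.0], [0.0, 0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(0.7746, abs=1e-4)
        assert res.df == 3

    def test_p_uniform_under_null(self, rng):
        # 1000 replications at n = 8, true shift 0: p ~ Uniform(0, 1)
        n_rep, n = 1000, 8
        x = rng.normal(size=(n_rep, n))
        y = rng.normal(size=(n_rep, n))
        d = x - y
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / math.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), n - 1)
        ks = sps.kstest(p, "uniform")
        assert ks.statistic < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson(x, x)
        assert res.statistic == 1.0
        assert res.p_value == 0.0

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, -x).statistic == -1.0

    def test_worked_example(self):
        res = pearson([1, 2, 3], [2, 4, 7])
        assert res.statistic == pytest.approx(0.9934, abs=1e-4)
        assert res.df == 1

    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _brute_force_oneway(y):
    """Independent sums-of-squares oracle for the one-way within design."""
    n, k = y.shape
    gm = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - gm) ** 2)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + gm
    ss_err = np.sum(resid**2)
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def _epsilon_eigen_oracle(scores, d):
    """GG epsilon via double-centering of the condition covariance.

    Independent construction: double-center the covariance matrix itself
    (rather than projecting onto a contrast basis) and use its nonzero
    eigenvalues; the two routes agree because eigenvalue sums are
    basis-invariant on the contrast subspace.
    """
    s_mat = np.cov(scores, rowvar=False)
    k = s_mat.shape[0]
    j = np.eye(k) - np.ones((k, k)) / k
    sc = j @ s_mat @ j
    lam = np.sort(np.linalg.eigvalsh(sc))[::-1][:d]
    lam = np.clip(lam, 0, None)
    return float(np.sum(lam) ** 2 / (d * np.sum(lam**2)))


class TestRmAnova:
    def test_two_level_factor_has_epsilon_one(self, rng):
        y = rng.normal(size=(10, 2))
        res = rm_anova_gg(y)
        assert res.effects["A"].epsilon == 1.0

    def test_toy_table_hand_computed(self):
        # SS_cond = 14/3, SS_err = 4/3 -> F = 7 with df (2, 4)
        y = np.array([[1, 2, 3], [2, 3, 4], [3, 5, 4]], dtype=float)
        res = rm_anova_gg(y)
        eff = res.effects["A"]
        assert eff.F == pytest.approx(7.0, abs=1e-10)
        assert (eff.df1, eff.df2) == (2, 4)
        assert eff.epsilon == pytest.approx(_epsilon_eigen_oracle(y, 2), abs=1e-12)

    def test_oneway_matches_brute_force(self, rng):
        for _ in range(10):
            y = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1))
            res = rm_anova_gg(y)
            assert res.effects["A"].F == pytest.approx(_brute_force_oneway(y), abs=1e-8)

    def test_twoway_f_matches_brute_force(self, rng):
        # brute-force cell-mean sums of squares on random 5 x 3 x 3 tables
        for _ in range(10):
            y = rng.normal(size=(5, 3, 3))
            n, a, b = y.shape
            res = rm_anova_gg(y)
            gm = y.mean()
            m_a, m_b = y.mean(axis=(0, 2)), y.mean(axis=(0, 1))
            m_ab, m_s = y.mean(axis=0), y.mean(axis=(1, 2))
            m_sa, m_sb = y.mean(axis=2), y.mean(axis=1)
            ss_a = n * b * np.sum((m_a - gm) ** 2)
            ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
            f_a = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))
            assert res.effects["A"].F == pytest.approx(f_a, abs=1e-8)
            ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
            resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None] +
                     m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - gm)
            f_ab = (ss_ab / 4) / (np.sum(resid**2) / (4 * (n - 1)))
            assert res.effects["AxB"].F == pytest.approx(f_ab, abs=1e-8)

    def test_main_effects_match_pingouin(self, rng):
        import warnings
        import pandas as pd

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import pingouin as pg

            y = rng.normal(size=(12, 3, 3)) + rng.normal(size=(12, 1, 1))
            res = rm_anova_gg(y)
            rows = [dict(subj=i, A=f"a{j}", B=f"b{k}", y=y[i, j, k])
                    for i in range(12) for j in range(3) for k in range(3)]
            aov = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["A", "B"],
                              subject="subj", correction=True, detailed=True)
        for src, name in (("A", "A"), ("B", "B")):
            row = aov[aov["Source"] == src].iloc[0]
            eff = res.effects[name]
            assert eff.F == pytest.approx(row["F"], abs=1e-8)
            assert eff.epsilon == pytest.approx(row["eps"], abs=1e-8)
            assert eff.p_gg == pytest.approx(row["p_GG_corr"], abs=1e-8)

    def test_epsilon_bounds_property(self, rng):
        # 100 random positive-definite covariances: 1/(k-1) <= eps <= 1
        for _ in range(100):
            k = int(rng.integers(3, 6))
            a_mat = rng.normal(size=(k + 3, k))
            scores = rng.normal(size=(30, k)) @ a_mat.T[:k, :k]
            res = rm_anova_gg(np.asarray(scores))
            eps = res.effects["A"].epsilon
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_compound_symmetry_epsilon_near_one(self, rng):
        # exchangeable covariance satisfies sphericity: eps ~ 1 at n = 200
        subj = rng.normal(size=(200, 1))
        y = subj + rng.normal(size=(200, 3))
        res = rm_anova_gg(y)
        assert res.effects["A"].epsilon > 0.95

    def test_interaction_epsilon_matches_eigen_oracle(self, rng):
        y = rng.normal(size=(8, 3, 3))
        res = rm_anova_gg(y)
        scores = y.reshape(8, 9)
        # interaction subspace: project out both main-effect margins
        ja = np.eye(3) - np.ones((3, 3)) / 3
        proj = np.kron(ja, ja)
        sc = proj @ np.cov(scores, rowvar=False) @ proj
        lam = np.clip(np.sort(np.linalg.eigvalsh(sc))[::-1][:4], 0, None)
        eps_oracle = float(np.sum(lam) ** 2 / (4 * np.sum(lam**2)))
        assert res.effects["AxB"].epsilon == pytest.approx(eps_oracle, abs=1e-10)

    def test_missing_cells_rejected(self):
        y = np.array([[1.0, 2.0], [3.0, np.nan], [2.0, 1.0]])
        with pytest.raises(ValueError):
            rm_anova_gg(y)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_gg(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestKde:
    def test_single_value_peak(self):
        est = gaussian_kde([0.5], bandwidth=0.04, grid=[0.5])
        assert est.density[0] == pytest.approx(1 / (0.04 * math.sqrt(2 * math.pi)), abs=1e-10)
        assert est.density[0] == pytest.approx(9.9736, abs=1e-4)

    def test_normalization(self, rng):
        vals = rng.normal(1.0, 0.2, size=40)
        est = gaussian_kde(vals, bandwidth=0.04)
        integral = np.trapezoid(est.density, est.grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_two_far_points_symmetric_modes(self):
        est = gaussian_kde([0.0, 10.0], bandwidth=0.04)
        d_lo = est.density[np.argmin(np.abs(est.grid - 0.0))]
        d_hi = est.density[np.argmin(np.abs(est.grid - 10.0))]
        assert d_lo == pytest.approx(d_hi, rel=1e-6)

    @given(a=st.floats(0.5, 4), b=st.floats(-2, 2))
    @settings(max_examples=30, deadline=None)
    def test_shift_scale_equivariance(self, a, b):
        x = np.array([0.9, 1.0, 1.1, 1.3])
        g = np.linspace(0.5, 1.5, 11)
        base = gaussian_kde(x, 0.04, grid=g)
        moved = gaussian_kde(a * x + b, a * 0.04, grid=a * g + b)
        np.testing.assert_allclose(moved.density, base.density / a, rtol=1e-9)

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kde([1.0], bandwidth=0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kde([], bandwidth=0.04)
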