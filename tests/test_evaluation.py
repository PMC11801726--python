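import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from methylpredict import (
    PhenotypeTable,
    bootstrap_compare,
    compute_eaa,
    median_abs_error,
    pearson,
    replicate_agreement,
)
from methylpredict.evaluation import Z_975, associate_eaa, ci_width_summary
from methylpredict.exceptions import NumericError, ValidationError


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(-x, x) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        obs = np.array([1.0, 3.0, 2.0, 5.0])
        # independent direct computation of the product-moment formula
        n = 4
        num = n * np.sum(pred * obs) - pred.sum() * obs.sum()
        den = np.sqrt(n * np.sum(pred**2) - pred.sum() ** 2) * np.sqrt(
            n * np.sum(obs**2) - obs.sum() ** 2
        )
        assert pearson(pred, obs) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_named(self):
        with pytest.raises(NumericError, match="observation"):
            pearson(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))
        with pytest.raises(NumericError, match="prediction"):
            pearson(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_agrees_with_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            assert pearson(a, b) == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)


class TestMedianAbsError:
    def test_zero_on_equal(self):
        x = np.array([1.0, 2.0, 3.0])
        assert median_abs_error(x, x) == 0.0

    def test_odd_length(self):
        assert median_abs_error(np.array([0.0, 1.0, 3.0]), np.zeros(3)) == 1.0

    def test_even_length_midpoint(self):
        assert median_abs_error(np.array([0.0, 1.0, 3.0, 7.0]), np.zeros(4)) == 2.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            median_abs_error(np.zeros(3), np.zeros(4))

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_matches_numpy_median(self, vals):
        arr = np.array(vals)
        assert median_abs_error(arr, np.zeros_like(arr)) == np.median(np.abs(arr))


class TestReplicateAgreement:
    def _pheno(self, groups):
        return PhenotypeTable(
            data=pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(len(groups))],
                    "target": np.arange(len(groups), dtype=float),
                    "grp": groups,
                }
            ),
            replicate_col="grp",
        )

    def test_two_perfect_pairs(self):
        pheno = self._pheno(["g1", "g1", "g2", "g2"])
        rep = replicate_agreement(np.array([5.0, 5.0, 7.0, 7.0]), pheno)
        assert rep.mae_median == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_median_pair_difference(self):
        pheno = self._pheno(["g1", "g1", "g2", "g2"])
        rep = replicate_agreement(np.array([5.0, 6.0, 7.0, 9.0]), pheno)
        assert rep.mae_median == pytest.approx(1.5)

    def test_unpaired_members_ignored(self):
        pheno = self._pheno(["g1", "g1", "", "g2", "g2"])
        rep = replicate_agreement(np.array([5.0, 5.0, 99.0, 7.0, 8.0]), pheno)
        assert rep.n == 2

    def test_triple_group_error(self):
        pheno = self._pheno(["g1", "g1", "g1", "g2", "g2"])
        with pytest.raises(ValidationError, match="g1"):
            replicate_agreement(np.arange(5.0), pheno)

    def test_no_replicate_column(self, tiny_pheno):
        with pytest.raises(ValidationError):
            replicate_agreement(np.arange(5.0), tiny_pheno)


class TestBootstrapCompare:
    @pytest.fixture
    def data(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(40, 12, 80)
        pa = obs + rng.normal(0, 4, 80)
        pb = obs + rng.normal(0, 6, 80)
        return pa, pb, obs

    def test_identical_predictors(self, data):
        pa, _, obs = data
        cmp_res = bootstrap_compare(pa, pa.copy(), obs, n_iter=500, seed=0)
        assert cmp_res.delta_r_point == 0.0
        assert cmp_res.delta_mae_point == 0.0
        assert cmp_res.delta_r_ci_95[0] <= 0.0 <= cmp_res.delta_r_ci_95[1]
        assert cmp_res.delta_mae_ci_95[0] <= 0.0 <= cmp_res.delta_mae_ci_95[1]

    def test_deterministic(self, data):
        pa, pb, obs = data
        c1 = bootstrap_compare(pa, pb, obs, n_iter=400, seed=3)
        c2 = bootstrap_compare(pa, pb, obs, n_iter=400, seed=3)
        assert c1.delta_r_ci_95 == c2.delta_r_ci_95
        assert c1.delta_mae_ci_95 == c2.delta_mae_ci_95

    def test_point_deltas_are_full_sample(self, data):
        pa, pb, obs = data
        c = bootstrap_compare(pa, pb, obs, n_iter=200, seed=0)
        assert c.delta_r_point == pearson(pa, obs) - pearson(pb, obs)
        assert c.delta_mae_point == median_abs_error(pa, obs) - median_abs_error(pb, obs)

    def test_ci_ordering(self, data):
        pa, pb, obs = data
        c = bootstrap_compare(pa, pb, obs, n_iter=2000, seed=5)
        assert c.delta_r_ci_95[0] <= c.delta_r_ci_95[1]
        assert c.delta_mae_ci_95[0] <= c.delta_mae_ci_95[1]

    def test_detects_clear_difference(self):
        rng = np.random.default_rng(2)
        obs = rng.normal(40, 12, 120)
        good = obs + rng.normal(0, 1, 120)
        bad = obs + rng.normal(0, 20, 120)
        c = bootstrap_compare(good, bad, obs, n_iter=2000, seed=0)
        assert c.delta_r_ci_95[0] > 0  # good predictor clearly better

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_compare(np.arange(5.0), np.arange(5.0), np.arange(5.0))


class TestComputeEaa:
    def test_perfectly_linear_gives_zero_residuals(self):
        age = np.linspace(0, 20, 30)
        pred = 2.0 + 1.1 * age
        np.testing.assert_allclose(compute_eaa(pred, age), 0.0, atol=1e-10)

    def test_hand_computed_three_point_instance(self):
        age = np.array([0.0, 1.0, 2.0])
        pred = np.array([1.0, 1.0, 4.0])
        # closed-form simple OLS: slope = 1.5, intercept = 0.5
        np.testing.assert_allclose(compute_eaa(pred, age), [0.5, -1.0, 0.5], atol=1e-12)

    def test_orthogonality(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(0, 20, 50)
        pred = age + rng.normal(0, 2, 50)
        res = compute_eaa(pred, age)
        assert abs(res.mean()) < 1e-10
        assert abs(np.cov(res, age, bias=True)[0, 1]) < 1e-10

    def test_matches_closed_form_everywhere(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            age = rng.uniform(0, 80, 25)
            pred = rng.normal(50, 10, 25)
            slope = np.cov(age, pred, bias=True)[0, 1] / np.var(age)
            icpt = pred.mean() - slope * age.mean()
            np.testing.assert_allclose(
                compute_eaa(pred, age), pred - icpt - slope * age, atol=1e-9
            )

    def test_cell_adjustment_drops_collinear_column(self):
        rng = np.random.default_rng(5)
        n = 60
        age = rng.uniform(0, 20, n)
        cells = rng.dirichlet(np.ones(6), size=n)  # rows sum to 1 exactly
        pred = age + cells[:, 0] * 5 + rng.normal(0, 1, n)
        res = compute_eaa(pred, age, cell_props=cells)
        assert abs(res.mean()) < 1e-8
        for c in range(5):
            assert abs(np.cov(res, cells[:, c], bias=True)[0, 1]) < 1e-8


class TestAssociateEaa:
    def test_effect_recovery_coverage(self):
        hits = 0
        n_sims = 100
        for s in range(n_sims):
            rng = np.random.default_rng(600 + s)
            n = 500
            exposure = rng.integers(0, 2, n).astype(float)
            eaa = 1.0 * exposure + rng.normal(0, 3, n)
            beta, se, _ = associate_eaa(eaa, exposure)
            hits += abs(beta - 1.0) <= 2 * se
        assert hits >= 95

    def test_null_p_uniform(self):
        pvals = []
        for s in range(200):
            rng = np.random.default_rng(900 + s)
            eaa = rng.normal(0, 3, 120)
            exposure = rng.normal(size=120)
            pvals.append(associate_eaa(eaa, exposure)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_exposure(self):
        with pytest.raises(NumericError):
            associate_eaa(np.random.default_rng(0).normal(size=20), np.ones(20))

    def test_covariate_adjustment(self):
        rng = np.random.default_rng(6)
        n = 300
        sex = rng.integers(0, 2, n).astype(float)
        exposure = rng.normal(size=n)
        eaa = 0.5 * exposure + 2.0 * sex + rng.normal(0, 1, n)
        beta, se, _ = associate_eaa(eaa, exposure, covariates=sex)
        assert abs(beta - 0.5) < 4 * se


class TestCiWidthSummary:
    def test_single_fit_width(self):
        out = ci_width_summary({"m": [(1.0, 0.25, 0.01)]})
        assert out["m"] == pytest.approx(2 * Z_975 * 0.25)

    def test_mean_of_identical_fits(self):
        fits = [(1.0, 0.3, 0.5), (2.0, 0.3, 0.5)]
        out = ci_width_summary({"m": fits})
        assert out["m"] == pytest.approx(2 * Z_975 * 0.3)

    def test_monotone_in_residual_noise(self):
        rng = np.random.default_rng(7)
        fits = {"noisy": [], "quiet": []}
        for s in range(10):
            exposure = rng.normal(size=200)
            for label, sd in (("noisy", 4.0), ("quiet", 2.0)):
                eaa = 0.5 * exposure + rng.normal(0, sd, 200)
                fits[label].append(associate_eaa(eaa, exposure))
        widths = ci_width_summary(fits)
        assert widths["quiet"] < widths["noisy"]

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            ci_width_summary({"m": []})
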