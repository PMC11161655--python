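"""Rank correlations, group contrasts, Fisher z, and bootstrap mediation."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ctrlred import (
    assign_age_group,
    bonferroni,
    group_compare,
    mediate,
    partial_spearman,
    residualize_on,
    sex_correlation_contrast,
)
from ctrlred.errors import (
    DegenerateInputError,
    DiagnosticsError,
    DivergenceError,
    ValidationError,
)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni(0.002, 17) == pytest.approx(0.034)
        assert bonferroni(0.2, 17) == 1.0
        assert bonferroni(0.03, 1) == 0.03

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 100))
    def test_adjustment_bounds_and_monotonicity(self, p, m):
        adj = bonferroni(p, m)
        assert p <= adj <= 1.0
        assert bonferroni(p, m + 1) >= adj

    def test_vector_and_validation(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.5], 3), [0.03, 1.0])
        with pytest.raises(ValidationError):
            bonferroni(1.5, 2)


class TestPartialSpearman:
    def test_monotone_relationship_is_perfect(self, rng):
        x = rng.normal(size=50)
        r = partial_spearman(x, np.exp(x))
        assert r.rho == pytest.approx(1.0)

    def test_no_covariates_equals_plain_spearman(self, rng):
        x, y = rng.normal(size=(2, 80))
        r = partial_spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(rho) and r.p_raw == pytest.approx(p)

    def test_covariate_absorbs_outcome(self, rng):
        n = 480
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        r = partial_spearman(x, z, covariates=z[:, None])
        assert abs(r.rho) < 0.05

    def test_matches_pingouin_partial_corr_on_ranks(self, rng):
        n = 120
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.4 * z + 0.3 * x + rng.normal(size=n)
        ours = partial_spearman(x, y, covariates=z[:, None])
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(df, x="x", y="y", covar=["z"], method="spearman")
        assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_injected_correlation_recovered(self, rng):
        n = 480
        target = -0.3
        pearson = 2 * np.sin(target * np.pi / 6)  # Spearman -> Pearson for normals
        cov = [[1.0, pearson], [pearson, 1.0]]
        x, y = rng.multivariate_normal([0, 0], cov, size=n).T
        r = partial_spearman(x, y)
        assert r.rho == pytest.approx(target, abs=0.1)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            partial_spearman(np.ones(20), np.arange(20.0))


class TestGroupCompare:
    def test_age_cut_boundary(self):
        groups = assign_age_group([64.9, 65.0, 40.0, 89.9])
        assert groups.tolist() == ["middle", "old", "middle", "old"]

    def test_detects_large_shift(self, rng):
        y = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        g = ["a"] * 100 + ["b"] * 100
        for method in ("welch_anova", "ancova"):
            res = group_compare(y, g, method=method, family_size=15)
            assert res.p_adjusted < 0.05

    def test_ancova_adjusts_for_covariate(self, rng):
        # group difference explained entirely by the covariate
        z = np.concatenate([rng.normal(0, 1, 150), rng.normal(2, 1, 150)])
        y = 1.5 * z + rng.normal(0, 1, 300)
        g = ["a"] * 150 + ["b"] * 150
        raw = group_compare(y, g, method="welch_anova")
        adj = group_compare(y, g, covariates=pd.DataFrame({"z": z}),
                            method="ancova")
        assert raw.p_raw < 0.001 and adj.p_raw > 0.01

    def test_welch_type_one_error_in_binomial_band(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y = rng.normal(size=60)
            res = group_compare(y, ["a"] * 30 + ["b"] * 30, method="welch_anova")
            rejections += res.p_raw < 0.05
        lo, hi = sps.binom.ppf([0.025, 0.975], reps, 0.05)
        assert lo <= rejections <= hi

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            group_compare(np.arange(5.0), ["a"] * 5)


class TestFisherContrast:
    def test_equal_correlations_null(self):
        z, p = sex_correlation_contrast(0.4, 50, 0.4, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # atanh(0.5) = 0.5493; z = 0.5493 / sqrt(2/100) = 3.884
        z, p = sex_correlation_contrast(0.5, 103, 0.0, 103)
        assert z == pytest.approx(3.884, abs=1e-3)
        assert p < 0.001

    def test_antisymmetry(self):
        z1, p1 = sex_correlation_contrast(0.6, 80, 0.2, 120)
        z2, p2 = sex_correlation_contrast(0.2, 120, 0.6, 80)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(DivergenceError):
            sex_correlation_contrast(1.0, 50, 0.0, 50)


class TestResidualize:
    def test_exact_linear_gives_zero(self):
        x = np.arange(30.0)
        np.testing.assert_allclose(residualize_on(3.0 * x + 7.0, x), 0.0,
                                   atol=1e-10)

    def test_orthogonal_regressor_centers(self, rng):
        x = np.tile([-1.0, 1.0], 25)
        y = rng.normal(size=50)
        y -= (y @ x) / (x @ x) * x  # make exactly orthogonal
        np.testing.assert_allclose(residualize_on(y, x), y - y.mean(),
                                   atol=1e-10)

    def test_residuals_orthogonal_to_regressor(self, rng):
        x, y = rng.normal(size=(2, 100))
        r = residualize_on(y, x)
        assert abs(r @ x) < 1e-10

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValidationError):
            residualize_on(np.arange(10.0), np.ones(10))


def _mediation_data(rng, n=480, a=0.5, b=0.5, c_prime=0.0, noise=1.0):
    x = rng.normal(size=n)
    m = a * x + rng.normal(0, noise, n)
    y = b * m + c_prime * x + rng.normal(0, noise, n)
    return x, m, y


class TestMediation:
    def test_path_algebra_identity(self, rng):
        """a*b + c' == c exactly for nested OLS with shared covariates."""
        x, m, y = _mediation_data(rng)
        z = rng.normal(size=480)
        res = mediate(x, m, y, covariates=z[:, None], n_boot=100, seed=0)
        assert res.a * res.b + res.c_prime == pytest.approx(res.c_total,
                                                            abs=1e-8)

    def test_seeded_bootstrap_reproducible(self, rng):
        x, m, y = _mediation_data(rng, n=100)
        r1 = mediate(x, m, y, n_boot=500, seed=42)
        r2 = mediate(x, m, y, n_boot=500, seed=42)
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)

    def test_ci_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (60, 2000):
            x, m, y = _mediation_data(rng, n=n)
            r = mediate(x, m, y, n_boot=1000, seed=1)
            widths.append(r.ci_upper - r.ci_lower)
        assert widths[1] < widths[0]

    def test_point_estimate_contained_in_ci(self, rng):
        x, m, y = _mediation_data(rng)
        r = mediate(x, m, y, n_boot=2000, seed=3)
        assert r.ci_lower - 0.02 <= r.indirect <= r.ci_upper + 0.02

    def test_matches_pingouin_point_estimates(self, rng):
        x, m, y = _mediation_data(rng, n=150)
        ours = mediate(x, m, y, n_boot=200, seed=5)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        ref = pg.mediation_analysis(data=df, x="x", m="m", y="y", n_boot=200,
                                    seed=5)
        ref = ref.set_index("path")["coef"]
        assert ours.a == pytest.approx(float(ref["m ~ X"]), abs=1e-8)
        assert ours.c_total == pytest.approx(float(ref["Total"]), abs=1e-8)
        assert ours.c_prime == pytest.approx(float(ref["Direct"]), abs=1e-8)
        # product-of-paths indirect effect (== Total - Direct for one mediator)
        assert ours.indirect == pytest.approx(float(ref["Indirect"]), abs=1e-8)

    def test_null_b_path_centers_indirect_on_zero(self, rng):
        ests = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.normal(size=480)
            m = 0.5 * x + r.normal(size=480)
            y = r.normal(size=480)  # independent of m given x
            ests.append(mediate(x, m, y, n_boot=100, seed=seed).indirect)
        assert abs(np.mean(ests)) < 0.05

    def test_collinear_mediator_rejected(self, rng):
        x, m, y = _mediation_data(rng, n=100)
        with pytest.raises(DiagnosticsError):
            mediate(x, m, y, covariates=m[:, None], n_boot=100, seed=0)

    def test_too_few_cases_rejected(self, rng):
        x, m, y = _mediation_data(rng, n=20)
        with pytest.raises(ValidationError):
            mediate(x, m, y, n_boot=100)
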