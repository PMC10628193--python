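import numpy as np
import pytest

from connpls import pls, synthetic
from connpls.io_model import SchemaError
from helpers import grid_search_max_covariance, pearson


def _standardize(m):
    return (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)


class TestFitPls:
    def test_identical_blocks(self, rng):
        x = _standardize(rng.standard_normal((20, 2)))
        model = pls.fit_pls(x, x.copy())
        np.testing.assert_allclose(model.composite_x[:, 0], model.composite_y[:, 0], atol=1e-10)
        assert pearson(model.composite_x[:, 0], model.composite_y[:, 0]) == pytest.approx(1.0)

    def test_diagonal_cross_covariance(self):
        # orthogonal design with R = diag(1, 0.5): saliences are axes and
        # covariance explained is (0.8, 0.2)
        x1 = np.array([1.0, 1.0, -1.0, -1.0])
        x2 = np.array([1.0, -1.0, 1.0, -1.0])
        x3 = np.array([1.0, -1.0, -1.0, 1.0])
        X = np.column_stack([x1, x2]) * np.sqrt(3.0 / 4.0)  # sd(ddof=1)=1 scaling
        Y = np.column_stack([x1, 0.5 * x2 + np.sqrt(0.75) * x3]) * np.sqrt(3.0 / 4.0)
        X = _standardize(X)
        Y = _standardize(Y)
        model = pls.fit_pls(X, Y)
        np.testing.assert_allclose(np.abs(model.saliences_y), np.eye(2), atol=1e-10)
        np.testing.assert_allclose(np.abs(model.saliences_x), np.eye(2), atol=1e-10)
        np.testing.assert_allclose(model.covariance_explained, [0.8, 0.2], atol=1e-10)

    def test_grid_search_oracle_single_instance(self, rng):
        x = _standardize(rng.standard_normal((8, 5)))
        y = _standardize(rng.standard_normal((8, 3)))
        model = pls.fit_pls(x, y)
        r = y.T @ x / 7.0
        val, u, v = grid_search_max_covariance(r)
        assert model.singular_values[0] == pytest.approx(val, abs=1e-3)
        assert abs(np.dot(model.saliences_y[:, 0], u)) > np.cos(np.deg2rad(2.0))
        assert abs(np.dot(model.saliences_x[:, 0], v)) > np.cos(np.deg2rad(2.0))

    def test_unstandardized_input_warns(self, rng):
        x = rng.standard_normal((15, 3)) * 5 + 2
        y = rng.standard_normal((15, 2))
        with pytest.warns(UserWarning):
            pls.fit_pls(x, y)

    def test_constant_column_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        x[:, 1] = 4.0
        with pytest.raises(ValueError):
            pls.fit_pls(x, rng.standard_normal((10, 2)))

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            pls.fit_pls(rng.standard_normal((2, 3)), rng.standard_normal((2, 2)))

    def test_sign_convention_idempotent(self, rng):
        x = _standardize(rng.standard_normal((25, 4)))
        y = _standardize(rng.standard_normal((25, 3)))
        model = pls.fit_pls(x, y)
        sal_x, sal_y = model.saliences_x.copy(), model.saliences_y.copy()
        pls._apply_sign_convention(sal_x, sal_y)
        np.testing.assert_array_equal(sal_x, model.saliences_x)
        np.testing.assert_array_equal(sal_y, model.saliences_y)
        for k in range(model.n_lvs):
            col = model.saliences_y[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_loadings_are_column_correlations(self, rng):
        x = _standardize(rng.standard_normal((30, 4)))
        y = _standardize(rng.standard_normal((30, 3)))
        model = pls.fit_pls(x, y)
        for j in range(3):
            assert model.loadings_y[j, 0] == pytest.approx(
                pearson(y[:, j], model.composite_y[:, 0])
            )


class TestCovarianceExplained:
    def test_example(self):
        np.testing.assert_allclose(
            pls.covariance_explained([2.0, 1.0, 1.0]), [4 / 6, 1 / 6, 1 / 6]
        )

    def test_single_value(self):
        np.testing.assert_allclose(pls.covariance_explained([3.0]), [1.0])

    def test_scale_invariance(self, rng):
        s = np.sort(rng.random(5))[::-1]
        np.testing.assert_allclose(
            pls.covariance_explained(s), pls.covariance_explained(7.0 * s), atol=1e-14
        )

    def test_sums_to_one(self, rng):
        s = rng.random(8)
        assert pls.covariance_explained(s).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum(self):
        with pytest.raises(ValueError):
            pls.covariance_explained([0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pls.covariance_explained([1.0, -0.1])


class TestPermutationTest:
    def test_add_one_formula_minimum(self):
        c = synthetic.generate_cohort(300, 7, 5, latent_strength=0.8, seed=21)
        p, q = pls.permutation_test_lvs(
            c.edges.values, c.behavior.values, n_perm=200, seed=0
        )
        assert p[0] == pytest.approx(1.0 / 201.0)
        assert q[0] <= 0.05
        assert np.all(p > 0)

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ValueError):
            pls.permutation_test_lvs(
                rng.standard_normal((20, 3)), rng.standard_normal((20, 2)), n_perm=5
            )

    def test_reproducible(self, null_cohort):
        kw = dict(n_perm=50, seed=3)
        p1, _ = pls.permutation_test_lvs(null_cohort.edges.values, null_cohort.behavior.values, **kw)
        p2, _ = pls.permutation_test_lvs(null_cohort.edges.values, null_cohort.behavior.values, **kw)
        np.testing.assert_array_equal(p1, p2)

    def test_confound_contamination_detected_then_removed(self):
        # confound-driven cross-block structure inflates LV1 unless the data
        # are residualized first
        from connpls.preprocess import apply_residualizer, fit_residualizer

        c = synthetic.generate_cohort(
            250, 7, 5, latent_strength=0.0,
            confound_effects=(4.0, 4.0, 4.0, 4.0), seed=31,
        )
        conf = c.behavior.confounds
        p_raw, _ = pls.permutation_test_lvs(c.edges.values, c.behavior.values, n_perm=200, seed=1)
        rx = fit_residualizer(c.edges.values, conf)
        ry = fit_residualizer(c.behavior.values, conf)
        x = apply_residualizer(rx, c.edges.values, conf)
        y = apply_residualizer(ry, c.behavior.values, conf)
        p_res, _ = pls.permutation_test_lvs(x, y, n_perm=200, seed=1)
        assert p_raw[0] < 0.01
        assert p_res[0] > 0.05


class TestBootstrap:
    def test_duplicated_columns_zero_sd(self, rng):
        x = _standardize(rng.standard_normal((40, 3)))
        ycol = rng.standard_normal(40)
        y = _standardize(np.column_stack([ycol, ycol]))
        model = pls.fit_pls(x, y)
        boot = pls.bootstrap_loadings(x, y, model, n_boot=50, seed=4)
        np.testing.assert_allclose(boot.loading_sd_y[:, 0], 0.0, atol=1e-10)

    def test_sign_flip_invariance(self, planted_cohort, std):
        x = std(planted_cohort.edges.values)
        y = std(planted_cohort.behavior.values)
        model = pls.fit_pls(x, y)
        flipped = pls.PlsModel.from_dict(model.to_dict())
        flipped.saliences_x = -flipped.saliences_x
        flipped.saliences_y = -flipped.saliences_y
        a = pls.bootstrap_loadings(x, y, model, n_boot=30, seed=5)
        b = pls.bootstrap_loadings(x, y, flipped, n_boot=30, seed=5)
        np.testing.assert_allclose(a.loading_sd_y, b.loading_sd_y, atol=1e-12)

    def test_planted_support_z_scores(self):
        c = synthetic.generate_cohort(
            400, 7, 6, latent_strength=0.8, support_fraction_y=0.5, seed=41
        )
        x = _standardize(c.edges.values)
        y = _standardize(c.behavior.values)
        model = pls.fit_pls(x, y)
        boot = pls.bootstrap_loadings(x, y, model, n_boot=200, seed=6)
        support = c.true_salience_y != 0
        assert np.all(np.abs(boot.bootstrap_z_y[support, 0]) > 3.0)
        assert np.all(np.abs(boot.bootstrap_z_y[~support, 0]) < 3.0)


class TestCrossValidate:
    def test_planted_signal_generalizes(self):
        c = synthetic.generate_cohort(400, 7, 5, latent_strength=0.8, seed=51)
        cv = pls.cross_validate(
            c.edges.values, c.behavior.values, c.behavior.confounds,
            folds=10, repetitions=5, n_perm_cv=100, seed=7,
        )
        assert cv.mean_test_r[0] > 0.3
        assert cv.permuted_p[0] <= 0.01

    def test_null_cohort_centered(self, null_cohort):
        cv = pls.cross_validate(
            null_cohort.edges.values, null_cohort.behavior.values,
            null_cohort.behavior.confounds,
            folds=10, repetitions=10, n_perm_cv=50, seed=8,
        )
        # single-cohort mean r is noisy; the tight ±0.05 bound is asserted on
        # a multi-cohort average in the acceptance suite
        assert abs(cv.mean_test_r[0]) < 0.15
        assert cv.permuted_p[0] > 0.05

    def test_small_fold_rejected(self, rng):
        with pytest.raises(ValueError):
            pls.cross_validate(
                rng.standard_normal((12, 4)), rng.standard_normal((12, 3)), None,
                folds=10, repetitions=1, n_perm_cv=0,
            )

    def test_reproducible(self, null_cohort):
        kw = dict(folds=5, repetitions=2, n_perm_cv=0, seed=9)
        a = pls.cross_validate(null_cohort.edges.values, null_cohort.behavior.values, None, **kw)
        b = pls.cross_validate(null_cohort.edges.values, null_cohort.behavior.values, None, **kw)
        np.testing.assert_array_equal(a.fold_correlations, b.fold_correlations)


class TestProject:
    def test_training_projection_identity(self, rng):
        x = _standardize(rng.standard_normal((30, 5)))
        y = _standardize(rng.standard_normal((30, 3)))
        model = pls.fit_pls(x, y)
        out = pls.project(model, x, y, n_perm=20, seed=1)
        np.testing.assert_allclose(out["composite_x"], model.composite_x, atol=1e-12)
        np.testing.assert_allclose(out["composite_y"], model.composite_y, atol=1e-12)

    def test_second_cohort_same_latent(self):
        c = synthetic.generate_cohort(600, 7, 5, latent_strength=0.8, seed=61)
        half = 300
        xa, ya = _standardize(c.edges.values[:half]), _standardize(c.behavior.values[:half])
        xb, yb = _standardize(c.edges.values[half:]), _standardize(c.behavior.values[half:])
        model = pls.fit_pls(xa, ya)
        out = pls.project(model, xb, yb, n_perm=200, seed=2)
        assert out["r"][0] > 0.3
        assert out["p"][0] <= 0.01

    def test_null_second_cohort(self, null_cohort, std):
        half = 100
        x = std(null_cohort.edges.values)
        y = std(null_cohort.behavior.values)
        model = pls.fit_pls(x[:half], y[:half])
        out = pls.project(model, x[half:], y[half:], n_perm=200, seed=3)
        assert abs(out["r"][0]) < 0.25
        assert out["p"][0] > 0.05

    def test_dimension_mismatch(self, rng):
        x = _standardize(rng.standard_normal((20, 4)))
        y = _standardize(rng.standard_normal((20, 3)))
        model = pls.fit_pls(x, y)
        with pytest.raises(SchemaError):
            pls.project(model, rng.standard_normal((10, 5)), rng.standard_normal((10, 3)), n_perm=10)


class TestCompareModels:
    def test_self_comparison(self, rng):
        x = _standardize(rng.standard_normal((25, 4)))
        y = _standardize(rng.standard_normal((25, 3)))
        model = pls.fit_pls(x, y)
        out = pls.compare_models(model, model)
        assert out["salience_y_r"] == pytest.approx(1.0)
        assert out["loading_x_r"] == pytest.approx(1.0)

    def test_sign_flip_alignment(self, rng):
        x = _standardize(rng.standard_normal((25, 4)))
        y = _standardize(rng.standard_normal((25, 3)))
        model = pls.fit_pls(x, y)
        flipped = pls.PlsModel.from_dict(model.to_dict())
        flipped.saliences_x = -flipped.saliences_x
        flipped.saliences_y = -flipped.saliences_y
        flipped.loadings_x = -flipped.loadings_x
        flipped.loadings_y = -flipped.loadings_y
        out = pls.compare_models(model, flipped)
        assert out["salience_y_r"] == pytest.approx(1.0)
        assert out["sign"] == -1.0

    def test_split_half_recovery(self):
        c = synthetic.generate_cohort(600, 7, 5, latent_strength=0.8, seed=71)
        half = 300
        a = pls.fit_pls(_standardize(c.edges.values[:half]), _standardize(c.behavior.values[:half]))
        b = pls.fit_pls(_standardize(c.edges.values[half:]), _standardize(c.behavior.values[half:]))
        out = pls.compare_models(a, b)
        assert out["salience_y_r"] > 0.8

    def test_mismatched_spaces(self, rng):
        x = _standardize(rng.standard_normal((20, 4)))
        a = pls.fit_pls(x, _standardize(rng.standard_normal((20, 3))))
        b = pls.fit_pls(x, _standardize(rng.standard_normal((20, 2))))
        with pytest.raises(SchemaError):
            pls.compare_models(a, b)


class TestFirstPrincipalComponent:
    def test_spiked_covariance(self, rng):
        direction = rng.standard_normal(5)
        direction /= np.linalg.norm(direction)
        scores = rng.standard_normal(300)
        y = np.outer(scores * 5, direction) + rng.standard_normal((300, 5)) * 0.3
        pc, _ = pls.first_principal_component(y)
        assert abs(np.dot(pc, direction)) > 0.99

    def test_self_correlation(self, rng):
        y = rng.standard_normal((50, 4))
        pc, _ = pls.first_principal_component(y)
        pc2, r = pls.first_principal_component(y, salience=pc)
        assert r == pytest.approx(1.0)

    def test_isotropic_returns_unit_vector(self, rng):
        pc, _ = pls.first_principal_component(rng.standard_normal((100, 4)))
        assert np.linalg.norm(pc) == pytest.approx(1.0)


class TestInvariants:
    def test_oracle_equivalence_batch(self, rng):
        # leading salience pair attains the grid-search maximum of u'Rv
        for _ in range(5):
            n = int(rng.integers(4, 11))
            e = int(rng.integers(2, 7))
            p = int(rng.integers(2, 5))
            x = _standardize(rng.standard_normal((n, e)))
            y = _standardize(rng.standard_normal((n, p)))
            model = pls.fit_pls(x, y)
            val, _, _ = grid_search_max_covariance(y.T @ x / (n - 1))
            assert model.singular_values[0] == pytest.approx(val, abs=1e-3)

    def test_covariance_explained_full_spectrum(self, rng):
        x = _standardize(rng.standard_normal((30, 6)))
        y = _standardize(rng.standard_normal((30, 4)))
        model = pls.fit_pls(x, y)
        assert model.covariance_explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reported_quantities_sign_invariant(self, rng):
        # flipping (salience_x_k, salience_y_k) together leaves singular
        # values, covariance explained and composite correlations unchanged
        x = _standardize(rng.standard_normal((30, 5)))
        y = _standardize(rng.standard_normal((30, 3)))
        model = pls.fit_pls(x, y)
        r_orig = [pearson(model.composite_x[:, k], model.composite_y[:, k]) for k in range(model.n_lvs)]
        flipped_x = x @ (-model.saliences_x)
        flipped_y = y @ (-model.saliences_y)
        r_flip = [pearson(flipped_x[:, k], flipped_y[:, k]) for k in range(model.n_lvs)]
        np.testing.assert_allclose(r_orig, r_flip, atol=1e-12)
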