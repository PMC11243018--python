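"""PCA, clustering and OPLS-DA: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import adjusted_rand_score

from svmscreen import (
    SyntheticConfig,
    generate_spiked_dataset,
    hcluster,
    make_two_class_data,
    oplsda_fit,
    pca,
    permutation_test,
    scale,
)


class TestScale:
    def test_unit_variance(self):
        xs = scale(np.array([[1.0], [2.0], [3.0]]), mode="uv")
        assert np.allclose(xs.x.ravel(), [-1, 0, 1])

    def test_center_only(self):
        xs = scale(np.array([[1.0], [2.0], [3.0]]), mode="none")
        assert np.allclose(xs.x.ravel(), [-1, 0, 1] / np.ones(1))
        assert np.allclose(xs.scales, 1.0)

    def test_pareto_divides_by_sqrt_sd(self):
        col = np.array([0.0, 4.0, 8.0, 4.0])  # sd = sqrt(32/3)
        xs = scale(col[:, None], mode="pareto")
        sd = col.std(ddof=1)
        assert np.allclose(xs.x.ravel(), (col - col.mean()) / np.sqrt(sd))

    def test_constant_column_unit_factor(self):
        xs = scale(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.allclose(xs.x[:, 0], 0.0)
        assert xs.scales[0] == 1.0

    def test_invariants_after_uv(self, rng):
        x = rng.normal(size=(20, 7))
        xs = scale(x)
        assert np.allclose(xs.x.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(xs.x.var(axis=0, ddof=1), 1, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            scale(np.empty((0, 3)))
        with pytest.raises(ValueError):
            scale(np.array([[1.0, 2.0]]))


class TestPca:
    def test_duplicated_samples_get_identical_scores(self, rng):
        x = rng.normal(size=(4, 5))
        x = np.vstack([x, x[0]])
        model = pca(scale(x, mode="none"), 2)
        assert np.allclose(model.scores[0], model.scores[-1])

    def test_matches_eigendecomposition(self, rng):
        x = rng.normal(size=(4, 3))
        xs = scale(x, mode="none")
        model = pca(xs, 2)
        cov = xs.x.T @ xs.x
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for i in range(2):
            v = evecs[:, order[i]]
            got = model.loadings[:, i]
            assert np.allclose(np.abs(got @ v), 1.0, atol=1e-8)
            assert np.allclose(
                np.abs(model.scores[:, i]), np.abs(xs.x @ v), atol=1e-8
            )

    def test_loadings_orthonormal_scores_orthogonal(self, rng):
        xs = scale(rng.normal(size=(10, 6)))
        m = pca(xs, 3)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(3), atol=1e-8)
        assert abs(m.scores[:, 0] @ m.scores[:, 1]) < 1e-8
        assert np.all(np.diff(m.r2x) <= 1e-12)

    def test_groups_separate_on_first_component(self, small_dataset):
        table, _ = small_dataset
        spiked = [s for s in table.sample_ids if table.samples.loc[s, "group"] != "QC"]
        xs = scale(table.intensities.loc[table.feature_ids, spiked].T)
        model = pca(xs, 2)
        t1 = model.scores[:, 0]
        groups = table.samples.loc[spiked, "group"].to_numpy()
        # between-group spread dominates within-group spread along t1
        means = {g: t1[groups == g].mean() for g in set(groups)}
        within = max(t1[groups == g].std() for g in set(groups))
        spread = max(means.values()) - min(means.values())
        assert spread > 2 * within

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca(scale(rng.normal(size=(4, 3))), 4)


class TestHcluster:
    def test_close_pairs_merge_first(self):
        x = np.array([[0.0, 0], [0.1, 0], [10, 10], [10.1, 10]])
        tree, _ = hcluster(scale(x, mode="none"), linkage="single")
        first_two = {int(tree[0, 0]), int(tree[0, 1]), int(tree[1, 0]), int(tree[1, 1])}
        assert first_two == {0, 1, 2, 3}

    def test_recovers_concentration_groups(self, default_calibrated):
        calibrated, _ = default_calibrated
        table = calibrated.table
        spiked = [s for s in table.sample_ids if table.samples.loc[s, "group"] != "QC"]
        xs = scale(table.intensities.loc[table.feature_ids, spiked].T)
        _, labels = hcluster(xs, k=3)
        truth = table.samples.loc[spiked, "group"].to_numpy()
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_invalid_inputs_rejected(self, rng):
        xs = scale(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            hcluster(xs, linkage="bogus")
        with pytest.raises(ValueError):
            hcluster(xs, metric="bogus")


def _separable(seed=0, n=12, p=6):
    """One variable equal to the labels; the rest exactly y-orthogonal.

    "No noise" here means no chance correlation between the nuisance
    variables and the response.
    """
    rng = np.random.default_rng(seed)
    y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
    x = rng.normal(size=(n, p))
    x -= np.outer(y, y @ x) / (y @ y)  # project nuisance columns off y
    x[:, 0] = y  # one variable carries the labels exactly
    return x, y


class TestOplsDa:
    def test_perfect_predictor_gives_r2y_one(self):
        x, y = _separable()
        model = oplsda_fit(scale(x), y)
        assert model.r2y == pytest.approx(1.0, abs=5e-3)

    def test_without_orthogonal_components_reduces_to_pls1(self, rng):
        x = rng.normal(size=(14, 8))
        y = np.sign(rng.normal(size=14))
        y[: 7] = -1.0
        y[7:] = 1.0
        xs = scale(x)
        model = oplsda_fit(xs, y, n_orthogonal=0)
        pls = PLSRegression(n_components=1, scale=False).fit(xs.x, y - y.mean())
        ref = pls.x_scores_.ravel()
        got = model.scores
        sign = np.sign(ref @ got)
        assert np.allclose(got, sign * ref, atol=1e-8)

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            oplsda_fit(scale(x), np.ones(6))

    def test_q2_bounded_by_r2y_on_training_data(self, rng):
        for seed in range(5):
            x, y = make_two_class_data(9, 30, 5, 2.0, seed=seed)
            model = oplsda_fit(scale(x), y)
            assert model.q2 <= model.r2y + 1e-6

    def test_random_labels_on_noise_give_nonpositive_q2(self):
        # at the study's matrix shape (36 samples, ~1450 variables)
        neg = 0
        n_draws = 20
        for seed in range(n_draws):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(36, 1447))
            y = rng.permutation([-1] * 18 + [1] * 18)
            model = oplsda_fit(scale(x), y)
            neg += model.q2 <= 0
        assert neg >= 0.9 * n_draws

    def test_loo_q2_on_separable_data(self):
        # noise-free: every variable is an exact multiple of the class pattern
        y = np.array([-1.0] * 7 + [1.0] * 7)
        coef = np.array([0.5, 1.0, -2.0, 3.0, 1.5])
        x = np.outer(y, coef)
        model = oplsda_fit(scale(x), y, cv_folds=len(y))
        assert model.q2 >= 0.99

    def test_vip_mean_square_is_one(self, rng):
        for seed in range(5):
            x, y = make_two_class_data(8, 25, 4, 2.0, seed=seed)
            model = oplsda_fit(scale(x), y)
            assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-6)

    def test_vip_matches_bruteforce_formula(self, rng):
        x = rng.normal(size=(10, 6))
        y = np.array([-1] * 5 + [1] * 5)
        model = oplsda_fit(scale(x), y)
        w = model.weights
        expected = np.sqrt(len(w) * (w / np.linalg.norm(w)) ** 2)
        assert np.allclose(model.vip, expected)

    def test_vip_symmetry_and_concentration(self):
        # equal |weights| -> all VIP 1; all weight on one variable -> sqrt(p)
        from svmscreen.multivariate import OplsModel, vip

        p = 4
        equal = OplsModel(
            weights=np.ones(p) / np.sqrt(p), scores=np.zeros(2),
            loadings=np.zeros(p), q_coef=1.0,
        )
        assert np.allclose(vip(equal), 1.0)
        single = OplsModel(
            weights=np.eye(p)[0], scores=np.zeros(2),
            loadings=np.zeros(p), q_coef=1.0,
        )
        assert vip(single)[0] == pytest.approx(np.sqrt(p))

    def test_splot_cov_and_corr_share_signs(self, rng):
        x, y = make_two_class_data(10, 30, 6, 2.0, seed=1)
        model = oplsda_fit(scale(x), y)
        s = model.splot
        nz = s["p1"].abs() > 1e-12
        assert (np.sign(s.loc[nz, "p1"]) == np.sign(s.loc[nz, "pcorr1"])).all()
        assert (s["pcorr1"].abs() <= 1 + 1e-9).all()


class TestPermutationTest:
    def test_separated_classes_pass_q2_rules(self):
        x, y = make_two_class_data(18, 200, 20, 3.0, seed=0)
        res = permutation_test(scale(x), y, n_iter=100, seed=0)
        assert res.q2_intercept <= 0.05
        assert res.p_value < 0.05
        assert res.overfit_free

    def test_pure_noise_fails_validity(self):
        invalid = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=(16, 30))
            y = np.array([-1] * 8 + [1] * 8)
            res = permutation_test(scale(x), y, n_iter=30, seed=seed)
            invalid += not res.valid
        assert invalid >= 0.9 * n_seeds

    def test_too_few_iterations_rejected(self):
        x, y = _separable()
        with pytest.raises(ValueError):
            permutation_test(scale(x), y, n_iter=5)

    def test_pvalue_definition(self):
        x, y = make_two_class_data(9, 40, 8, 3.0, seed=2)
        res = permutation_test(scale(x), y, n_iter=20, seed=1)
        n_ge = int((res.iterations["q2"] >= res.q2_original).sum())
        assert res.p_value == pytest.approx((1 + n_ge) / (len(res.iterations) + 1))
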