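import numpy as np
import pytest
from scipy import integrate
from scipy.spatial.distance import cdist

from surfppi.rvkde import (
    ClassDensityModel,
    RvkdeClassifier,
    RvkdeParams,
    density,
    dimension_constant,
    fit_density,
    log_density,
)


def brute_force_radii(X, ks):
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    return np.sort(D, axis=1)[:, ks - 1]


def brute_force_density(model, v):
    d2 = np.sum((model.instances - v) ** 2, axis=1)
    k = (np.sqrt(np.pi) * model.sigmas) ** (-model.m) * np.exp(
        -d2 / model.sigmas**2
    )
    return k.sum() / model.n


class TestFitDensity:
    def test_two_point_radii(self):
        m = fit_density(np.array([[0.0], [1.0]]), RvkdeParams(ks=1))
        np.testing.assert_allclose(m.radii, [1.0, 1.0])

    def test_duplicate_instances_floor_with_warning(self):
        X = np.zeros((4, 2))
        with pytest.warns(RuntimeWarning, match="floored"):
            m = fit_density(X, RvkdeParams(ks=2))
        assert np.all(m.sigmas > 0)

    def test_radii_match_brute_force(self, rng):
        X = rng.normal(size=(5, 2))
        m = fit_density(X, RvkdeParams(ks=2))
        np.testing.assert_allclose(m.radii, brute_force_radii(X, 2))

    def test_requires_more_instances_than_ks(self):
        with pytest.raises(ValueError, match="ks"):
            fit_density(np.zeros((3, 1)) + np.arange(3)[:, None], RvkdeParams(ks=3))

    def test_beta_scales_bandwidths_proportionally(self, rng):
        X = rng.normal(size=(10, 3))
        m1 = fit_density(X, RvkdeParams(beta=1.0, ks=2))
        m2 = fit_density(X, RvkdeParams(beta=2.5, ks=2))
        np.testing.assert_allclose(m2.sigmas, 2.5 * m1.sigmas)


class TestDensity:
    def test_unit_integral_single_instance_1d(self):
        model = ClassDensityModel(
            instances=np.array([[0.0]]),
            radii=np.array([1.0]),
            sigmas=np.array([1.0]),
            params=RvkdeParams(ks=1),
        )
        val, _ = integrate.quad(lambda x: density(model, np.array([x])), -10, 10)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_kernel_maximum_closed_form(self):
        sigma = 0.7
        model = ClassDensityModel(
            instances=np.array([[1.0, 2.0]]),
            radii=np.array([1.0]),
            sigmas=np.array([sigma]),
            params=RvkdeParams(ks=1),
        )
        expected = (np.sqrt(np.pi) * sigma) ** (-2)
        assert density(model, np.array([1.0, 2.0])) == pytest.approx(expected)

    def test_kt_all_matches_brute_force(self, rng):
        X = rng.normal(size=(30, 4))
        model = fit_density(X, RvkdeParams(ks=3))
        for _ in range(100):
            v = rng.normal(size=4)
            assert density(model, v, kt="all") == pytest.approx(
                brute_force_density(model, v), rel=1e-10
            )

    def test_kt_truncation_monotone_in_kt(self, rng):
        X = rng.normal(size=(25, 3))
        model = fit_density(X, RvkdeParams(ks=2))
        for _ in range(10):
            v = rng.normal(size=3)
            vals = [density(model, v, kt=kt) for kt in range(1, 26)]
            assert np.all(np.diff(vals) >= -1e-15)
            assert vals[-1] == pytest.approx(density(model, v, kt="all"))

    def test_equal_radii_reduce_to_fixed_bandwidth_kde(self, rng):
        # grid instances so every ks-NN radius is identical
        X = np.array([[float(i)] for i in range(8)])
        model = fit_density(X, RvkdeParams(ks=1))
        np.testing.assert_allclose(model.radii, 1.0)
        sigma = model.sigmas[0]
        from scipy.stats import norm

        for v in (-1.3, 0.0, 2.7, 9.1):
            fixed = norm.pdf(v, loc=X[:, 0], scale=sigma / np.sqrt(2)).mean()
            assert density(model, np.array([v])) == pytest.approx(fixed, rel=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_density(rng.normal(size=(5, 3)), RvkdeParams(ks=2))
        with pytest.raises(ValueError, match="dimension"):
            log_density(model, np.zeros(4))

    def test_dimension_constant_positive(self):
        for m in (1, 2, 10, 686):
            for ks in (1, 5, 50):
                assert dimension_constant(m, ks) > 0


class TestClassifier:
    def test_symmetric_tie_goes_to_non_interacting(self):
        X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        clf = RvkdeClassifier(RvkdeParams(beta=1.0, ks=1), standardize=False).fit(X, y)
        label, ll = clf.classify(np.array([0.0]))
        assert ll[0] == pytest.approx(ll[1])
        assert label == 0

    def test_query_at_training_point_of_isolated_class(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(8, 0.1, (10, 2))])
        y = np.array([1] * 10 + [0] * 10)
        clf = RvkdeClassifier(RvkdeParams(beta=1.0, ks=2)).fit(X, y)
        assert clf.predict(X[:1])[0] == 1

    def test_two_gaussian_problem_accuracy(self, rng):
        n = 100
        X = np.vstack(
            [rng.normal(0, 1.0, (n, 2)), rng.normal(5.0, 1.0, (n, 2))]
        )
        y = np.array([0] * n + [1] * n)
        idx = rng.permutation(2 * n)
        X, y = X[idx], y[idx]
        clf = RvkdeClassifier(RvkdeParams(beta=1.0, ks=5, kt=20)).fit(
            X[:140], y[:140]
        )
        acc = (clf.predict(X[140:]) == y[140:]).mean()
        assert acc > 0.9

    def test_labels_stable_over_beta_range(self, rng):
        # well-separated classes: doubling beta must not flip labels
        n = 30
        X = np.vstack([rng.normal(0, 0.5, (n, 2)), rng.normal(6, 0.5, (n, 2))])
        y = np.array([0] * n + [1] * n)
        Q = rng.normal(3, 3, (40, 2))
        preds = []
        for beta in (0.5, 1.0):
            clf = RvkdeClassifier(RvkdeParams(beta=beta, ks=3)).fit(X, y)
            preds.append(clf.predict(Q))
        mismatch = (preds[0] != preds[1]).mean()
        assert mismatch <= 0.1

    def test_unfitted_classifier_rejected(self):
        clf = RvkdeClassifier(RvkdeParams())
        with pytest.raises(RuntimeError):
            clf.predict(np.zeros((1, 2)))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            RvkdeClassifier(RvkdeParams(ks=1)).fit(np.zeros((4, 2)), np.ones(4))

    @pytest.mark.parametrize(
        "kwargs", [{"beta": 0.0}, {"ks": 0}, {"kt": 0}, {"kt": "some"}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RvkdeParams(**kwargs)
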