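import math

import numpy as np
import pytest

from dvhpredict import (
    DistanceDoseSamples,
    KdeModel,
    conditional_density,
    fit_bandwidths,
    predict_dose_density,
    train_model,
)
from dvhpredict.errors import DegenerateTrainingError, ModelInputError


def double_sum_oracle(t_query, dose_axis, train_t, train_x, h_t, h_x, weights=None):
    """Literal double Gaussian kernel sum with reflection at x = 0."""
    w = np.ones_like(train_t) if weights is None else weights
    num = np.zeros_like(dose_axis)
    den = 0.0
    for ti, xi, wi in zip(train_t, train_x, w):
        kt = math.exp(-0.5 * ((t_query - ti) / h_t) ** 2)
        kx = (
            np.exp(-0.5 * ((dose_axis - xi) / h_x) ** 2)
            + np.exp(-0.5 * ((dose_axis + xi) / h_x) ** 2)
        ) / (h_x * math.sqrt(2 * math.pi))
        num = num + wi * kt * kx
        den += wi * kt
    return num / den


def make_model(t, x, h_t=None, h_x=None, **kw):
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if h_t is None or h_x is None:
        h_t, h_x = fit_bandwidths(t, x)
    return KdeModel(
        oar_class="test", train_t=t, train_x=x, h_t=h_t, h_x=h_x,
        n_train_plans=1, x_max=float(x.max()) * 1.2 + 5.0, **kw
    )


class TestBandwidths:
    def test_single_sample_raises(self):
        with pytest.raises(DegenerateTrainingError):
            fit_bandwidths(np.array([1.0]), np.array([2.0]))

    def test_zero_variance_names_coordinate(self):
        t = np.array([1.0, 1.0, 1.0])
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateTrainingError, match="distance"):
            fit_bandwidths(t, x)
        with pytest.raises(DegenerateTrainingError, match="dose"):
            fit_bandwidths(x, t)

    def test_reference_rule_closed_form(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=1000)
        t = (t - t.mean()) / np.std(t, ddof=1) * 2.0  # exact sample sd of 2.0
        x = rng.normal(10, 3, size=1000)
        h_t, _ = fit_bandwidths(t, x)
        assert h_t == pytest.approx(2.0 * 1000 ** (-1 / 6), rel=1e-12)
        assert h_t == pytest.approx(0.6325, abs=2e-4)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=200)
        x = rng.gamma(2, 5, size=200)
        h_t, h_x = fit_bandwidths(t, x)
        h_t2, h_x2 = fit_bandwidths(3.5 * t, x)
        assert h_t2 == pytest.approx(3.5 * h_t, rel=1e-12)
        assert h_x2 == pytest.approx(h_x, rel=1e-12)

    def test_lscv_runs_and_is_positive(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=300)
        x = 10 + 2 * t + rng.normal(size=300)
        h_t, h_x = fit_bandwidths(t, x, method="lscv")
        assert h_t > 0 and h_x > 0


class TestConditionalDensity:
    def test_single_pair_gaussian(self):
        model = make_model([0.0, 0.0], [30.0, 30.0], h_t=1.0, h_x=1.5)
        axis = np.arange(0, 50.001, 0.05)
        for tq in (-3.0, 0.0, 5.0):
            p = conditional_density(model, tq, axis)
            peak = axis[np.argmax(p)]
            assert peak == pytest.approx(30.0, abs=0.05)
            assert np.trapezoid(p, axis) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 201))
        t = rng.normal(10, 5, n)
        x = np.abs(rng.normal(20, 8, n))
        model = make_model(t, x)
        axis = np.arange(0, model.x_max + 1e-9, 0.25)
        tq = float(rng.uniform(-5, 25))
        expected = double_sum_oracle(tq, axis, t, x, model.h_t, model.h_x)
        np.testing.assert_allclose(conditional_density(model, tq, axis), expected, atol=1e-9)

    def test_weighted_double_sum_oracle(self):
        rng = np.random.default_rng(9)
        t = rng.normal(0, 3, 50)
        x = np.abs(rng.normal(15, 5, 50))
        w = rng.uniform(0.1, 2.0, 50)
        model = make_model(t, x, weights=w)
        axis = np.arange(0, model.x_max + 1e-9, 0.25)
        expected = double_sum_oracle(1.0, axis, t, x, model.h_t, model.h_x, weights=w)
        np.testing.assert_allclose(conditional_density(model, 1.0, axis), expected, atol=1e-9)

    def test_symmetry(self):
        model = make_model([0.0, 0.0], [10.0, 20.0], h_t=1.0, h_x=1.0)
        axis = np.arange(0, 30.001, 0.1)
        p = conditional_density(model, 0.0, axis)
        assert p[np.searchsorted(axis, 10.0)] == pytest.approx(p[np.searchsorted(axis, 20.0)], rel=1e-9)

    def test_far_query_clamped_not_zero(self):
        model = make_model([0.0, 1.0, 2.0], [10.0, 12.0, 14.0], h_t=0.5, h_x=1.0)
        axis = np.arange(0, 20.001, 0.1)
        p = conditional_density(model, 1e6, axis)
        assert np.isfinite(p).all() and p.max() > 0


class TestPredictDensity:
    def test_identical_queries_equal_conditional(self):
        rng = np.random.default_rng(4)
        model = make_model(rng.normal(5, 2, 50), np.abs(rng.normal(20, 5, 50)))
        dens = predict_dose_density(model, np.full(7, 3.0), dx=0.1, method="exact")
        cond = conditional_density(model, 3.0, dens.dose_axis)
        np.testing.assert_allclose(dens.density, cond / np.trapezoid(cond, dens.dose_axis), rtol=1e-9)

    def test_two_queries_arithmetic_mean(self):
        rng = np.random.default_rng(5)
        model = make_model(rng.normal(5, 2, 40), np.abs(rng.normal(20, 5, 40)))
        dens = predict_dose_density(model, np.array([2.0, 8.0]), dx=0.1, method="exact")
        c1 = conditional_density(model, 2.0, dens.dose_axis)
        c2 = conditional_density(model, 8.0, dens.dose_axis)
        mean = 0.5 * (c1 + c2)
        np.testing.assert_allclose(
            dens.density, mean / np.trapezoid(mean, dens.dose_axis), rtol=1e-9
        )

    @pytest.mark.parametrize("method", ["exact", "grid"])
    def test_normalized(self, method):
        rng = np.random.default_rng(6)
        model = make_model(rng.normal(10, 6, 500), np.abs(rng.normal(25, 10, 500)))
        dens = predict_dose_density(model, rng.normal(12, 6, 300), dx=0.1, method=method)
        assert dens.integral == pytest.approx(1.0, abs=1e-6)
        assert (dens.density >= 0).all()

    def test_empty_queries_raise(self):
        model = make_model([0.0, 1.0], [10.0, 12.0], h_t=1.0, h_x=1.0)
        with pytest.raises(ModelInputError):
            predict_dose_density(model, np.array([]))

    def test_grid_path_matches_exact(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(-10, 40, 2000)
        x = np.clip(50 / (1 + np.exp((t - 10) / 4)) + rng.normal(0, 1.5, t.size), 0, None)
        model = make_model(t, x)
        q = rng.uniform(-5, 35, 800)
        exact = predict_dose_density(model, q, dx=0.1, method="exact")
        grid = predict_dose_density(model, q, dx=0.1, method="grid")
        scale = exact.density.max()
        np.testing.assert_allclose(grid.density, exact.density, atol=5e-3 * scale)
        # derived mean doses agree tightly
        assert grid.mean() == pytest.approx(exact.mean(), abs=0.05)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        t = rng.normal(5, 3, 120)
        x = np.abs(rng.normal(20, 6, 120))
        model = make_model(t, x)
        perm = rng.permutation(120)
        model_p = make_model(t[perm], x[perm], h_t=model.h_t, h_x=model.h_x)
        q = rng.normal(5, 3, 30)
        d1 = predict_dose_density(model, q, method="exact")
        d2 = predict_dose_density(model_p, q, method="exact")
        np.testing.assert_allclose(d1.density, d2.density, atol=1e-12)

    def test_consistency_l1_decreases(self):
        """Predicted p(x|t0) approaches the true normal law as n grows."""
        t0, sigma = 5.0, 2.0
        mu = lambda t: 40.0 - 0.8 * t  # noqa: E731
        axis = np.arange(0, 60.001, 0.1)
        from scipy.stats import norm

        truth = norm.pdf(axis, mu(t0), sigma)
        medians = []
        for n in (100, 1000, 10000):
            l1s = []
            for seed in range(5):
                rng = np.random.default_rng(1000 * n + seed)
                t = rng.uniform(0, 10, n)
                x = np.clip(mu(t) + rng.normal(0, sigma, n), 0, None)
                model = make_model(t, x)
                p = conditional_density(model, t0, axis)
                l1s.append(np.trapezoid(np.abs(p - truth), axis))
            medians.append(np.median(l1s))
        assert medians[0] > medians[1] > medians[2]


class TestTrainModel:
    def _samples(self, rng, n, plan_id):
        t = rng.normal(10, 5, n)
        x = np.abs(rng.normal(20, 6, n))
        return DistanceDoseSamples(structure="s", plan_id=plan_id, t=t, x=x, voxel_volume=8.0)

    def test_pooling_counts(self):
        rng = np.random.default_rng(0)
        plans = [self._samples(rng, 100, "a"), self._samples(rng, 100, "b")]
        model = train_model(plans, "heart")
        assert model.n_train == 200
        assert model.n_train_plans == 2

    def test_dose_domain_headroom(self):
        rng = np.random.default_rng(1)
        model = train_model([self._samples(rng, 50, "a")], "heart", dx=0.1)
        assert model.x_max >= model.train_x.max() * 1.1 - 1e-9
        assert round(model.x_max / 0.1) == pytest.approx(model.x_max / 0.1, abs=1e-9)

    def test_zero_dose_variance_raises(self):
        s = DistanceDoseSamples(
            structure="s", plan_id="a", t=np.array([1.0, 2.0, 3.0]),
            x=np.zeros(3), voxel_volume=1.0,
        )
        with pytest.raises(DegenerateTrainingError):
            train_model([s], "heart")

    def test_empty_plan_list_raises(self):
        with pytest.raises(ModelInputError):
            train_model([], "heart")

    def test_deterministic_serialization(self):
        rng = np.random.default_rng(2)
        plans = [self._samples(rng, 60, "a")]
        m1 = train_model(plans, "lung")
        m2 = train_model(plans, "lung")
        assert m1.to_json() == m2.to_json()
        m3 = KdeModel.from_json(m1.to_json())
        np.testing.assert_array_equal(m3.train_t, m1.train_t)
        assert m3.h_t == m1.h_t and m3.x_max == m1.x_max

    def test_plan_equal_weighting(self):
        rng = np.random.default_rng(3)
        plans = [self._samples(rng, 10, "a"), self._samples(rng, 40, "b")]
        model = train_model(plans, "heart", plan_equal_weight=True)
        assert model.weights is not None
        assert model.weights[:10].sum() == pytest.approx(model.weights[10:].sum())
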