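"""Landscape reconstruction against closed-form and simulation oracles."""

import numpy as np
import pytest

from flexdec import landscape
from flexdec.landscape import (ChoiceAxis, aggregate_models, basin_metrics,
                               estimate_potential, make_grid)


class TestChoiceAxis:
    def _clusters(self, sep=4.0, n=200, n_units=12, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        direction = rng.normal(size=n_units)
        direction /= np.linalg.norm(direction)
        X = rng.normal(size=(n, n_units, 30))
        X += (sep * (y - 0.5))[:, None, None] * direction[None, :, None]
        return X, y

    def test_separated_clusters_classified(self):
        X, y = self._clusters()
        axis = ChoiceAxis(random_state=0).fit(X, y)
        assert axis.cv_accuracy_ > 0.95
        pos = axis.transform(X)[:, -1]
        # projections sign-separate by label
        side = pos > 0
        agreement = max(np.mean(side == (y == 1)), np.mean(side == (y == 0)))
        assert agreement > 0.95
        assert axis.reliable_

    def test_shuffled_labels_at_chance(self):
        X, y = self._clusters(seed=1)
        rng = np.random.default_rng(2)
        axis = ChoiceAxis(random_state=0).fit(X, rng.permutation(y))
        assert abs(axis.cv_accuracy_ - 0.5) < 0.12
        assert not axis.reliable_

    def test_axis_unit_norm_and_boundary_zero(self):
        X, y = self._clusters(seed=3)
        axis = ChoiceAxis(random_state=0).fit(X, y)
        assert np.linalg.norm(axis.axis_) == pytest.approx(1.0)
        # a PC-space point on the hyperplane projects to 0, and moving one
        # unit along the axis moves the projection by one
        p0 = -axis.offset_ * axis.axis_
        assert axis.project_points(p0[None, :])[0] == pytest.approx(0.0,
                                                                    abs=1e-9)
        assert axis.project_points((p0 + axis.axis_)[None, :])[0] == \
            pytest.approx(1.0, abs=1e-9)

    def test_projection_consistent_with_classifier_sign(self):
        X, y = self._clusters(seed=4)
        axis = ChoiceAxis(random_state=0).fit(X, y)
        late = axis.pca_.transform(X[:, :, -10:].mean(axis=2))
        pos = axis.project_points(late)
        pred_side = (pos > 0).astype(int)
        acc = np.mean(pred_side == y)
        assert max(acc, 1 - acc) > 0.9


class TestPotential:
    def test_constant_drift_linear_potential(self):
        rng = np.random.default_rng(0)
        g = 0.02          # drift per ms
        dt = 10.0
        n_trials, n_t = 4000, 30
        x0 = rng.uniform(-1, 1, n_trials)
        X = x0[:, None] + g * dt * np.arange(n_t)[None, :]
        times = np.arange(n_t) * dt
        land = estimate_potential(X, times, np.zeros(n_trials), n_bins=40)
        V = land.potential[0.0]
        centers = land.positions
        col = 5
        fin = np.isfinite(V[:, col]) & (np.abs(centers) > 1e-9)
        # deviation from -g*x below 1% of the potential range
        resid = V[fin, col] - (-g * centers[fin])
        assert np.max(np.abs(resid)) < 0.01 * np.ptp(-g * centers[fin])

    def test_ou_curvature_recovered(self):
        # dX = -k X dt + sigma dW  => V = k x^2 / 2
        rng = np.random.default_rng(1)
        k, sigma, dt = 0.01, 0.05, 10.0       # per-ms units
        n_trials, n_t = 10_000, 40
        X = np.empty((n_trials, n_t))
        X[:, 0] = rng.normal(0, sigma * np.sqrt(1 / (2 * k)), n_trials)
        for t in range(1, n_t):
            X[:, t] = X[:, t - 1] * (1 - k * dt) + \
                sigma * np.sqrt(dt) * rng.normal(size=n_trials)
        times = np.arange(n_t) * dt
        land = estimate_potential(X, times, np.zeros(n_trials), n_bins=30)
        V = np.nanmean(land.potential[0.0], axis=1)
        c = land.positions
        fin = np.isfinite(V)
        k_hat = np.polyfit(c[fin], V[fin], 2)[0] * 2
        assert k_hat == pytest.approx(k, rel=0.15)

    def test_double_well_minima(self):
        # drift toward +-x*: dX = -4 a X (X^2 - xstar^2) dt + noise
        rng = np.random.default_rng(2)
        xstar, a, dt = 1.0, 0.002, 10.0
        n_trials, n_t = 6000, 60
        X = np.empty((n_trials, n_t))
        X[:, 0] = rng.uniform(-1.6, 1.6, n_trials)
        for t in range(1, n_t):
            x = X[:, t - 1]
            X[:, t] = x - 4 * a * x * (x ** 2 - xstar ** 2) * dt + \
                0.03 * np.sqrt(dt) * rng.normal(size=n_trials)
        times = np.arange(n_t) * dt
        land = estimate_potential(X, times, np.zeros(n_trials), n_bins=40)
        V = np.nanmean(land.potential[0.0][:, 20:], axis=1)
        c = land.positions
        m = basin_metrics(V[:, None], c, np.array([0.0]), t_eval=0.0)
        assert m["depth_left"] > 0 and m["depth_right"] > 0
        assert m["separation"] == pytest.approx(2 * xstar, abs=0.4)

    def test_boundary_reference_exact_zero_limit(self):
        # V at the first bins adjacent to 0 tends to 0 as dx -> 0; the
        # boundary itself is the anchor: cumulative sums start there
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(2000, 10))
        land = estimate_potential(X, np.arange(10) * 10.0,
                                  np.zeros(2000), n_bins=80)
        V = land.potential[0.0]
        c = land.positions
        inner = np.argsort(np.abs(c))[:2]
        assert np.all(np.abs(V[inner, :][np.isfinite(V[inner, :])])
                      < 0.05 * np.nanmax(np.abs(V)))

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(4)
        n_trials, n_t = 3000, 20
        X = np.cumsum(rng.normal(0.001, 0.05, size=(n_trials, n_t)), axis=1)
        times = np.arange(n_t) * 10.0
        land1 = estimate_potential(X, times, np.zeros(n_trials), n_bins=20)
        land2 = estimate_potential(-X, times, np.zeros(n_trials), n_bins=20)
        V1 = land1.potential[0.0]
        V2 = land2.potential[0.0]
        # V'(x) = V(-x): compare on the mirrored grid
        mirror = np.argsort(-land2.positions)
        assert np.allclose(land1.positions, -land2.positions[mirror],
                           atol=1e-9)
        a, b = V1, V2[mirror]
        fin = np.isfinite(a) & np.isfinite(b)
        assert np.allclose(a[fin], b[fin], atol=1e-9)


class TestBasinMetrics:
    def test_flat_potential_flagged(self):
        c = np.linspace(-2, 2, 41)
        V = np.zeros((41, 1))
        m = basin_metrics(V, c, np.array([0.0]), t_eval=0.0)
        assert m["depth_left"] == 0 and m["depth_right"] == 0
        assert np.isnan(m["separation"])

    def test_quartic_double_well_closed_form(self):
        c = np.linspace(-2, 2, 401)
        V = ((c ** 2 - 1) ** 2 / 4)[:, None] - 0.25  # V(0)=0, minima -0.25
        m = basin_metrics(V, c, np.array([0.0]), t_eval=0.0)
        assert m["depth_left"] == pytest.approx(0.25, abs=1e-6)
        assert m["depth_right"] == pytest.approx(0.25, abs=1e-6)
        assert m["separation"] == pytest.approx(2.0, abs=0.02)


class TestAggregateModels:
    def test_identical_landscapes(self):
        c = np.linspace(-1, 1, 21)
        v = c ** 2
        mean, se, count = aggregate_models([(c, v)] * 5)
        assert np.allclose(mean, v)
        assert np.allclose(se, 0.0)
        assert np.all(count == 5)

    def test_below_threshold_masked(self):
        c = np.linspace(-1, 1, 21)
        v = c ** 2
        mean, se, count = aggregate_models([(c, v)] * 3, min_models=4)
        assert np.all(np.isnan(mean))

    def test_disjoint_supports_keep_overlap(self):
        c = np.linspace(-1, 1, 21)
        left = np.where(c <= 0.3, c ** 2, np.nan)
        right = np.where(c >= -0.3, c ** 2, np.nan)
        models = [(c, left)] * 4 + [(c, right)] * 4
        mean, se, count = aggregate_models(models, min_models=5)
        overlap = (c >= -0.3) & (c <= 0.3)
        assert np.all(np.isfinite(mean[overlap]))
        assert np.all(np.isnan(mean[~overlap]))


def test_grid_contains_zero_edge():
    rng = np.random.default_rng(0)
    edges, centers = make_grid(rng.normal(0.3, 1.0, 1000), n_bins=30)
    assert np.min(np.abs(edges)) < 1e-12
    dx = np.diff(edges)
    assert np.allclose(dx, dx[0])
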