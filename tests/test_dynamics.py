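"""Forward-model tests: splines, rates, and the RK4-DDE integrators,
checked against closed forms and a brute-force Euler oracle."""

import numpy as np
import pytest

import tdss
from tdss.dynamics import (
    DelayMatrices,
    SeriesBlock,
    TDSSGeneModel,
    TimeSeriesSet,
    integrate_decoupled,
    integrate_full,
    linear_spline,
    resample_series,
    tdss_rate,
)


class TestLinearSpline:
    def test_midpoint_knot_and_clamp(self):
        sp = linear_spline([0.0, 1.0], [1.0, 3.0])
        assert sp(0.5) == pytest.approx(2.0)
        assert sp(1.0) == pytest.approx(3.0)
        assert sp(-1.0) == pytest.approx(1.0)  # clamped below the domain
        assert sp(9.0) == pytest.approx(3.0)

    def test_exact_at_every_knot_and_affine_invariance(self, rng):
        t = np.sort(rng.uniform(0, 10, 8))
        t += np.arange(8) * 1e-3  # guarantee strict increase
        x = rng.uniform(0.5, 2.0, 8)
        sp = linear_spline(t, x)
        assert np.allclose(sp(t), x)
        a, b = 2.5, -0.3
        sp2 = linear_spline(t, a * x + b)
        q = rng.uniform(t[0], t[-1], 30)
        assert np.allclose(sp2(q), a * sp(q) + b)

    @pytest.mark.parametrize(
        "times,values",
        [([1.0, 1.0, 2.0], [1, 2, 3]), ([0.0, 1.0], [1, 2, 3]), ([0.0], [1.0])],
    )
    def test_invalid_inputs(self, times, values):
        with pytest.raises(ValueError):
            linear_spline(times, values)


class TestResample:
    def _series(self, times, values):
        return TimeSeriesSet([SeriesBlock(np.asarray(times, float), np.asarray(values, float))])

    def test_20min_to_10min_doubles_sampling(self):
        t = 20.0 * np.arange(16)
        vals = np.linspace(1, 4, 16)[:, None]
        out = resample_series(self._series(t, vals), 10.0)
        blk = out.series[0]
        assert blk.times.size == 31
        assert np.allclose(blk.values[::2, 0], vals[:, 0])  # originals preserved

    def test_identity_and_midpoint(self):
        out = resample_series(self._series([0.0, 20.0], [[1.0], [3.0]]), 10.0)
        assert out.series[0].values[1, 0] == pytest.approx(2.0)
        same = resample_series(self._series([0.0, 20.0], [[1.0], [3.0]]), 20.0)
        assert np.allclose(same.series[0].values, [[1.0], [3.0]])

    def test_rejects_bad_interval(self, conf1_data):
        with pytest.raises(ValueError):
            resample_series(conf1_data, -1.0)


class TestRate:
    def test_zero_orders_cancel(self):
        m = TDSSGeneModel(0, 1.0, 1.0, [0.0], [0.0], [0.0], [0.0])
        assert tdss_rate(0, m, lambda j, t: 5.0, 1.0) == pytest.approx(0.0)

    def test_five_gene_second_equation(self, conf1):
        # alpha_2 X1^2 - beta_2 X2^2 at unit expressions, then with X1 = 2
        p = conf1.params
        m = TDSSGeneModel(1, p.alpha[1], p.beta[1], p.G[1], p.H[1],
                          np.zeros(5), np.zeros(5))
        assert tdss_rate(1, m, lambda j, t: 1.0, 0.0) == pytest.approx(0.0)
        lookup = lambda j, t: 2.0 if j == 0 else 1.0
        assert tdss_rate(1, m, lookup, 0.0) == pytest.approx(30.0)

    def test_nonpositive_lookup_raises(self):
        m = TDSSGeneModel(0, 1.0, 1.0, [0.5], [0.0], [0.0], [0.0])
        with pytest.raises(ValueError):
            tdss_rate(0, m, lambda j, t: -1.0, 0.0)


def _plain_rk4(params, x0, t_grid, h):
    """Non-delayed S-System RK4 oracle (independent of the DDE machinery)."""
    def f(x):
        P = np.where(params.G != 0, x[None, :] ** params.G, 1.0).prod(axis=1)
        D = np.where(params.H != 0, x[None, :] ** params.H, 1.0).prod(axis=1)
        return params.alpha * P - params.beta * D

    span = t_grid[-1] - t_grid[0]
    K = int(round(span / h))
    out = np.empty((K + 1, x0.size))
    out[0] = x0
    for k in range(K):
        y = out[k]
        k1 = f(y); k2 = f(y + 0.5 * h * k1); k3 = f(y + 0.5 * h * k2); k4 = f(y + h * k3)
        out[k + 1] = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    fine_t = t_grid[0] + h * np.arange(K + 1)
    return np.column_stack([np.interp(t_grid, fine_t, out[:, j]) for j in range(x0.size)])


class TestIntegrateFull:
    def test_zero_delay_matches_plain_rk4(self, conf1):
        x0 = np.array([0.3, 0.8, 0.5, 0.6, 0.4])
        t_grid = 0.05 * np.arange(12)
        h = 0.05 / 20
        hist = [linear_spline([-1.0, 0.0], [x0[j], x0[j]]) for j in range(5)]
        delays = DelayMatrices.zero(5, tau_max=0.15)
        res = integrate_full(conf1.params, delays, hist, t_grid, rk4_step=h)
        oracle = _plain_rk4(conf1.params, x0, t_grid, h)
        assert res.ok
        assert np.max(np.abs(res.values - oracle) / oracle) < 1e-10

    def test_constant_at_fixed_point(self):
        # dX = a X2^0 ... simple 1-gene: a - b X^2 has fixed point sqrt(a/b)
        params = tdss.SSystemParameters([4.0], [1.0], [[0.0]], [[2.0]])
        delays = DelayMatrices.zero(1, tau_max=0.5)
        hist = [linear_spline([-1.0, 0.0], [2.0, 2.0])]
        res = integrate_full(params, delays, hist, np.linspace(0, 3, 10), rk4_step=0.01)
        assert np.allclose(res.values, 2.0, atol=1e-9)

    def test_delayed_against_euler_oracle(self, conf2):
        si = 0.05  # one TS in model time
        n = 5
        x0 = np.array([0.4, 0.9, 0.6, 0.7, 0.5])
        tau_g = conf2.delays.tau_g * si
        tau_h = conf2.delays.tau_h * si
        tau_max = conf2.tau_max * si
        t_grid = si * np.arange(16)
        hist = [linear_spline([-tau_max, 0.0], [x0[j], x0[j]]) for j in range(n)]
        res = integrate_full(
            conf2.params, DelayMatrices(tau_g, tau_h, tau_max, 0.1 * si), hist, t_grid,
            rk4_step=si / 20,
        )
        # brute-force Euler with history lookup on a fine grid
        h = 1e-4
        K = int(round(t_grid[-1] / h))
        s = int(round(tau_max / h))
        X = np.empty((s + K + 1, n))
        X[: s + 1] = x0
        dg = np.rint(tau_g / h).astype(int)
        dh = np.rint(tau_h / h).astype(int)
        jj = np.broadcast_to(np.arange(n), (n, n))
        p = conf2.params
        for k in range(K):
            row = s + k
            Vg = X[row - dg, jj]
            Vh = X[row - dh, jj]
            P = np.where(p.G != 0, Vg ** p.G, 1.0).prod(axis=1)
            D = np.where(p.H != 0, Vh ** p.H, 1.0).prod(axis=1)
            X[row + 1] = X[row] + h * (p.alpha * P - p.beta * D)
        fine_t = h * np.arange(K + 1)
        oracle = np.column_stack(
            [np.interp(t_grid, fine_t, X[s:, j]) for j in range(n)]
        )
        assert res.ok
        assert np.max(np.abs(res.values - oracle) / oracle) < 1e-3


class TestIntegrateDecoupled:
    def _decay_series(self, T=15):
        t = np.arange(T, dtype=float)
        x = np.exp(-0.2 * t)  # gentle decay, strictly positive
        return SeriesBlock(t, x[:, None])

    def test_matches_closed_form_decay(self):
        # dX/dt = alpha_eps - X  =>  X(t) ~ X0 exp(-t) for tiny alpha
        t = np.arange(15, dtype=float)
        series = SeriesBlock(t, np.exp(-t * 0.5)[:, None] + 1e-12)
        model = TDSSGeneModel(0, 1e-9, 0.5, [0.0], [1.0], [0.0], [0.0])
        res = integrate_decoupled(model, series, tau_max=1.0)
        expected = np.exp(-0.5 * res.times)
        assert res.ok
        assert np.max(np.abs(res.values - expected) / expected) < 1e-5

    def test_fourth_order_convergence(self):
        t = np.arange(15, dtype=float)
        series = SeriesBlock(t, np.exp(-t)[:, None] + 1e-15)
        model = TDSSGeneModel(0, 1e-12, 1.0, [0.0], [1.0], [0.0], [0.0])
        errs = []
        for step in (0.5, 0.25):
            res = integrate_decoupled(model, series, tau_max=1.0, rk4_step=step)
            exact = np.exp(-res.times)
            errs.append(np.max(np.abs(res.values - exact)))
        ratio = errs[0] / errs[1]
        assert 12 < ratio < 20

    def test_true_model_round_trip(self, conf2):
        data = tdss.generate_data(conf2, M=1, T=15, seed=3)
        blk = data.series[0]
        ts = data.ts_unit
        for i in range(5):
            model = TDSSGeneModel(
                i,
                conf2.params.alpha[i] * ts,  # rates rescaled to TS time
                conf2.params.beta[i] * ts,
                conf2.params.G[i],
                conf2.params.H[i],
                conf2.delays.tau_g[i],
                conf2.delays.tau_h[i],
            )
            scaled = SeriesBlock(blk.times / ts, blk.values)
            res = integrate_decoupled(model, scaled, tau_max=conf2.tau_max)
            obs = blk.values[3:, i]
            assert res.ok
            assert np.max(np.abs(res.values - obs) / obs) < 1e-2

    def test_divergence_is_flagged_not_raised(self):
        t = np.arange(15, dtype=float)
        series = SeriesBlock(t, np.full((15, 1), 2.0))
        # strong positive self-production: explodes
        model = TDSSGeneModel(0, 15.0, 1e-9, [2.5], [0.0], [0.0], [0.0])
        res = integrate_decoupled(model, series, tau_max=1.0)
        assert not res.ok
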