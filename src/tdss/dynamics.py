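"""Forward models for (time-delayed) S-System gene regulatory networks.

An S-System describes each gene's expression rate as the difference of a
production and a degradation term, both power laws over the current state:

    dX_i/dt = alpha_i * prod_j X_j^g_ij  -  beta_i * prod_j X_j^h_ij

The delayed generalisation replaces every regulator value X_j by its value a
regulation-specific lag ago, X_j(t - tau_ij), turning the system into a delay
differential equation (DDE).  This module provides

* the parameter containers (:class:`SSystemParameters`, :class:`DelayMatrices`,
  :class:`TDSSGeneModel`, :class:`TimeSeriesSet`),
* piecewise-linear profiles (:func:`linear_spline`, :func:`resample_series`),
* the instantaneous rate (:func:`tdss_rate`),
* a coupled RK4-DDE integrator for data generation (:func:`integrate_full`),
* a decoupled single-gene integrator used by the inference engine
  (:func:`integrate_decoupled`), where all other genes are read off linear
  splines of the observed data.

Delays are expressed in time-stamp (TS) units, the spacing between consecutive
samples, at a default resolution of 0.1 TS.  Delayed arguments are evaluated on
the integrator's internal grid (half-step resolution), so the RK4 step should
divide the delay resolution; the defaults (step = TS/20, resolution 0.1 TS)
satisfy this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel

__all__ = [
    "SplineProfile",
    "SSystemParameters",
    "DelayMatrices",
    "TDSSGeneModel",
    "SeriesBlock",
    "TimeSeriesSet",
    "IntegrationResult",
    "linear_spline",
    "resample_series",
    "tdss_rate",
    "integrate_full",
    "integrate_decoupled",
]

#: Trajectories exceeding this value are treated as diverged.
DEFAULT_DIVERGENCE_CAP = 1e6

#: Default number of RK4 sub-steps per sampling interval.
DEFAULT_SUBSTEPS = 20


class SplineProfile:
    """Piecewise-linear interpolant of one gene's expression profile.

    Evaluation at a knot returns the knot value exactly; between knots it is
    linear; outside the domain the nearest endpoint value is returned (clamped
    extrapolation keeps positive expression positive).
    """

    def __init__(self, knots: np.ndarray, values: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)
        if knots.ndim != 1 or values.ndim != 1:
            raise ValueError("knots and values must be one-dimensional")
        if knots.size != values.size:
            raise ValueError(
                f"length mismatch: {knots.size} knots vs {values.size} values"
            )
        if knots.size < 2:
            raise ValueError("a spline needs at least two knots")
        if not np.all(np.diff(knots) > 0):
            raise ValueError("knot times must be strictly increasing")
        self.knots = knots
        self.values = values

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def __call__(self, t):
        return np.interp(t, self.knots, self.values)

    def __repr__(self) -> str:  # pragma: no cover
        lo, hi = self.domain
        return f"SplineProfile({self.knots.size} knots on [{lo:g}, {hi:g}])"


def linear_spline(times, values) -> SplineProfile:
    """Build a linear spline through ``(times, values)`` samples."""
    return SplineProfile(times, values)


@dataclass
class SSystemParameters:
    """Full-network S-System parameter set.

    alpha, beta : positive rate constants (length N)
    G, H        : NxN kinetic-order matrices; entry (i, j) is the exponent of
                  regulator j in gene i's production (G) or degradation (H)
                  term.  Zero means no regulation.
    """

    alpha: np.ndarray
    beta: np.ndarray
    G: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        n = self.alpha.size
        if self.beta.size != n or self.G.shape != (n, n) or self.H.shape != (n, n):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("rate constants must be positive")

    @property
    def n_genes(self) -> int:
        return self.alpha.size


@dataclass
class DelayMatrices:
    """Per-regulation delays (TS units) for production and degradation."""

    tau_g: np.ndarray
    tau_h: np.ndarray
    tau_max: float
    step: float = 0.1

    def __post_init__(self):
        self.tau_g = np.asarray(self.tau_g, dtype=float)
        self.tau_h = np.asarray(self.tau_h, dtype=float)
        if self.tau_g.shape != self.tau_h.shape:
            raise ValueError("tau_g and tau_h must have the same shape")
        for name, m in (("tau_g", self.tau_g), ("tau_h", self.tau_h)):
            if np.any(m < 0) or np.any(m > self.tau_max + 1e-12):
                raise ValueError(f"{name} entries must lie in [0, tau_max]")

    def snapped(self) -> "DelayMatrices":
        """Return a copy with every delay snapped to a multiple of ``step``."""
        snap = lambda m: np.round(m / self.step) * self.step
        return DelayMatrices(snap(self.tau_g), snap(self.tau_h), self.tau_max, self.step)

    @classmethod
    def zero(cls, n: int, tau_max: float, step: float = 0.1) -> "DelayMatrices":
        z = np.zeros((n, n))
        return cls(z, z.copy(), tau_max, step)


@dataclass
class TDSSGeneModel:
    """Decoupled parameter set of one gene: the 4N+2 quantities
    {alpha_i, beta_i, g_i., h_i., tau^g_i., tau^h_i.}."""

    gene_index: int
    alpha_i: float
    beta_i: float
    g_row: np.ndarray
    h_row: np.ndarray
    taug_row: np.ndarray
    tauh_row: np.ndarray

    def __post_init__(self):
        self.g_row = np.asarray(self.g_row, dtype=float)
        self.h_row = np.asarray(self.h_row, dtype=float)
        self.taug_row = np.asarray(self.taug_row, dtype=float)
        self.tauh_row = np.asarray(self.tauh_row, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.g_row.size


@dataclass
class SeriesBlock:
    """One replicate time series: sample times and a T x N value matrix."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.times.size != self.values.shape[0]:
            raise ValueError("values must be T x N with T matching times")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be positive and finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class TimeSeriesSet:
    """M replicate series over the same N genes.

    ``ts_unit`` is the duration of one time-stamp in the native time units of
    ``times`` (1.0 when times are already expressed in TS).
    """

    series: list
    gene_names: list = field(default_factory=list)
    ts_unit: float = 1.0

    def __post_init__(self):
        if not self.series:
            raise ValueError("at least one series is required")
        n = self.series[0].n_genes
        if any(s.n_genes != n for s in self.series):
            raise ValueError("all series must share the same gene count")
        if not self.gene_names:
            self.gene_names = [f"G{j + 1}" for j in range(n)]
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must equal the gene count")
        if self.ts_unit <= 0:
            raise ValueError("ts_unit must be positive")

    @property
    def n_genes(self) -> int:
        return self.series[0].n_genes

    @property
    def n_series(self) -> int:
        return len(self.series)

    def splines(self, series_index: int) -> list:
        blk = self.series[series_index]
        return [linear_spline(blk.times, blk.values[:, j]) for j in range(self.n_genes)]


def resample_series(data: TimeSeriesSet, new_interval: float) -> TimeSeriesSet:
    """Resample every series onto a uniform grid of spacing ``new_interval``
    (native time units) by linear interpolation.  Original sample points that
    fall on the new grid are preserved exactly."""
    if new_interval <= 0:
        raise ValueError("new_interval must be positive")
    out = []
    for blk in data.series:
        span = blk.times[-1] - blk.times[0]
        n_steps = span / new_interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("new_interval must divide the series span evenly")
        grid = blk.times[0] + new_interval * np.arange(int(round(n_steps)) + 1)
        vals = np.column_stack(
            [np.interp(grid, blk.times, blk.values[:, j]) for j in range(blk.n_genes)]
        )
        out.append(SeriesBlock(grid, vals))
    return TimeSeriesSet(out, list(data.gene_names), data.ts_unit)


def tdss_rate(i: int, model: TDSSGeneModel, lookup, t: float) -> float:
    """Instantaneous rate dX_i/dt of the delayed S-System.

    ``lookup(j, s)`` must return gene j's (positive) expression at time s.
    Regulators with kinetic order exactly 0 contribute a factor of 1 and their
    profile is never queried.
    """
    prod = model.alpha_i
    degr = model.beta_i
    for j in range(model.n_genes):
        g = model.g_row[j]
        if g != 0.0:
            x = float(lookup(j, t - model.taug_row[j]))
            if x <= 0:
                raise ValueError(
                    f"non-positive expression for gene {j} at t={t - model.taug_row[j]:g}"
                )
            prod *= x ** g
        h = model.h_row[j]
        if h != 0.0:
            x = float(lookup(j, t - model.tauh_row[j]))
            if x <= 0:
                raise ValueError(
                    f"non-positive expression for gene {j} at t={t - model.tauh_row[j]:g}"
                )
            degr *= x ** h
    return prod - degr


@dataclass
class IntegrationResult:
    """Integrator output; ``ok`` is False when the trajectory diverged or lost
    positivity (callers translate that into a worst-case fitness, not an
    exception)."""

    times: np.ndarray
    values: np.ndarray
    ok: bool


def _power_product(rate_const, orders, vals):
    # prod_j vals^orders with exact-zero orders contributing 1 (0^0-safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(orders != 0.0, vals ** orders, 1.0)
    return rate_const * factors.prod(axis=-1)


def integrate_full(
    params: SSystemParameters,
    delays: DelayMatrices,
    histories: list,
    t_grid,
    rk4_step: float | None = None,
    cap: float = DEFAULT_DIVERGENCE_CAP,
) -> IntegrationResult:
    """Simultaneous RK4-DDE integration of all N genes.

    ``histories`` is one :class:`SplineProfile` per gene covering at least
    [t0 - tau_max, t0]; delayed lookups before t0 use it, later lookups use
    linear interpolation of the computed solution.  With all delays zero this
    reduces exactly to classic RK4 of the non-delayed system.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n = params.n_genes
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    span = t_end - t0
    if rk4_step is None:
        rk4_step = float(np.min(np.diff(t_grid))) / DEFAULT_SUBSTEPS
    K = max(1, int(round(span / rk4_step)))
    h = span / K
    s = int(math.ceil(delays.tau_max / h - 1e-9))

    # Solution on the fine grid, extended s steps into the history region.
    X = np.empty((s + K + 1, n))
    hist_t = t0 + h * np.arange(-s, 1)
    for j in range(n):
        X[: s + 1, j] = histories[j](hist_t)
    if np.any(X[: s + 1] <= 0):
        raise ValueError("history profiles must be positive")

    Dg2 = np.rint(2.0 * delays.tau_g / h).astype(np.int64)
    Dh2 = np.rint(2.0 * delays.tau_h / h).astype(np.int64)
    jj = np.broadcast_to(np.arange(n), (n, n))
    last = s + K

    def delayed_values(D2, u2, k_done, y):
        """N x N matrix of X_j(t_u - tau_ij); half-index u2, rows stored
        through fine index k_done, current stage state y."""
        U = u2 - D2
        lo = U // 2
        rem = U - 2 * lo
        idx = np.clip(lo + s, 0, k_done + s)
        vals = X[idx, jj]
        if rem.any():
            hi = np.clip(idx + 1, 0, k_done + s)
            vals = np.where(rem == 1, 0.5 * (vals + X[hi, jj]), vals)
        return np.where(D2 == 0, y[jj], vals)

    def rate(u2, k_done, y):
        vg = delayed_values(Dg2, u2, k_done, y)
        vh = delayed_values(Dh2, u2, k_done, y)
        return _power_product(params.alpha, params.G, vg) - _power_product(
            params.beta, params.H, vh
        )

    ok = True
    for k in range(K):
        y0 = X[s + k]
        u2 = 2 * k
        k1 = rate(u2, k, y0)
        k2 = rate(u2 + 1, k, y0 + 0.5 * h * k1)
        k3 = rate(u2 + 1, k, y0 + 0.5 * h * k2)
        k4 = rate(u2 + 2, k, y0 + h * k3)
        y1 = y0 + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y1)) or np.any(y1 <= 0) or np.any(y1 > cap):
            X[s + k + 1 :] = np.nan
            ok = False
            break
        X[s + k + 1] = y1

    fine_t = t0 + h * np.arange(K + 1)
    sol = X[s:]
    out = np.column_stack(
        [np.interp(t_grid, fine_t, sol[:, j]) for j in range(n)]
    )
    return IntegrationResult(t_grid, out, ok)


# ---------------------------------------------------------------------------
# Decoupled evaluation grids
# ---------------------------------------------------------------------------


class DecoupledGrids:
    """Precomputed observation grids shared by all decoupled integrations on
    one dataset: per-series fine and half-step log profiles, the history
    cut-off index, and the fitted sample indices.

    Requires uniformly sampled series of equal length (resample first
    otherwise).  Times are converted to TS units via ``ts_unit``.
    """

    def __init__(
        self,
        data: TimeSeriesSet,
        tau_max: float,
        substeps: int = DEFAULT_SUBSTEPS,
    ):
        times0 = data.series[0].times / data.ts_unit
        T = times0.size
        dt = np.diff(times0)
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise ValueError("decoupled evaluation requires uniform sampling")
        for blk in data.series:
            t = blk.times / data.ts_unit
            if t.size != T or np.max(np.abs(t - t[0] - (times0 - times0[0]))) > 1e-9:
                raise ValueError("all series must share one sampling grid")
        self.interval_ts = float(dt[0])
        self.h = self.interval_ts / substeps
        self.substeps = substeps
        self.K = (T - 1) * substeps
        self.s = int(round(tau_max / self.h))
        if self.s >= self.K:
            raise ValueError("series shorter than tau_max plus one sample")
        self.tau_max = tau_max
        self.n_genes = data.n_genes
        self.n_series = data.n_series

        M, N, K = self.n_series, self.n_genes, self.K
        self.obs_fine = np.empty((M, N, K + 1))
        self.log_obs_half = np.empty((M, N, 2 * K + 1))
        fine = np.arange(K + 1) * self.h
        half = np.arange(2 * K + 1) * (self.h / 2.0)
        for m, blk in enumerate(data.series):
            t = blk.times / data.ts_unit
            t = t - t[0]
            for j in range(N):
                self.obs_fine[m, j] = np.interp(fine, t, blk.values[:, j])
                self.log_obs_half[m, j] = np.log(np.interp(half, t, blk.values[:, j]))
        # observed samples inside the fitted window (t >= t_first + tau_max)
        sample_fine = np.arange(T) * substeps
        fit = sample_fine >= self.s
        self.sample_idx = sample_fine[fit].astype(np.int64)
        self.sample_times = times0[fit]
        self.observed = np.stack(
            [blk.values[fit] for blk in data.series]
        )  # (M, Q, N)

    def delay_to_half_steps(self, tau_rows: np.ndarray) -> np.ndarray:
        d2 = np.rint(np.asarray(tau_rows) / (self.h / 2.0)).astype(np.int64)
        # a nonzero delay must span at least one full integrator step so the
        # gene's own past is always available to the stage evaluations
        return np.where((d2 > 0) & (d2 < 2), 2, d2)


def integrate_decoupled(
    model: TDSSGeneModel,
    series: SeriesBlock,
    tau_max: float,
    rk4_step: float | None = None,
    ts_unit: float = 1.0,
    cap: float = DEFAULT_DIVERGENCE_CAP,
) -> IntegrationResult:
    """Predict gene i's trajectory with all other genes pinned to linear
    splines of the observed data.

    Integration starts at t_first + tau_max; the initial tau_max-long stretch
    of the observed series is the history.  Returns the prediction at the
    observed sample times inside the fitted window.
    """
    if rk4_step is not None:
        interval = float(np.min(np.diff(series.times))) / ts_unit
        substeps = max(1, int(round(interval / rk4_step)))
    else:
        substeps = DEFAULT_SUBSTEPS
    data = TimeSeriesSet([series], ts_unit=ts_unit)
    grids = DecoupledGrids(data, tau_max, substeps)
    i = model.gene_index
    dg2 = grids.delay_to_half_steps(model.taug_row)
    dh2 = grids.delay_to_half_steps(model.tauh_row)
    ok, x = _kernel.solve_gene(
        i,
        model.alpha_i,
        model.beta_i,
        model.g_row,
        model.h_row,
        dg2,
        dh2,
        grids.log_obs_half[0],
        grids.obs_fine[0],
        grids.s,
        grids.K,
        grids.h,
        cap,
    )
    pred = x[grids.sample_idx]
    return IntegrationResult(grids.sample_times * ts_unit, pred, bool(ok))
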