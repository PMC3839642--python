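"""Built-in benchmark networks and synthetic time-course generation.

Two widely used S-System benchmarks are bundled so the whole inference
pipeline can be exercised offline:

* a 5-gene cascade (conf1: no delays; conf2: five 1.0-TS delays; conf3: six
  mixed fractional delays up to 2.1 TS), and
* a 20-gene network with 26 production regulations and per-gene
  self-degradation (conf4: no delays; conf5: eight delayed regulations).

Data generation draws M random initial states, holds each constant over the
history window [-tau_max, 0], integrates the coupled delayed system with RK4
and samples it at 1-TS spacing.  Measurement noise is multiplicative Gaussian
(a "5% noise" level is a relative standard deviation of 0.05), floored at a
small positive value so power-law terms stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    DelayMatrices,
    IntegrationResult,
    SSystemParameters,
    SeriesBlock,
    TimeSeriesSet,
    integrate_full,
    linear_spline,
)

__all__ = [
    "BenchmarkNetwork",
    "NoiseSpec",
    "network_5gene",
    "network_20gene",
    "benchmark_network",
    "generate_data",
    "add_noise",
]

SYNTHETIC_TAU_MAX = 3.0  # TS; the benchmark delay configurations stay within this

#: Expression floor applied after noise injection.
NOISE_FLOOR = 1e-3


@dataclass(frozen=True)
class BenchmarkNetwork:
    name: str
    params: SSystemParameters
    delays: DelayMatrices
    tau_max: float

    @property
    def n_genes(self) -> int:
        return self.params.n_genes


@dataclass(frozen=True)
class NoiseSpec:
    level: float
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be non-negative")


def _params_5gene() -> SSystemParameters:
    n = 5
    alpha = np.array([5.0, 10.0, 10.0, 8.0, 10.0])
    beta = np.array([10.0, 10.0, 10.0, 10.0, 10.0])
    G = np.zeros((n, n))
    H = np.zeros((n, n))
    G[0, 2], G[0, 4] = 1.0, -1.0
    G[1, 0] = 2.0
    G[2, 1] = -1.0
    G[3, 2], G[3, 4] = 2.0, -1.0
    G[4, 3] = 2.0
    H[0, 0] = 2.0
    H[1, 1] = 2.0
    H[2, 1], H[2, 2] = -1.0, 2.0
    H[3, 3] = 2.0
    H[4, 4] = 2.0
    return SSystemParameters(alpha, beta, G, H)


def network_5gene(config: str) -> BenchmarkNetwork:
    """The 5-gene benchmark in one of its delay configurations
    (``conf1`` no delays, ``conf2`` integer delays, ``conf3`` fractional)."""
    params = _params_5gene()
    n = 5
    tau_g = np.zeros((n, n))
    tau_h = np.zeros((n, n))
    if config == "conf1":
        pass
    elif config == "conf2":
        tau_g[0, 4] = tau_g[1, 0] = tau_g[2, 1] = tau_g[3, 4] = 1.0
        tau_h[2, 1] = 1.0
    elif config == "conf3":
        tau_g[0, 2] = 1.1
        tau_g[1, 0] = 1.2
        tau_g[2, 1] = 1.3
        tau_g[4, 3] = 2.1
        tau_g[3, 4] = 1.0
        tau_h[2, 1] = 1.0
    else:
        raise ValueError(f"unknown 5-gene configuration {config!r}")
    delays = DelayMatrices(tau_g, tau_h, SYNTHETIC_TAU_MAX)
    return BenchmarkNetwork(config, params, delays, SYNTHETIC_TAU_MAX)


# (target, regulator, kinetic order), 1-based, production phase
_G20 = [
    (3, 15, -0.7), (5, 1, 1.0), (6, 1, 2.0), (7, 2, 1.2), (7, 3, -0.8),
    (7, 10, 1.6), (8, 3, -0.6), (9, 4, 0.5), (9, 5, 0.7), (10, 6, -0.3),
    (10, 14, 0.9), (11, 7, 0.5), (12, 1, 1.0), (13, 10, -0.4), (13, 17, 1.3),
    (14, 11, -0.4), (15, 8, 0.5), (15, 11, -1.0), (15, 18, -0.9),
    (16, 12, 2.0), (17, 13, -0.5), (18, 14, 1.2), (19, 12, 1.4),
    (19, 17, 0.6), (20, 14, 1.0), (20, 17, 1.5),
]

# (target, regulator, delay in TS), production phase
_TAU20_CONF5 = [
    (3, 15, 1.1), (5, 1, 1.3), (7, 10, 1.6), (10, 6, 2.1),
    (14, 11, 1.5), (18, 14, 1.9), (19, 17, 0.6), (20, 14, 1.0),
]


def network_20gene(config: str) -> BenchmarkNetwork:
    """The 20-gene benchmark: 26 production regulations, unit self-inhibition
    in degradation, rate constants 10 (``conf4`` no delays, ``conf5`` eight
    delayed regulations)."""
    n = 20
    alpha = np.full(n, 10.0)
    beta = np.full(n, 10.0)
    G = np.zeros((n, n))
    H = np.eye(n)
    for tgt, reg, k in _G20:
        G[tgt - 1, reg - 1] = k
    params = SSystemParameters(alpha, beta, G, H)
    tau_g = np.zeros((n, n))
    tau_h = np.zeros((n, n))
    if config == "conf4":
        pass
    elif config == "conf5":
        for tgt, reg, tau in _TAU20_CONF5:
            tau_g[tgt - 1, reg - 1] = tau
    else:
        raise ValueError(f"unknown 20-gene configuration {config!r}")
    delays = DelayMatrices(tau_g, tau_h, SYNTHETIC_TAU_MAX)
    return BenchmarkNetwork(config, params, delays, SYNTHETIC_TAU_MAX)


def benchmark_network(name: str) -> BenchmarkNetwork:
    """Look up any built-in configuration by name (conf1..conf5)."""
    if name in ("conf1", "conf2", "conf3"):
        return network_5gene(name)
    if name in ("conf4", "conf5"):
        return network_20gene(name)
    raise ValueError(f"unknown benchmark network {name!r}")


#: Duration of one time-stamp in model time units.  The benchmark rate
#: constants are O(10), giving relaxation times of ~0.05 model time units;
#: sampling every 0.01 units spreads the informative transient over many
#: time-stamps, so it survives the tau_max-long history cut-off (a 1-unit
#: spacing would only ever see the steady state).
DEFAULT_SAMPLING_INTERVAL = 0.01


def generate_data(
    network: BenchmarkNetwork,
    M: int = 10,
    T: int = 15,
    seed: int = 0,
    init_range: tuple[float, float] = (0.1, 1.0),
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    rk4_step: float | None = None,
    max_retries: int = 20,
) -> TimeSeriesSet:
    """Noise-free expression data: M series of T samples at 1-TS spacing
    (one TS = ``sampling_interval`` model time units; the returned set carries
    this as its ``ts_unit``).

    Each series starts from a uniform random state in ``init_range`` held
    constant over the history window.  A diverging draw is redrawn (bounded
    retries).  Network delays, specified in TS, are scaled to model time for
    the integration.
    """
    if M < 1 or T < 2:
        raise ValueError("need M >= 1 series and T >= 2 samples")
    rng = np.random.default_rng(seed)
    n = network.n_genes
    si = sampling_interval
    t_grid = si * np.arange(T, dtype=float)
    native_delays = DelayMatrices(
        network.delays.tau_g * si,
        network.delays.tau_h * si,
        network.tau_max * si,
        network.delays.step * si,
    )
    hist_t = np.array([-network.tau_max * si, 0.0])
    series = []
    for _ in range(M):
        result: IntegrationResult | None = None
        for _attempt in range(max_retries):
            x0 = rng.uniform(init_range[0], init_range[1], size=n)
            histories = [linear_spline(hist_t, np.full(2, x0[j])) for j in range(n)]
            res = integrate_full(
                network.params, native_delays, histories, t_grid, rk4_step
            )
            if res.ok and np.all(res.values > 0):
                result = res
                break
        if result is None:
            raise RuntimeError("could not generate a stable series")
        series.append(SeriesBlock(t_grid.copy(), result.values))
    return TimeSeriesSet(series, ts_unit=si)



def add_noise(data: TimeSeriesSet, spec: NoiseSpec) -> TimeSeriesSet:
    """Multiplicative Gaussian measurement noise X * (1 + eps),
    eps ~ N(0, level), independently per value; level 0 is the identity."""
    if spec.level == 0:
        return data
    rng = np.random.default_rng(spec.seed)
    out = []
    for blk in data.series:
        noisy = blk.values * (1.0 + rng.normal(0.0, spec.level, size=blk.values.shape))
        out.append(SeriesBlock(blk.times.copy(), np.maximum(noisy, NOISE_FLOOR)))
    return TimeSeriesSet(out, list(data.gene_names), data.ts_unit)
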