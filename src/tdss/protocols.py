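"""Benchmark campaign protocols.

A "campaign" is the standard evaluation recipe for the built-in synthetic
networks: generate a handful of replicate series from distinct initial
conditions (one seed per series), optionally corrupt them with multiplicative
noise, run the full inference once per optimizer seed, and assemble the best
of those independent runs per gene sub-problem.  Both the test suite and the
reproduction script drive the package through these entry points.
"""

from __future__ import annotations

import numpy as np

from .dynamics import TimeSeriesSet
from .evaluation import GoldNetwork, confusion, metrics
from .optimizer import InferredNetwork, TDEConfig, infer_network, select_best
from .synthesis import BenchmarkNetwork, NoiseSpec, add_noise, benchmark_network, generate_data

__all__ = ["benchmark_data", "run_campaign", "score"]


def benchmark_data(
    network: BenchmarkNetwork,
    series_seeds=(1, 2, 3, 4),
    T: int = 15,
    noise: float = 0.0,
    noise_seed: int = 0,
) -> TimeSeriesSet:
    """Replicate series from distinct initial conditions, one seed each."""
    blocks = []
    ts_unit = 1.0
    for s in series_seeds:
        d = generate_data(network, M=1, T=T, seed=s)
        blocks.append(d.series[0])
        ts_unit = d.ts_unit
    data = TimeSeriesSet(blocks, ts_unit=ts_unit)
    if noise > 0:
        data = add_noise(data, NoiseSpec(noise, seed=noise_seed))
    return data


def run_campaign(
    data: TimeSeriesSet,
    run_seeds=(1, 2, 3, 4, 5),
    **config_overrides,
) -> InferredNetwork:
    """Run the full inference once per seed and assemble the per-gene best."""
    runs = []
    for s in run_seeds:
        cfg = TDEConfig(seed=int(s), **config_overrides)
        runs.append(infer_network(data, cfg))
    return select_best(runs)


def score(inferred: InferredNetwork, network: BenchmarkNetwork):
    """(ConfusionCounts, Metrics) of an inferred network against the
    benchmark's gold standard."""
    gold = GoldNetwork.from_benchmark(network)
    c = confusion(inferred, gold)
    return c, metrics(c)
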