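"""Model-evaluation criteria for decoupled S-System inference.

Two criteria are provided:

* the squared relative error (SRE) between calculated and observed profiles,
  summed over all time series, and
* the adaptive squared relative error (ASRE), which adds a scale-free
  sparsity penalty:

      ASRE = SRE + B_i * C_i * 2N / (2N - r_i)

  where r_i is the number of distinct regulators of gene i, C_i penalises
  regulator counts outside the current in-degree band [J, I] by 1 + d^2
  (d = band violation distance), and B_i balances accuracy against
  complexity.  B_i starts at 0 (warm-up: pure accuracy) and is later set to
  the ratio of mean accuracy to mean complexity over the better half of the
  population, so neither objective dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TDSSGeneModel

__all__ = [
    "FitnessConfig",
    "FitnessValue",
    "sre",
    "count_regulators",
    "penalty_C",
    "asre",
    "asre_array",
    "update_balance",
    "adapt_in_degrees",
]


@dataclass
class FitnessConfig:
    """State and knobs of the adaptive criterion for one gene sub-problem.

    I, J      : current max/min in-degree bounds (adapted from the population)
    B_i       : balancing factor (0 during warm-up)
    n_e       : maximum warm-up length in generations
    gamma_i   : SRE threshold that ends warm-up early (set from the initial
                population: half the best initial criterion value)
    l         : in-degree adaptation interval in generations
    """

    I: int
    J: int = 0
    B_i: float = 0.0
    n_e: int = 50
    gamma_i: float | None = None
    l: int = 50
    gamma_exponent: int = 2

    def __post_init__(self):
        if not (0 <= self.J <= self.I):
            raise ValueError("in-degree bounds must satisfy 0 <= J <= I")
        if self.B_i < 0:
            raise ValueError("B_i must be non-negative")
        if self.n_e <= 0 or self.l <= 0:
            raise ValueError("n_e and l must be positive")


@dataclass(frozen=True)
class FitnessValue:
    sre: float
    complexity: float  # the 2N/(2N - r_i) term
    penalty_C: float
    total: float


def sre(predicted, observed) -> float:
    """Squared relative error sum_t ((X_cal - X_exp)/X_exp)^2.

    Accepts single vectors or matching lists of per-series vectors (summed)."""
    if isinstance(predicted, (list, tuple)):
        if len(predicted) != len(observed):
            raise ValueError("series count mismatch")
        return float(sum(sre(p, o) for p, o in zip(predicted, observed)))
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same shape")
    if np.any(observed == 0):
        raise ValueError("observed values must be nonzero")
    rel = (predicted - observed) / observed
    return float(np.sum(rel * rel))


def count_regulators(model: TDSSGeneModel) -> int:
    """Number of distinct regulator genes (nonzero in either phase).

    A gene acting in both the production and degradation phase counts once,
    keeping r_i <= N.
    """
    return int(np.count_nonzero((model.g_row != 0) | (model.h_row != 0)))


def penalty_C(r_i: int, I: int, J: int) -> float:
    """Scale-free penalty factor: 1 inside the open band (J, I), else
    1 + (distance to the violated bound)^2."""
    if r_i < 0:
        raise ValueError("regulator count cannot be negative")
    if not (0 <= J <= I):
        raise ValueError("in-degree bounds must satisfy 0 <= J <= I")
    if J < r_i < I:
        return 1.0
    if r_i <= J:
        return 1.0 + float(J - r_i) ** 2
    return 1.0 + float(r_i - I) ** 2


def asre(sre_value: float, r_i: int, N: int, B_i: float, C_i: float) -> FitnessValue:
    """Assemble the adaptive criterion from its parts."""
    if r_i >= 2 * N:
        raise ValueError("regulator count must be below 2N")
    complexity = 2.0 * N / (2.0 * N - r_i)
    total = sre_value + B_i * C_i * complexity
    return FitnessValue(sre=sre_value, complexity=complexity, penalty_C=C_i, total=total)


def asre_array(sre_values: np.ndarray, r: np.ndarray, N: int, B_i: float, J: int, I: int) -> np.ndarray:
    """Vectorised ASRE totals for a whole population (used by the optimizer)."""
    r = np.asarray(r, dtype=float)
    C = np.ones_like(r)
    low = r <= J
    high = r >= I
    C[low] = 1.0 + (J - r[low]) ** 2
    C[high & ~low] = 1.0 + (r[high & ~low] - I) ** 2
    complexity = 2.0 * N / (2.0 * N - r)
    return np.asarray(sre_values, dtype=float) + B_i * C * complexity


def update_balance(population_fitness: list[FitnessValue]) -> float:
    """Balancing factor B_i = ANA / AMC: mean SRE over the better half of the
    population divided by its mean complexity term."""
    if not population_fitness:
        raise ValueError("population must be non-empty")
    ranked = sorted(population_fitness, key=lambda f: f.total)
    top = ranked[: max(1, -(-len(ranked) // 2))]  # ceil(n/2)
    ana = float(np.mean([f.sre for f in top]))
    amc = float(np.mean([f.complexity for f in top]))
    return ana / amc


def adapt_in_degrees(population: list[TDSSGeneModel]) -> tuple[int, int]:
    """New (J, I): the smallest and largest in-degree in the population,
    with I capped at N."""
    if not population:
        raise ValueError("population must be non-empty")
    counts = [count_regulators(m) for m in population]
    n = population[0].n_genes
    return min(counts), min(n, max(counts))
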