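"""Scoring of inferred networks against a gold standard.

The counting space is the 2N^2 kinetic-order slots: every (phase, target,
regulator) triple with phase in {production, degradation}, self-edges
included.  A slot is "present" when its kinetic order is nonzero.  Sensitivity
(Sn), specificity (Sp), precision (Pr) and F-score are computed from the
resulting confusion counts; undefined ratios (0/0) are reported as ``None``
rather than coerced.  Delay recovery is assessed separately per true edge, at
the 0.1-TS resolution of the delay grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "GoldNetwork",
    "ConfusionCounts",
    "Metrics",
    "DelayVerdict",
    "confusion",
    "metrics",
    "classify_edge",
    "delay_accuracy",
]

PRODUCTION, DEGRADATION = 0, 1
_PHASE_NAMES = ("production", "degradation")


@dataclass(frozen=True)
class GoldNetwork:
    """Reference network: presence, sign and true delay per kinetic-order slot,
    stacked as (2, N, N) tensors indexed (phase, target, regulator)."""

    present: np.ndarray
    sign: np.ndarray
    tau_true: np.ndarray

    def __post_init__(self):
        if not (self.present.shape == self.sign.shape == self.tau_true.shape):
            raise ValueError("tensor shapes must agree")
        if np.any((self.sign != 0) != self.present):
            raise ValueError("sign must be nonzero exactly where present")
        if np.any(self.tau_true[~self.present] != 0):
            raise ValueError("absent slots must have zero delay")

    @property
    def n_genes(self) -> int:
        return self.present.shape[1]

    @classmethod
    def from_benchmark(cls, network) -> "GoldNetwork":
        """Build the gold standard from a :class:`~tdss.synthesis.BenchmarkNetwork`."""
        K = np.stack([network.params.G, network.params.H])
        tau = np.stack([network.delays.tau_g, network.delays.tau_h])
        present = K != 0
        return cls(present, np.sign(K).astype(int), np.where(present, tau, 0.0))


def _kinetic_tensors(inferred) -> tuple[np.ndarray, np.ndarray]:
    """(2,N,N) kinetic orders and delays from an InferredNetwork or a
    BenchmarkNetwork-like object."""
    if hasattr(inferred, "kinetic_tensor"):
        return inferred.kinetic_tensor(), inferred.delay_tensor()
    K = np.stack([inferred.params.G, inferred.params.H])
    tau = np.stack([inferred.delays.tau_g, inferred.delays.tau_h])
    return K, tau


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


class Metrics(NamedTuple):
    sn: float | None
    sp: float | None
    pr: float | None
    f: float | None


def confusion(inferred, gold: GoldNetwork) -> ConfusionCounts:
    """Score all 2N^2 slots of an inferred network against the gold one."""
    K, _ = _kinetic_tensors(inferred)
    if K.shape != gold.present.shape:
        raise ValueError("gene count mismatch between inferred and gold")
    inf_present = K != 0
    tp = int(np.sum(inf_present & gold.present))
    fp = int(np.sum(inf_present & ~gold.present))
    fn = int(np.sum(~inf_present & gold.present))
    tn = int(np.sum(~inf_present & ~gold.present))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, precision and F-score; None when undefined."""
    sn = _ratio(c.TP, c.TP + c.FN)
    sp = _ratio(c.TN, c.TN + c.FP)
    pr = _ratio(c.TP, c.TP + c.FP)
    if pr is None or sn is None or pr + sn == 0:
        f = 0.0 if (sn == 0 or pr == 0) else None
    else:
        f = 2.0 * pr * sn / (pr + sn)
    return Metrics(sn, sp, pr, f)


def classify_edge(tau: float, step: float = 0.1) -> str:
    """An interaction inferred with a delay at or below the delay resolution
    is deemed instantaneous; larger delays are genuine."""
    if tau < 0:
        raise ValueError("delay cannot be negative")
    return "instantaneous" if tau <= step + 1e-12 else "delayed"


@dataclass(frozen=True)
class DelayVerdict:
    phase: str
    target: int
    regulator: int
    tau_true: float
    tau_inferred: float
    correct: bool


def delay_accuracy(inferred, gold: GoldNetwork, tol: float = 0.1) -> list[DelayVerdict]:
    """Per-true-edge delay report over edges present in both networks:
    a delay is correct when |tau_inferred - tau_true| <= tol (default one
    0.1-TS resolution step)."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    K, tau_inf = _kinetic_tensors(inferred)
    report = []
    for phase in (PRODUCTION, DEGRADATION):
        for i, j in zip(*np.nonzero(gold.present[phase])):
            if K[phase, i, j] == 0:
                continue
            t_true = float(gold.tau_true[phase, i, j])
            t_inf = float(tau_inf[phase, i, j])
            report.append(
                DelayVerdict(
                    phase=_PHASE_NAMES[phase],
                    target=int(i),
                    regulator=int(j),
                    tau_true=t_true,
                    tau_inferred=t_inf,
                    correct=abs(t_inf - t_true) <= tol + 1e-12,
                )
            )
    return report
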