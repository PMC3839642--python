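"""Cross-correlation seeding of regulatory time lags.

Before the evolutionary search starts, the most probable lag of every ordered
gene pair (regulator -> target) is estimated: both profiles are resampled to
the delay resolution by linear interpolation, the target profile is shifted
forward one step at a time, and the lag maximising the absolute Pearson
correlation over the overlap is kept.  The absolute value makes activating and
repressing interactions (negative correlation) detectable alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import SplineProfile, TimeSeriesSet, linear_spline

__all__ = ["LagEstimate", "pearson", "estimate_lag", "lag_matrix"]


@dataclass(frozen=True)
class LagEstimate:
    lag: float  # TS units, multiple of the scan step
    correlation: float  # signed Pearson correlation at that lag


def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    return float(stats.pearsonr(x, y).statistic)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / den) if den > 0 else np.nan


def _scan(reg: np.ndarray, tgt: np.ndarray, kmax: int) -> np.ndarray:
    """|correlation| per candidate shift k = 0..kmax; NaN where undefined."""
    out = np.full(kmax + 1, np.nan)
    n = reg.size
    for k in range(kmax + 1):
        a = reg[: n - k]
        b = tgt[k:]
        if a.size < 3:
            continue
        out[k] = abs(_corr(a, b))
    return out


def estimate_lag(
    regulator: SplineProfile,
    target: SplineProfile,
    tau_max: float,
    step: float,
) -> LagEstimate:
    """Most probable lag of a regulator -> target interaction.

    Ties in |correlation| break toward the smallest lag; lags whose overlap is
    shorter than 3 grid points are skipped.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo = max(regulator.domain[0], target.domain[0])
    hi = min(regulator.domain[1], target.domain[1])
    if hi - lo <= tau_max:
        raise ValueError("profiles must overlap over more than tau_max")
    grid = lo + step * np.arange(int(np.floor((hi - lo) / step + 1e-9)) + 1)
    reg = regulator(grid)
    tgt = target(grid)
    kmax = int(np.floor(tau_max / step + 1e-9))
    corr = _scan(reg, tgt, kmax)
    if np.all(np.isnan(corr)):
        raise ValueError("no candidate lag had a usable overlap")
    k = int(np.nanargmax(corr))  # argmax returns the first (smallest) lag on ties
    signed = stats.pearsonr(reg[: reg.size - k], tgt[k:]).statistic if k < reg.size else 0.0
    return LagEstimate(lag=k * step, correlation=float(signed))


def lag_matrix(
    data: TimeSeriesSet,
    tau_max: float,
    step: float,
    return_sign: bool = False,
):
    """NxN matrix of lag seeds; entry (i, j) is the estimated lag of the
    regulation j -> i, in TS units.

    With several replicate series the per-lag |correlation| profiles are
    averaged across series before the maximum is taken, which is more robust
    than trusting any single replicate.  Pairs with no usable lag (for
    example a constant profile) fall back to lag 0.  With ``return_sign``
    a second matrix gives the sign of the correlation at the chosen lag
    (0 where undefined), a cheap activation/repression indicator.
    """
    n = data.n_genes
    kmax = int(np.floor(tau_max / step + 1e-9))
    lags = np.zeros((n, n))
    signs = np.zeros((n, n))
    profiles = []  # per series: resampled gene profiles in TS units
    for blk in data.series:
        t = blk.times / data.ts_unit
        grid = t[0] + step * np.arange(int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1)
        profiles.append(
            [np.interp(grid, t, blk.values[:, j]) for j in range(n)]
        )
    for i in range(n):
        for j in range(n):
            acc = np.zeros(kmax + 1)
            cnt = np.zeros(kmax + 1)
            for genes in profiles:
                c = _scan(genes[j], genes[i], kmax)
                good = ~np.isnan(c)
                acc[good] += c[good]
                cnt[good] += 1
            with np.errstate(invalid="ignore"):
                mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
            if not np.all(np.isnan(mean)):
                k = int(np.nanargmax(mean))
                lags[i, j] = k * step
                signed = 0.0
                for genes in profiles:
                    a = genes[j][: genes[j].size - k] if k else genes[j]
                    b = genes[i][k:]
                    cv = _corr(a, b)
                    if not np.isnan(cv):
                        signed += cv
                signs[i, j] = np.sign(signed)
    if return_sign:
        return lags, signs
    return lags
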