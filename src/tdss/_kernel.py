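"""Compiled inner loops for decoupled RK4-DDE evaluation.

Layout conventions shared with :mod:`tdss.dynamics`:

* One series spans fine-grid indices 0..K with spacing ``h`` (TS units);
  index ``s`` marks the end of the history region (t_first + tau_max).
* Delays are passed as *half-step* counts (``d2 = round(tau / (h/2))``), so a
  delayed argument at RK4 stage offset c in {0, 1/2, 1} lands exactly on the
  half grid.  Observed regulator profiles are therefore pre-tabulated in log
  space on the half grid (``log_obs_half``, shape (N, 2K+1)), turning each
  power-law factor into one multiply-add.
* The gene's own past beyond the history region is read from the growing
  solution array with midpoint interpolation; with the delay resolution at
  least one full step, those values are always already computed.

Everything here is plain float64/int64 arrays so the functions compile once
and are cached on disk.
"""

import numpy as np
from numba import njit

__all__ = ["solve_gene", "evaluate_population"]


@njit(cache=True)
def solve_gene(i, alpha, beta, g, h_row, dg2, dh2, log_obs_half, obs_fine, s, K, h, cap):
    """Integrate decoupled gene ``i`` from fine index s to K.

    Returns (ok, x) where x[:s+1] is the observed history and x[s:] the RK4
    solution; on divergence or positivity loss x is NaN from the failure point
    and ok is False.
    """
    n = g.shape[0]
    two_k = 2 * K

    # Pre-combined observed-regulator factors on the half grid:
    #   Eg[u] = alpha * prod_{j != i, g_j != 0} obs_j(t_u - taug_j)^g_j
    Eg = np.empty(two_k + 1)
    Eh = np.empty(two_k + 1)
    u0 = 2 * s  # stages never query production/degradation terms before t_start
    for u in range(u0, two_k + 1):
        acc_g = 0.0
        acc_h = 0.0
        for j in range(n):
            if j == i:
                continue
            gj = g[j]
            if gj != 0.0:
                v = u - dg2[j]
                if v < 0:
                    v = 0
                acc_g += gj * log_obs_half[j, v]
            hj = h_row[j]
            if hj != 0.0:
                v = u - dh2[j]
                if v < 0:
                    v = 0
                acc_h += hj * log_obs_half[j, v]
        Eg[u] = alpha * np.exp(acc_g)
        Eh[u] = beta * np.exp(acc_h)

    x = np.empty(K + 1)
    for k in range(s + 1):
        x[k] = obs_fine[i, k]
    for k in range(s + 1, K + 1):
        x[k] = np.nan

    gi = g[i]
    hi = h_row[i]
    dgi = dg2[i]
    dhi = dh2[i]

    ok = True
    for k in range(s, K):
        y0 = x[k]
        u2 = 2 * k

        # four stages; c encodes the half-step offset of each stage
        acc = 0.0
        y = y0
        for stage in range(4):
            if stage == 0:
                u = u2
            elif stage == 3:
                u = u2 + 2
            else:
                u = u2 + 1
            prod = Eg[u]
            if gi != 0.0:
                if dgi == 0:
                    xv = y
                else:
                    xv = _self_lookup(x, obs_fine, i, u - dgi)
                prod *= xv ** gi
            degr = Eh[u]
            if hi != 0.0:
                if dhi == 0:
                    xv = y
                else:
                    xv = _self_lookup(x, obs_fine, i, u - dhi)
                degr *= xv ** hi
            r = prod - degr
            if stage == 0:
                y = y0 + 0.5 * h * r
                acc = r
            elif stage == 1:
                y = y0 + 0.5 * h * r
                acc += 2.0 * r
            elif stage == 2:
                y = y0 + h * r
                acc += 2.0 * r
            else:
                acc += r
        y1 = y0 + (h / 6.0) * acc
        # NaN-safe: a NaN fails the positive-and-bounded test
        if not (y1 > 0.0 and y1 <= cap):
            ok = False
            break
        x[k + 1] = y1
    return ok, x


@njit(cache=True)
def _self_lookup(x, obs_fine, i, v):
    """Gene i's own value at half index v (midpoint-interpolated)."""
    if v < 0:
        v = 0
    lo = v // 2
    if v == 2 * lo:
        return x[lo]
    return 0.5 * (x[lo] + x[lo + 1])


@njit(cache=True)
def evaluate_population(
    gene,
    alphas,
    betas,
    G,
    H,
    DG2,
    DH2,
    log_obs_half,  # (M, N, 2K+1)
    obs_fine,  # (M, N, K+1)
    sample_idx,  # (Q,) fine indices of fitted samples
    observed,  # (M, Q) observed values of `gene` at those samples
    s,
    K,
    h,
    cap,
):
    """Squared relative error of P candidate models for one gene, summed over
    all series and fitted samples.  Failed integrations yield inf."""
    P = alphas.shape[0]
    M = log_obs_half.shape[0]
    Q = sample_idx.shape[0]
    sre = np.empty(P)
    for p in range(P):
        tot = 0.0
        good = True
        for m in range(M):
            ok, x = solve_gene(
                gene,
                alphas[p],
                betas[p],
                G[p],
                H[p],
                DG2[p],
                DH2[p],
                log_obs_half[m],
                obs_fine[m],
                s,
                K,
                h,
                cap,
            )
            if not ok:
                good = False
                break
            for q in range(Q):
                o = observed[m, q]
                d = (x[sample_idx[q]] - o) / o
                tot += d * d
        sre[p] = tot if good else np.inf
    return sre
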