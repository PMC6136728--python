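"""Compiled inner loop for the Metropolis-within-Gibbs sampler.

The update rule is identical to the pure-Python path in ``sampler.py``:
single-coordinate normal proposals on (dG, dH, dH0, Ls, R0, ln sigma) in a
fixed cyclic order, accepted by the Metropolis criterion, with states
stored every ``thin`` trial moves.  Optionally, proposal scales are tuned
during the discarded burn-in phase by the standard acceptance-rate rule of
adaptive Metropolis samplers; scales are frozen once storage begins so the
stored chain has a fixed transition kernel.

Compiled with numba's legacy np.random (seedable inside nopython code);
the Python fallback in ``sampler.py`` uses numpy Generators, so the two
backends are each deterministic under a seed but draw different streams.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_core"]

# packed bound indices: dG_lo, dG_hi, dH_lo, dH_hi, dH0_lo, dH0_hi,
#                       lnsig_lo, lnsig_hi, R0_lo, R0_hi
# packed conc params:   mu_L, s_L, mu_R, s_R, r0_flat(0/1)

_TUNE_INTERVAL = 100


@njit(cache=False)
def _logpost(x, q, vfrac, d, V0, RT, bounds, conc, const, n_keep, skip_first):
    dG = x[0]
    dH = x[1]
    dH0 = x[2]
    Ls = x[3]
    R0 = x[4]
    ln_sig = x[5]
    if not (bounds[0] < dG < bounds[1]):
        return -np.inf
    if not (bounds[2] < dH < bounds[3]):
        return -np.inf
    if not (bounds[4] < dH0 < bounds[5]):
        return -np.inf
    if not (bounds[6] < ln_sig < bounds[7]):
        return -np.inf
    if Ls <= 0.0 or not (bounds[8] < R0 < bounds[9]):
        return -np.inf
    mu_L, s_L, mu_R, s_R, r0_flat = conc[0], conc[1], conc[2], conc[3], conc[4]
    zl = (np.log(Ls) - mu_L) / s_L
    lp = -np.log(Ls * s_L) - 0.9189385332046727 - 0.5 * zl * zl
    if r0_flat == 0.0:
        zr = (np.log(R0) - mu_R) / s_R
        lp += -np.log(R0 * s_R) - 0.9189385332046727 - 0.5 * zr * zr
    Ka = np.exp(-dG / RT)
    inv_Ka = 1.0 / Ka
    n = q.shape[0]
    ssr = 0.0
    c_prev = 0.0
    for i in range(n):
        Rtot = R0 * d[i]
        Ltot = Ls * (1.0 - d[i])
        s = Rtot + Ltot + inv_Ka
        disc = s * s - 4.0 * Rtot * Ltot
        if disc < 0.0:
            disc = 0.0
        c = 0.5 * (s - np.sqrt(disc))
        qstar = V0 * dH * 1.0e3 * (c - c_prev * vfrac[i]) + dH0
        c_prev = c
        if skip_first and i == 0:
            continue
        r = q[i] - qstar
        ssr += r * r
    sigma2 = np.exp(2.0 * ln_sig)
    return lp + const - n_keep * ln_sig - 0.5 * ssr / sigma2


@njit(cache=False)
def run_core(
    q,
    vfrac,
    d,
    V0,
    RT,
    bounds,
    conc,
    const,
    n_keep,
    skip_first,
    x0,
    scales,
    n_stored,
    thin,
    burn_moves,
    adapt,
    seed,
):
    np.random.seed(seed)
    n_params = 6
    x = x0.copy()
    sc = scales.copy()
    lp = _logpost(x, q, vfrac, d, V0, RT, bounds, conc, const, n_keep, skip_first)
    out = np.empty((n_stored, n_params + 1))
    n_acc = np.zeros(n_params, dtype=np.int64)
    n_try = np.zeros(n_params, dtype=np.int64)
    win_acc = np.zeros(n_params, dtype=np.int64)
    win_try = np.zeros(n_params, dtype=np.int64)

    total_moves = burn_moves + n_stored * thin
    stored = 0
    for move in range(total_moves):
        i = move % n_params
        old = x[i]
        x[i] = old + sc[i] * np.random.standard_normal()
        lp_new = _logpost(
            x, q, vfrac, d, V0, RT, bounds, conc, const, n_keep, skip_first
        )
        accept = False
        if lp_new > -np.inf:
            if lp_new >= lp or np.random.random() < np.exp(lp_new - lp):
                accept = True
        if accept:
            lp = lp_new
            n_acc[i] += 1
            win_acc[i] += 1
        else:
            x[i] = old
        n_try[i] += 1
        win_try[i] += 1

        in_burn = move < burn_moves
        if adapt and in_burn and win_try[i] >= _TUNE_INTERVAL:
            rate = win_acc[i] / win_try[i]
            if rate < 0.001:
                sc[i] *= 0.1
            elif rate < 0.05:
                sc[i] *= 0.5
            elif rate < 0.2:
                sc[i] *= 0.9
            elif rate > 0.95:
                sc[i] *= 10.0
            elif rate > 0.75:
                sc[i] *= 2.0
            elif rate > 0.5:
                sc[i] *= 1.1
            win_acc[i] = 0
            win_try[i] = 0

        if move == burn_moves - 1:
            # report acceptance over the stored phase only
            for j in range(n_params):
                n_acc[j] = 0
                n_try[j] = 0

        if not in_burn and (move - burn_moves + 1) % thin == 0:
            out[stored, 0] = x[0]
            out[stored, 1] = x[1]
            out[stored, 2] = x[2]
            out[stored, 3] = x[3]
            out[stored, 4] = x[4]
            out[stored, 5] = x[5]
            out[stored, 6] = lp
            stored += 1

    return out, n_acc, n_try, sc
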