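"""Numba forward–backward kernel for the per-branch two-state import HMM.

States: 0 = clonal, 1 = import.  Observations per alignment column:
1 = a substitution was assigned to this branch, 0 = none, -1 = missing
(column unusable).  Emissions are Bernoulli (event probability e0 in the
clonal state, e1 inside an import); missing columns emit 1 under both
states, i.e. are marginalized.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward"]


@njit(cache=True)
def forward_backward(obs, e0, e1, a01, a10):
    """Scaled forward–backward over one branch track.

    Returns (loglik, post1, stats) where post1 is the per-column posterior
    of the import state and stats packs the Baum–Welch sufficient
    statistics: [xi01, xi10, occ0_head, occ1_head, ev0, ev1, occobs0,
    occobs1] (expected transition counts, state occupancies over all but the
    last column, expected event counts and occupancies over observed
    columns).
    """
    L = obs.shape[0]
    post1 = np.zeros(L)
    stats = np.zeros(8)
    if L == 0:
        return 0.0, post1, stats

    denom = a01 + a10
    pi1 = a01 / denom if denom > 0 else 0.5
    pi0 = 1.0 - pi1

    b0 = np.empty(L)
    b1 = np.empty(L)
    for t in range(L):
        o = obs[t]
        if o < 0:
            b0[t] = 1.0
            b1[t] = 1.0
        elif o == 1:
            b0[t] = e0
            b1[t] = e1
        else:
            b0[t] = 1.0 - e0
            b1[t] = 1.0 - e1

    alpha0 = np.empty(L)
    alpha1 = np.empty(L)
    c = np.empty(L)
    a0 = pi0 * b0[0]
    a1 = pi1 * b1[0]
    s = a0 + a1
    if s <= 0.0:
        s = 1e-300
    c[0] = s
    alpha0[0] = a0 / s
    alpha1[0] = a1 / s
    t00 = 1.0 - a01
    t11 = 1.0 - a10
    for t in range(1, L):
        a0 = (alpha0[t - 1] * t00 + alpha1[t - 1] * a10) * b0[t]
        a1 = (alpha0[t - 1] * a01 + alpha1[t - 1] * t11) * b1[t]
        s = a0 + a1
        if s <= 0.0:
            s = 1e-300
        c[t] = s
        alpha0[t] = a0 / s
        alpha1[t] = a1 / s

    beta0 = 1.0
    beta1 = 1.0
    g0 = alpha0[L - 1]
    g1 = alpha1[L - 1]
    post1[L - 1] = g1
    o = obs[L - 1]
    if o >= 0:
        stats[6] += g0
        stats[7] += g1
        if o == 1:
            stats[4] += g0
            stats[5] += g1
    for t in range(L - 2, -1, -1):
        bn0 = b0[t + 1] * beta0
        bn1 = b1[t + 1] * beta1
        # transition expectations from t to t+1
        x01 = alpha0[t] * a01 * bn1 / c[t + 1]
        x10 = alpha1[t] * a10 * bn0 / c[t + 1]
        stats[0] += x01
        stats[1] += x10
        nb0 = (t00 * bn0 + a01 * bn1) / c[t + 1]
        nb1 = (a10 * bn0 + t11 * bn1) / c[t + 1]
        beta0 = nb0
        beta1 = nb1
        g0 = alpha0[t] * beta0
        g1 = alpha1[t] * beta1
        z = g0 + g1
        if z > 0.0:
            g0 /= z
            g1 /= z
        post1[t] = g1
        stats[2] += g0
        stats[3] += g1
        o = obs[t]
        if o >= 0:
            stats[6] += g0
            stats[7] += g1
            if o == 1:
                stats[4] += g0
                stats[5] += g1

    loglik = 0.0
    for t in range(L):
        loglik += np.log(c[t])
    return loglik, post1, stats
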