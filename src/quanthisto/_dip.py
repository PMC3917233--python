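"""Hartigans' dip statistic for unimodality testing.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function.  It is
computed with the classic iterative algorithm over the greatest convex
minorant (GCM) and least concave majorant (LCM) of F_n restricted to a
shrinking modal interval: the largest GCM-LCM discrepancy either confirms
the current modal interval or tightens it, and the one-sided deviations of
F_n from the GCM below and the LCM above the modal interval give the dip.
All deviations are tracked in count units (steps of 1/n) and divided by 2n
at the end; the smallest attainable dip for distinct values is 1/(2n).

The kernel is plain array code, optionally JIT-compiled with numba when it
is importable.
"""

from __future__ import annotations

import numpy as np


def _dip_kernel(x):  # pragma: no cover - exercised via dip_statistic
    """Dip of sorted 1-based-padded data ``x[1..n]`` in count units * 1/(2n).

    ``x`` must be a float64 array of length n+1 with x[0] unused and
    x[1..n] sorted ascending.
    """
    n = x.shape[0] - 1
    if n < 2 or x[n] == x[1]:
        return 0.0
    if n < 4:
        return 1.0 / (2.0 * n)

    # mn[j]: previous touch point of the GCM ending at j
    mn = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or ((x[j] - x[mnj]) * (mnj - mnmnj)
                            < (x[mnj] - x[mnmnj]) * (j - mnj)):
                break
            mn[j] = mnmnj

    # mj[k]: next touch point of the LCM starting at k
    mj = np.zeros(n + 1, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or ((x[k] - x[mjk]) * (mjk - mjmjk)
                            < (x[mjk] - x[mjmjk]) * (k - mjk)):
                break
            mj[k] = mjmjk

    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)
    low, high = 1, n
    dip = 1.0  # lower bound in count units -> 1/(2n) after scaling

    while True:
        # GCM touch points in [low, high], from high down to low
        gcm[1] = high
        l_gcm = 1
        while gcm[l_gcm] > low:
            gcm[l_gcm + 1] = mn[gcm[l_gcm]]
            l_gcm += 1
        # LCM touch points from low up to high
        lcm[1] = low
        l_lcm = 1
        while lcm[l_lcm] < high:
            lcm[l_lcm + 1] = mj[lcm[l_lcm]]
            l_lcm += 1

        ig = l_gcm
        ih = l_lcm
        ix = l_gcm - 1
        iv = 2
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            # largest distance between the GCM and LCM curves in [low, high]
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next point along x is an LCM touch point
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) \
                        - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) \
                        / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next point along x is a GCM touch point
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) \
                        / (x[lcmiv] - x[lcmiv1]) \
                        - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # one-sided dip of F_n against the GCM below the modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for i in range(jb, je + 1):
                    t = (i - jb + 1) - (x[i] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # ... and against the LCM above it
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for i in range(jb, je + 1):
                    t = (x[i] - x[jb]) * c - (i - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew
        low = gcm[ig]
        high = lcm[ih]
        if dip >= d:
            break

    return dip / (2.0 * n)


try:  # JIT the kernel when numba is present; fall back to pure Python
    from numba import njit

    _dip_kernel_jit = njit(cache=True)(_dip_kernel)
except Exception:  # pragma: no cover
    _dip_kernel_jit = _dip_kernel


def dip_statistic(values) -> float:
    """Hartigans' dip of a 1-D sample (0 for constant samples)."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    if v.size == 0:
        raise ValueError("empty sample")
    padded = np.empty(v.size + 1)
    padded[0] = np.nan
    padded[1:] = v
    return float(_dip_kernel_jit(padded))


def dip_pvalue_bootstrap(values, n_boot: int = 2000, seed: int = 0):
    """Dip statistic and bootstrap p-value under the uniform null.

    The null distribution of the dip is sampled from U(0, 1) samples of the
    same size (the dip is invariant to monotone rescaling, so any
    continuous unimodal null gives the same answer as the uniform least
    favourable case).  Returns ``(dip, p)`` with the add-one estimator
    ``p = (1 + #{dip_boot >= dip}) / (1 + n_boot)``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    d_obs = dip_statistic(v)
    if d_obs == 0.0:  # constant sample
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    n = v.size
    count = 0
    padded = np.empty(n + 1)
    padded[0] = np.nan
    for _ in range(int(n_boot)):
        u = rng.random(n)
        u.sort()
        padded[1:] = u
        if _dip_kernel_jit(padded) >= d_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_boot)
    return d_obs, float(p)
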