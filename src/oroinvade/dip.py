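"""Hartigan & Hartigan's dip statistic of unimodality.

Pure-Python/numpy port of the classical algorithm (greatest convex
minorant / least concave majorant cycling on the empirical cdf), plus a
Monte-Carlo p-value calibrated against the uniform null.  The minimum
attainable dip is 1/(2n) (the ``min.is.0 = FALSE`` convention).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "dip_test"]


def dip_statistic(x) -> float:
    """Dip statistic of a 1-D sample (sup-distance to the nearest unimodal cdf, halved)."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 1:
        raise ValueError("dip requires at least one observation")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip requires finite values")
    if n == 1 or x[0] == x[-1]:
        return 0.0
    if n < 4:
        return 1.0 / (2 * n)

    # 1-based arrays to mirror the published algorithm.
    xx = np.empty(n + 1)
    xx[1:] = x

    # mn[j]: previous index in the greatest convex minorant touching j.
    mn = np.empty(n + 1, dtype=np.intp)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xx[j] - xx[mnj]) * (mnj - mnmnj) < (xx[mnj] - xx[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # mj[k]: next index in the least concave majorant touching k.
    mj = np.empty(n + 2, dtype=np.intp)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xx[k] - xx[mjk]) * (mjk - mjmjk) < (xx[mjk] - xx[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in ecdf-count units; scaled by 1/(2n) on return
    gcm = np.empty(n + 2, dtype=np.intp)
    lcm = np.empty(n + 2, dtype=np.intp)

    while True:
        # Change points of the GCM (collected high→low) and LCM (low→high).
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        # Largest distance between the GCM and the LCM on [low, high],
        # walking both sequences of change points from low to high.
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xx[lcmiv] - xx[gcmi1]) * (gcmix - gcmi1) / (
                        xx[gcmix] - xx[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (xx[gcmix] - xx[lcmiv1]) * (lcmiv - lcmiv1) / (xx[lcmiv] - xx[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
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

        # Dip within the convex-minorant side.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xx[jj] - xx[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Dip within the concave-majorant side.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (xx[jj] - xx[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break  # no shrinkage: converged
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


@lru_cache(maxsize=64)
def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    """Sorted dip statistics of ``n_boot`` uniform samples of size ``n`` (cached)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, n, n_boot]))
    out = np.empty(n_boot)
    for b in range(n_boot):
        out[b] = dip_statistic(rng.random(n))
    out.sort()
    return out


def dip_pvalue(dip: float, n: int, n_boot: int = 2000, seed: int = 987654321) -> float:
    """Monte-Carlo p-value of a dip value against the uniform null.

    ``p = (1 + #{null dips >= dip}) / (n_boot + 1)``; the null table is
    simulated once per sample size and cached for the process lifetime.
    """
    null = _null_dips(int(n), int(n_boot), int(seed))
    n_ge = int(null.size - np.searchsorted(null, dip, side="left"))
    return (1.0 + n_ge) / (null.size + 1.0)


def dip_test(x, n_boot: int = 2000, seed: int = 987654321) -> tuple[float, float]:
    """Return ``(dip, p_value)`` for a sample."""
    x = np.asarray(x, dtype=float).ravel()
    d = dip_statistic(x)
    return d, dip_pvalue(d, x.size, n_boot=n_boot, seed=seed)
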