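"""Hartigan–Hartigan dip statistic for unimodality.

Pure-numpy port of the classic algorithm: the dip is the maximum distance
between the empirical CDF and the closest unimodal CDF, computed by
iteratively tightening a modal interval bracketed by the greatest convex
minorant (GCM) and least concave majorant (LCM) of the ECDF.

The p-value is calibrated by parametric bootstrap against the uniform
distribution, the asymptotically least favourable unimodal null.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue"]


def dip_statistic(values) -> float:
    """Dip statistic of a 1D sample.

    Returns 0.0 for samples with fewer than 2 distinct values (a point mass
    is trivially unimodal).  For n sorted distinct points the dip lies in
    [1/(2n), 1/4].
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0

    # 1-based arrays to mirror the published algorithm
    xs = np.empty(n + 1)
    xs[1:] = x
    mn = np.zeros(n + 1, dtype=np.intp)
    mj = np.zeros(n + 1, dtype=np.intp)
    gcm = np.zeros(n + 2, dtype=np.intp)
    lcm = np.zeros(n + 2, dtype=np.intp)

    # pointers defining the GCM of the ECDF over [1, j]
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (xs[mnj] - xs[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # pointers defining the LCM over [k, n]
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (xs[mjk] - xs[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    d = 1.0  # running dip * 2n (the statistic is never below 1/(2n))

    for _ in range(n + 10):  # guard: the bracket tightens every cycle
        # change points of the GCM from high to low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1

        # change points of the LCM from low to high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        # largest distance between GCM and LCM over [low, high]
        dist = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (gcmix - gcmi1) / (
                        xs[gcmix] - xs[gcmi1]
                    )
                    iv += 1
                    if dx >= dist:
                        dist = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= dist:
                        dist = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            dist = 1.0
        if dist <= d:
            break

        # maximum deviation of the ECDF from the two fits inside the brackets
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb = gcm[j + 1]
            je = gcm[j]
            best = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if t > best:
                        best = t
            if best > dip_l:
                dip_l = best
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb = lcm[j]
            je = lcm[j + 1]
            best = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if t > best:
                        best = t
            if best > dip_u:
                dip_u = best

        d = max(d, dip_l, dip_u)
        low = gcm[ig]
        high = lcm[ih]
        if low == high:
            break

    return max(d, 1.0) / (2.0 * n)


# sorted null dip distributions, keyed by (sample size, draws); the null is
# universal (uniform samples), so it can be reused across calls
_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _null_dips(n: int, n_boot: int) -> np.ndarray:
    key = (n, n_boot)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(1_000_003 * n + n_boot)
        _NULL_CACHE[key] = np.sort([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])
    return _NULL_CACHE[key]


def dip_pvalue(
    values,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value under a uniform null.

    Compares against ``n_boot`` uniform null samples of the same size and
    returns the fraction with a dip at least as large (add-one correction
    so the p-value is never exactly 0).  If ``rng`` is given the null is
    drawn fresh from it; otherwise a deterministic cached null table for
    this sample size is used.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2 or np.all(x == x[0]):
        return 0.0, 1.0
    d = dip_statistic(x)
    if rng is None:
        null = _null_dips(n, n_boot)
        n_ge = null.size - np.searchsorted(null, d, side="left")
    else:
        null = np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])
        n_ge = int(np.sum(null >= d))
    p = (1.0 + n_ge) / (n_boot + 1.0)
    return d, float(p)
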