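"""Inverse-CDF transforms of uniform variates used by the vectorized engine.

The population engine advances every cell from its own counter-style uniform
stream, so discrete event counts (mtDNA hits, copy turnover, replication)
must be functions of *one* uniform each.  These helpers implement exact
inverse-CDF sampling of the Poisson and binomial laws, vectorized over
arrays, with the recurrences p(k+1) = p(k)*lam/(k+1) (Poisson) and
p(k+1) = p(k)*(n-k)/(k+1)*p/(1-p) (binomial).

For the event rates the engine works at (lam*dt well below 1) almost every
uniform resolves to zero events at the first CDF term, so the recurrence is
only iterated on the handful of entries that remain unresolved.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["poisson_counts", "binomial_counts", "triangular_ppf", "triangular_cdf"]


def poisson_counts(u: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Poisson(lam) counts via the inverse CDF evaluated at uniforms ``u``.

    Exact for any ``lam >= 0`` (the summation is carried far enough that the
    residual tail mass is below float resolution for the largest mean in the
    array).  Shapes broadcast.
    """
    u = np.asarray(u, dtype=np.float64)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)
    lam = np.broadcast_to(np.asarray(lam, dtype=np.float64), u.shape)
    out = np.zeros(u.shape, dtype=np.int64)
    lam_max = float(lam.max(initial=0.0))
    if lam_max > 0.0:
        p0 = np.exp(-lam)
        idx = np.nonzero(u >= p0)
        if idx[0].size:
            k_max = int(lam_max + 12.0 * math.sqrt(lam_max) + 20.0)
            uu = u[idx]
            ll = lam[idx]
            pmf = p0[idx]
            cdf = pmf.copy()
            counts = np.zeros(uu.shape, dtype=np.int64)
            unresolved = uu >= cdf
            k = 0
            while unresolved.any() and k < k_max:
                k += 1
                pmf = pmf * ll / k
                cdf += pmf
                counts[unresolved] = k
                unresolved = uu >= cdf
            out[idx] = counts
    return out[0] if scalar else out


def binomial_counts(u: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial(n, p) counts via the inverse CDF evaluated at uniforms ``u``."""
    u = np.asarray(u, dtype=np.float64)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)
    n = np.broadcast_to(np.asarray(n, dtype=np.int64), u.shape)
    p = np.clip(np.broadcast_to(np.asarray(p, dtype=np.float64), u.shape), 0.0, 1.0)
    out = np.zeros(u.shape, dtype=np.int64)
    n_max = int(n.max(initial=0))
    if n_max > 0:
        certain = p >= 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            pmf = np.where(certain, 0.0, (1.0 - p) ** n)
            ratio = np.where(certain, 0.0, p / np.where(certain, 1.0, 1.0 - p))
        cdf = pmf.copy()
        unresolved = (u >= cdf) & ~certain & (n > 0)
        k = 0
        while unresolved.any() and k < n_max:
            pmf = pmf * (n - k).clip(min=0) / (k + 1) * ratio
            cdf += pmf
            k += 1
            out[unresolved] = k
            unresolved = (u >= cdf) & (k < n)
        out[certain] = n[certain]
        out = np.minimum(out, n)
    return out[0] if scalar else out


def triangular_ppf(u, a: float, c: float, b: float):
    """Inverse CDF of the triangular(a, mode=c, b) law; supports arrays.

    Degenerate edges (a == c, c == b, or a == b) are handled exactly.
    """
    u = np.asarray(u, dtype=np.float64)
    if b == a:
        return np.full(u.shape, float(a))
    fc = (c - a) / (b - a)
    left = a + np.sqrt(np.clip(u, 0.0, 1.0) * (b - a) * (c - a))
    right = b - np.sqrt((1.0 - np.clip(u, 0.0, 1.0)) * (b - a) * (b - c))
    out = np.where(u < fc, left, right)
    return np.clip(out, a, b)


def triangular_cdf(x, a: float, c: float, b: float):
    """Closed-form CDF of the triangular(a, mode=c, b) law."""
    x = np.asarray(x, dtype=np.float64)
    if b == a:
        return (x >= a).astype(np.float64)
    out = np.zeros(x.shape, dtype=np.float64)
    if c > a:
        lo = (x > a) & (x <= c)
        out[lo] = (x[lo] - a) ** 2 / ((b - a) * (c - a))
    hi = (x > c) & (x < b)
    out[hi] = 1.0 - (b - x[hi]) ** 2 / ((b - a) * (b - c))
    out[x >= b] = 1.0
    return out
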