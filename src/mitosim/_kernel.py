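"""Per-step organelle kernel: the (cell x organelle-slot) part of one
population step.

Two interchangeable implementations of the same discrete map are provided:
a numba-compiled element loop (used when numba is importable) and a
vectorized numpy fallback.  Both consume the same per-cell uniform channels
and the same exact inverse-CDF event transforms, so they produce identical
event counts; floating-point sums may differ at rounding level between the
two paths (a consistency test pins them to each other at 1e-10).

The kernel mutates the organelle arrays in place (OXPHOS capacity, damaged
protein fraction, mtDNA pools, stress state, age, alive mask) and returns
per-cell reductions the cell-level update needs: superoxide production,
post-mitophagy functional capacity and counts, pre-update mean defect, the
defective-organelle count, and the number of organelles removed.
"""

from __future__ import annotations

import math

import numpy as np

from ._random import poisson_counts

try:  # pragma: no cover - exercised implicitly by the consistency test
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# uniform channel indices within one organelle slot (keep in sync with engine)
_U_HITS, _U_DEGW, _U_DEGM, _U_REPL, _U_ALLOC, _U_STATE, _U_PHAGY = range(7)


@njit(cache=True)
def _pois(u: float, lam: float) -> int:
    if lam <= 0.0 or u < 1.0 - lam:  # 1-lam <= exp(-lam): exact shortcut
        return 0
    p = math.exp(-lam)
    c = p
    k = 0
    while u >= c and k < 200:
        k += 1
        p = p * lam / k
        c += p
    return k


@njit(cache=True)
def _binom(u: float, n: int, p: float) -> int:
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    pm = (1.0 - p) ** n
    c = pm
    ratio = p / (1.0 - p)
    k = 0
    while u >= c and k < n:
        pm = pm * (n - k) / (k + 1) * ratio
        c += pm
        k += 1
    return k


@njit(cache=True)
def _organelle_step_nb(
    F, Pd, Nw, Nm, S, age, alive, cell_alive, u,
    ros_dmg, chap, syn, g_nad, k_phagy_eff, state_mult, defective,
    pq_boost, p_up, p_down, dt,
    w_h, flux_floor, k_sox, leak, k_rep_F, k_dmg_F, rep_h_exp,
    k_rep_P, k_dmg_P, k_dmg_dna, k_deg, k_repl, n0, adv,
    prod, sumF, d_sum, n_pre, n_post, n_def, removed,
):
    C, W = F.shape
    for i in range(C):
        prod[i] = 0.0
        sumF[i] = 0.0
        d_sum[i] = 0.0
        n_pre[i] = 0
        n_post[i] = 0
        n_def[i] = 0
        removed[i] = 0
        if not cell_alive[i]:
            continue
        rd = ros_dmg[i]
        a_rep = k_rep_F * chap[i] * syn[i]
        b_F = k_dmg_F * rd
        a_P = k_dmg_P * rd
        b_P = k_rep_P * chap[i]
        kp = k_phagy_eff[i]
        best_j = -1
        best_F = -2.0
        for j in range(W):
            if not alive[i, j]:
                continue
            tot = Nw[i, j] + Nm[i, j]
            h = Nm[i, j] / tot
            d = 1.0 - F[i, j] * (1.0 - w_h * h)
            if d < 0.0:
                d = 0.0
            elif d > 1.0:
                d = 1.0
            n_pre[i] += 1
            d_sum[i] += d
            flux = g_nad[i] * (flux_floor + (1.0 - flux_floor) * F[i, j])
            prod[i] += k_sox * flux * (1.0 + leak * d) + pq_boost

            # OXPHOS capacity: exponential relaxation under damage/repair
            a = a_rep * (1.0 - h) ** rep_h_exp
            r = a + b_F
            if r > 0.0:
                tgt = a / r
                f = tgt + (F[i, j] - tgt) * math.exp(-r * dt)
                F[i, j] = 0.0 if f < 0.0 else (1.0 if f > 1.0 else f)
            # damaged-protein fraction: forward-Euler relaxation
            pd = Pd[i, j] + (a_P * (1.0 - Pd[i, j]) - b_P * Pd[i, j]) * dt
            Pd[i, j] = 0.0 if pd < 0.0 else (1.0 if pd > 1.0 else pd)

            # mtDNA: damage hits, turnover, deficit-driven replication
            hits = _pois(u[i, j, _U_HITS], k_dmg_dna * rd * Nw[i, j] * dt)
            if hits > Nw[i, j]:
                hits = Nw[i, j]
            Nw[i, j] -= hits
            Nm[i, j] += hits
            dw = _pois(u[i, j, _U_DEGW], k_deg * Nw[i, j] * dt)
            if dw > Nw[i, j]:
                dw = Nw[i, j]
            dm = _pois(u[i, j, _U_DEGM], k_deg * Nm[i, j] * dt)
            if dm > Nm[i, j]:
                dm = Nm[i, j]
            if Nw[i, j] + Nm[i, j] - dw - dm >= 1:
                Nw[i, j] -= dw
                Nm[i, j] -= dm
            deficit = n0 - (Nw[i, j] + Nm[i, j])
            if deficit > 0:
                nn = _pois(u[i, j, _U_REPL], k_repl * deficit * dt)
                if nn > 0:
                    p_mut = adv * Nm[i, j] / (adv * Nm[i, j] + Nw[i, j])
                    mu = _binom(u[i, j, _U_ALLOC], nn, p_mut)
                    Nm[i, j] += mu
                    Nw[i, j] += nn - mu
            age[i, j] += dt

            # stress-state machine: one band toward the defect target
            tb = 0 if d < 0.30 else (1 if d < 0.60 else (2 if d < 0.90 else 3))
            us = u[i, j, _U_STATE]
            s = S[i, j]
            if tb > s and us < p_up:
                s += 1
            elif tb < s and us < p_down:
                s -= 1
            S[i, j] = s

            # selective mitophagy (1 - exp(-x) <= x: exact shortcut)
            x = kp * state_mult[s] * dt
            up = u[i, j, _U_PHAGY]
            if up < x and up < 1.0 - math.exp(-x):
                alive[i, j] = False
                removed[i] += 1
                if F[i, j] > best_F:
                    best_F = F[i, j]
                    best_j = j
            else:
                n_post[i] += 1
                sumF[i] += F[i, j]
                if defective[s]:
                    n_def[i] += 1
        if n_post[i] == 0 and best_j >= 0:
            # a cell never digests its last mitochondrion: spare the fittest
            alive[i, best_j] = True
            removed[i] -= 1
            n_post[i] = 1
            sumF[i] = F[i, best_j]
            if defective[S[i, best_j]]:
                n_def[i] = 1


def _organelle_step_np(
    F, Pd, Nw, Nm, S, age, alive, cell_alive, u,
    ros_dmg, chap, syn, g_nad, k_phagy_eff, state_mult, defective,
    pq_boost, p_up, p_down, dt,
    w_h, flux_floor, k_sox, leak, k_rep_F, k_dmg_F, rep_h_exp,
    k_rep_P, k_dmg_P, k_dmg_dna, k_deg, k_repl, n0, adv,
    prod, sumF, d_sum, n_pre, n_post, n_def, removed,
):
    """Vectorized fallback implementing the same map as the numba kernel."""
    W = F.shape[1]
    stepped = cell_alive[:, None] & alive
    u = np.asarray(u, dtype=np.float64)

    total = (Nw + Nm).astype(np.float64)
    h = np.divide(Nm, total, out=np.zeros_like(total), where=total > 0)
    d = np.clip(1.0 - F * (1.0 - w_h * h), 0.0, 1.0)
    flux = g_nad[:, None] * (flux_floor + (1.0 - flux_floor) * F)
    sox = (k_sox * flux * (1.0 + leak * d) + pq_boost) * stepped
    prod[:] = sox.sum(axis=1)
    n_pre[:] = stepped.sum(axis=1)
    d_sum[:] = np.where(stepped, d, 0.0).sum(axis=1)

    a = (k_rep_F * chap * syn)[:, None] * (1.0 - h) ** rep_h_exp
    b = k_dmg_F * ros_dmg[:, None]
    r = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        tgt = np.where(r > 0, a / np.where(r > 0, r, 1.0), F)
    F_new = np.clip(tgt + (F - tgt) * np.exp(-r * dt), 0.0, 1.0)
    F[:] = np.where(stepped, F_new, F)
    dPd = (k_dmg_P * ros_dmg[:, None] * (1.0 - Pd) - (k_rep_P * chap)[:, None] * Pd) * dt
    Pd[:] = np.where(stepped, np.clip(Pd + dPd, 0.0, 1.0), Pd)

    hits = np.minimum(poisson_counts(u[:, :, _U_HITS], k_dmg_dna * ros_dmg[:, None] * Nw * dt), Nw)
    hits = hits * stepped
    Nw -= hits
    Nm += hits
    dw = np.minimum(poisson_counts(u[:, :, _U_DEGW], k_deg * Nw * dt), Nw)
    dm = np.minimum(poisson_counts(u[:, :, _U_DEGM], k_deg * Nm * dt), Nm)
    ok = stepped & (Nw + Nm - dw - dm >= 1)
    Nw -= dw * ok
    Nm -= dm * ok
    deficit = np.maximum(n0 - (Nw + Nm), 0) * stepped
    n_new = poisson_counts(u[:, :, _U_REPL], k_repl * deficit * dt)
    nz = np.nonzero(n_new)
    if nz[0].size:
        from ._random import binomial_counts

        nm_s, nw_s = Nm[nz], Nw[nz]
        denom = adv * nm_s + nw_s
        p_mut = np.divide(adv * nm_s, denom, out=np.zeros_like(denom, dtype=float), where=denom > 0)
        mu = binomial_counts(u[nz[0], nz[1], _U_ALLOC], n_new[nz], p_mut)
        Nm[nz] = nm_s + mu
        Nw[nz] = nw_s + n_new[nz] - mu
    age += dt * stepped

    target = np.zeros_like(S)
    target += (d >= 0.30).astype(np.int8)
    target += (d >= 0.60).astype(np.int8)
    target += (d >= 0.90).astype(np.int8)
    us = u[:, :, _U_STATE]
    up = (us < p_up) & (target > S) & stepped
    down = (us < p_down) & (target < S) & stepped
    S[:] = (S + up.astype(np.int8) - down.astype(np.int8)).astype(np.int8)

    x = k_phagy_eff[:, None] * state_mult[S] * dt
    rem = (u[:, :, _U_PHAGY] < 1.0 - np.exp(-x)) & stepped
    n_alive0 = alive.sum(axis=1)
    would_empty = cell_alive & (n_alive0 > 0) & (rem.sum(axis=1) >= n_alive0)
    if would_empty.any():
        idx = np.where(would_empty)[0]
        best = np.argmax(np.where(rem[idx], F[idx], -1.0), axis=1)
        rem[idx, best] = False
    alive &= ~rem
    removed[:] = rem.sum(axis=1)
    post = cell_alive[:, None] & alive
    n_post[:] = post.sum(axis=1)
    sumF[:] = np.where(post, F, 0.0).sum(axis=1)
    n_def[:] = (defective[S] & post).sum(axis=1)


organelle_step = _organelle_step_nb if HAVE_NUMBA else _organelle_step_np
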