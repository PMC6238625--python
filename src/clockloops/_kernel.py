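"""Compiled fixed-step RK4 integrator for the delayed clock equations.

The delay-differential system is integrated by the method of steps on a
uniform grid.  Delayed regulator levels are read from the already-computed
part of the solution with cubic Lagrange interpolation; lookups that fall
beyond the last computed grid point (possible only when a delay is shorter
than the current Runge-Kutta stage offset) use the stage state itself, which
is exact for zero delay.

Everything here operates on plain arrays so that :mod:`numba` can compile
it; the object-level API lives in :mod:`clockloops.network`.
"""

import numpy as np
from numba import njit

N_GENES = 5

__all__ = ["integrate_dde", "N_GENES"]


@njit(cache=True, inline="always")
def _ipow(x, n):
    r = 1.0
    for _ in range(n):
        r *= x
    return r


@njit(cache=True, inline="always")
def _hist(buf, filled, idx_f, g, y_stage):
    """Interpolated past value of gene g at fractional grid index idx_f."""
    if idx_f >= filled:
        return y_stage[g]
    i1 = int(np.floor(idx_f))
    if i1 < 1 or i1 + 2 > filled:
        if i1 < 0:
            i1 = 0
        if i1 > filled - 1:
            i1 = filled - 1
        f = idx_f - i1
        return buf[i1, g] * (1.0 - f) + buf[i1 + 1, g] * f
    f = idx_f - i1
    ym1 = buf[i1 - 1, g]
    y0 = buf[i1, g]
    y1 = buf[i1 + 1, g]
    y2 = buf[i1 + 2, g]
    return (
        (-f * (f - 1.0) * (f - 2.0) / 6.0) * ym1
        + ((f + 1.0) * (f - 1.0) * (f - 2.0) / 2.0) * y0
        + (-(f + 1.0) * f * (f - 2.0) / 2.0) * y1
        + ((f + 1.0) * f * (f - 1.0) / 6.0) * y2
    )


@njit(cache=True)
def _rhs(
    buf,
    filled,
    t_stage,
    h,
    n_hist,
    y_stage,
    src,
    tgt,
    is_act,
    nexp,
    pa,
    pK,
    pr,
    d,
    tau,
    e_clamped,
    e_clamp,
    g_clamped,
    g_clamp,
    lvl,
    dy,
):
    for s in range(N_GENES):
        if g_clamped[s]:
            lvl[s] = g_clamp[s]
        else:
            idx_f = (t_stage - tau[s]) / h + n_hist
            v = _hist(buf, filled, idx_f, s, y_stage)
            lvl[s] = v if v > 0.0 else 0.0
    for g in range(N_GENES):
        dy[g] = 1.0
    for e in range(src.shape[0]):
        if e_clamped[e]:
            fac = e_clamp[e]
        else:
            y = lvl[src[e]]
            if is_act[e]:
                u = _ipow(y / pK[e], nexp[e])
                fac = (1.0 + pa[e] * u) / (1.0 + u)
            else:
                fac = 1.0 / (1.0 + _ipow(pr[e] * y, nexp[e]))
        dy[tgt[e]] *= fac
    for g in range(N_GENES):
        if g_clamped[g]:
            dy[g] = 0.0
        else:
            dy[g] -= d[g] * y_stage[g]


@njit(cache=True)
def integrate_dde(
    buf,
    n_hist,
    n_steps,
    h,
    src,
    tgt,
    is_act,
    nexp,
    pa,
    pK,
    pr,
    d,
    tau,
    e_clamped,
    e_clamp,
    g_clamped,
    g_clamp,
):
    """Fill buf[n_hist+1:] by RK4 steps; rows 0..n_hist hold the history.

    Returns -1 on success, otherwise the index of the step at which the
    state became non-finite.
    """
    y = np.empty(N_GENES)
    ys = np.empty(N_GENES)
    lvl = np.empty(N_GENES)
    k1 = np.empty(N_GENES)
    k2 = np.empty(N_GENES)
    k3 = np.empty(N_GENES)
    k4 = np.empty(N_GENES)
    for g in range(N_GENES):
        y[g] = buf[n_hist, g]
    for step in range(n_steps):
        filled = n_hist + step
        t = step * h
        _rhs(buf, filled, t, h, n_hist, y, src, tgt, is_act, nexp, pa, pK, pr,
             d, tau, e_clamped, e_clamp, g_clamped, g_clamp, lvl, k1)
        for g in range(N_GENES):
            ys[g] = y[g] + 0.5 * h * k1[g]
        _rhs(buf, filled, t + 0.5 * h, h, n_hist, ys, src, tgt, is_act, nexp,
             pa, pK, pr, d, tau, e_clamped, e_clamp, g_clamped, g_clamp, lvl, k2)
        for g in range(N_GENES):
            ys[g] = y[g] + 0.5 * h * k2[g]
        _rhs(buf, filled, t + 0.5 * h, h, n_hist, ys, src, tgt, is_act, nexp,
             pa, pK, pr, d, tau, e_clamped, e_clamp, g_clamped, g_clamp, lvl, k3)
        for g in range(N_GENES):
            ys[g] = y[g] + h * k3[g]
        _rhs(buf, filled, t + h, h, n_hist, ys, src, tgt, is_act, nexp,
             pa, pK, pr, d, tau, e_clamped, e_clamp, g_clamped, g_clamp, lvl, k4)
        ok = True
        for g in range(N_GENES):
            if g_clamped[g]:
                y[g] = g_clamp[g]
            else:
                y[g] += (h / 6.0) * (k1[g] + 2.0 * k2[g] + 2.0 * k3[g] + k4[g])
                if y[g] < 0.0:
                    y[g] = 0.0
            if not np.isfinite(y[g]):
                ok = False
            buf[filled + 1, g] = y[g]
        if not ok:
            return step
    return -1
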