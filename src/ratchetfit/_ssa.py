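"""Stochastic-simulation kernels for stepping traces.

Exact (Gillespie) simulation of a scheme's continuous-time Markov chain,
embedded in the passive-mode trap mechanics: after every position-changing
event the tether force is re-solved from the force balance
``F = k_eff * (separation - x_tether(F))`` and the force-modulated rates
are refreshed. The kernels are written against plain numpy scalars/arrays
so that they run identically as pure Python; when numba is importable they
are jit-compiled for speed.

Random numbers come from the legacy ``np.random`` module via inverse-CDF
sampling, which numba reproduces bit-for-bit, so a fixed seed yields an
identical event list with or without compilation.
"""

from __future__ import annotations

import math

import numpy as np

# geometry codes
GEOM_OPPOSING = 0
GEOM_HAIRPIN = 1
GEOM_CLAMPED_OPPOSING = 2
GEOM_CLAMPED_HAIRPIN = 3

# end-of-run codes
END_DURATION = 0
END_FORCE_CAP = 1
END_POSITION_LIMIT = 2
END_DISSOCIATED = 3
END_OVERFLOW = 4
END_STUCK = 5


def _maybe_njit(func):
    try:  # pragma: no cover - exercised implicitly
        from numba import njit

        return njit(cache=False, fastmath=False)(func)
    except Exception:  # numba absent or compilation refused
        return func


@_maybe_njit
def _ds_factor(F, lp, S, kbt):
    return 1.0 - 0.5 * math.sqrt(kbt / (F * lp)) + F / S


@_maybe_njit
def _x_nt(F, lc, b, kbt):
    u = b * F / kbt
    if u < 1e-6:
        return lc * u / 3.0
    return lc * (1.0 / math.tanh(u) - 1.0 / u)


@_maybe_njit
def _x_total(F, L_ds, n_nt, lp, S, lc, b, kbt):
    x = L_ds * _ds_factor(F, lp, S, kbt)
    if n_nt > 0.0:
        x += n_nt * _x_nt(F, lc, b, kbt)
    return x


@_maybe_njit
def _solve_force(F_prev, L_ds, n_nt, k_trap, sep, lp, S, lc, b, kbt):
    """Root of g(F) = k_trap*(sep - x(F)) - F, strictly decreasing in F."""
    lo = 1e-9
    hi = 400.0
    F = F_prev
    if not (lo < F < hi):
        F = 10.0
    for _ in range(100):
        x = _x_total(F, L_ds, n_nt, lp, S, lc, b, kbt)
        g = k_trap * (sep - x) - F
        if abs(g) < 1e-9:
            return F
        if g > 0.0:
            lo = F
        else:
            hi = F
        # analytic derivative of the extension
        dxdF = L_ds * (0.25 * math.sqrt(kbt / lp) * F ** (-1.5) + 1.0 / S)
        if n_nt > 0.0:
            u = b * F / kbt
            if u < 1e-6:
                dlang = 1.0 / 3.0
            else:
                sh = math.sinh(u)
                dlang = 1.0 / (u * u) - 1.0 / (sh * sh)
            dxdF += n_nt * lc * dlang * b / kbt
        gp = -k_trap * dxdF - 1.0
        F_new = F - g / gp
        if not (lo < F_new < hi):
            F_new = 0.5 * (lo + hi)
        F = F_new
    return F


@_maybe_njit
def _popen_scalar(F, dg_bp, dg_dest, n_step, m_window, lc, b, kbt):
    u = b * F / kbt
    if u < 1e-4:
        w = u * u / 6.0
    elif u > 30.0:
        w = u - math.log(2.0 * u)
    else:
        w = math.log(math.sinh(u) / u)
    w *= lc / b
    dg = dg_bp - dg_dest - 2.0 * w
    e = -dg
    c = m_window * e if e > 0.0 else 0.0
    s_num = 0.0
    s_den = 0.0
    for j in range(m_window + 1):
        term = math.exp(j * e - c)
        s_den += term
        if j >= n_step:
            s_num += term
    return s_num / s_den


def _run_ssa(
    frm, to, base, mod, move_bp,  # transition tables
    out_idx, out_n,  # per-state out-transition lists (padded) and counts
    geom,
    a_fwd, a_bwd,  # Bell exponents per pN (opposing)
    dg_bp, dg_dest, n_step, m_window,  # fork (hairpin)
    lc_nt, kuhn_b, kbt,
    k_trap, sep, L_ds0, nm_per_bp, lp_ds, s_ds,
    nt_per_bp, pos_max_bp, f_stop, f_clamp,
    koff0, f_off_scale,
    duration, seed, max_events,
    state_burn_in,
    times, poss, forces,
):
    np.random.seed(seed)
    n_tr = frm.shape[0]
    rates = np.empty(n_tr)
    clamped = geom == GEOM_CLAMPED_OPPOSING or geom == GEOM_CLAMPED_HAIRPIN
    hairpin = geom == GEOM_HAIRPIN or geom == GEOM_CLAMPED_HAIRPIN

    pos = 0.0
    if clamped:
        F = f_clamp
    else:
        if hairpin:
            L_ds = L_ds0
            n_nt = nt_per_bp * pos
        else:
            L_ds = L_ds0 - pos * nm_per_bp
            n_nt = 0.0
        F = _solve_force(10.0, L_ds, n_nt, k_trap, sep, lp_ds, s_ds,
                         lc_nt, kuhn_b, kbt)

    if hairpin:
        fwd_mod = _popen_scalar(F, dg_bp, dg_dest, n_step, m_window,
                                lc_nt, kuhn_b, kbt)
        bwd_mod = 1.0
    else:
        fwd_mod = math.exp(-F * a_fwd)
        bwd_mod = math.exp(F * a_bwd)
    for i in range(n_tr):
        if mod[i] == 1:
            rates[i] = base[i] * fwd_mod
        elif mod[i] == 2:
            rates[i] = base[i] * bwd_mod
        else:
            rates[i] = base[i]

    # Relax the chemical state to stationarity at the initial force before
    # recording starts: a measured trace begins mid-activity, not at the
    # enzyme's cycle origin (starting every run at a fixed cycle state
    # would under-count progress in the first window by up to one step).
    state = 0
    if state_burn_in > 0.0:
        tb = 0.0
        while True:
            lam_b = 0.0
            for k in range(out_n[state]):
                lam_b += rates[out_idx[state, k]]
            if lam_b <= 1e-300:
                break
            ub = np.random.random()
            tb += -math.log(1.0 - ub) / lam_b
            if tb > state_burn_in:
                break
            ub2 = np.random.random() * lam_b
            jb = out_idx[state, 0]
            accb = 0.0
            for k in range(out_n[state]):
                jb = out_idx[state, k]
                accb += rates[jb]
                if ub2 < accb:
                    break
            state = to[jb]

    t = 0.0
    n_ev = 0
    times[0] = 0.0
    poss[0] = pos
    forces[0] = F
    n_ev = 1
    end = END_DURATION

    while True:
        lam = 0.0
        for k in range(out_n[state]):
            lam += rates[out_idx[state, k]]
        lam_off = 0.0
        if koff0 > 0.0:
            lam_off = koff0 * math.exp(F / f_off_scale)
        tot = lam + lam_off
        if tot <= 1e-300:
            end = END_STUCK
            break
        u1 = np.random.random()
        dt = -math.log(1.0 - u1) / tot
        if t + dt > duration:
            t = duration
            end = END_DURATION
            break
        t += dt
        u2 = np.random.random() * tot
        if u2 >= lam:
            end = END_DISSOCIATED
            break
        j = out_idx[state, 0]
        acc = 0.0
        for k in range(out_n[state]):
            j = out_idx[state, k]
            acc += rates[j]
            if u2 < acc:
                break
        state = to[j]
        mv = move_bp[j]
        if mv != 0.0:
            pos += mv
            if pos >= pos_max_bp:
                pos = pos_max_bp
                end = END_POSITION_LIMIT
                # fall through to record final event below
            if not clamped:
                if hairpin:
                    L_ds = L_ds0
                    n_nt = nt_per_bp * pos
                else:
                    L_ds = L_ds0 - pos * nm_per_bp
                    n_nt = 0.0
                F = _solve_force(F, L_ds, n_nt, k_trap, sep, lp_ds, s_ds,
                                 lc_nt, kuhn_b, kbt)
                if hairpin:
                    fwd_mod = _popen_scalar(F, dg_bp, dg_dest, n_step,
                                            m_window, lc_nt, kuhn_b, kbt)
                else:
                    fwd_mod = math.exp(-F * a_fwd)
                    bwd_mod = math.exp(F * a_bwd)
                for i in range(n_tr):
                    if mod[i] == 1:
                        rates[i] = base[i] * fwd_mod
                    elif mod[i] == 2:
                        rates[i] = base[i] * bwd_mod
        times[n_ev] = t
        poss[n_ev] = pos
        forces[n_ev] = F
        n_ev += 1
        if end == END_POSITION_LIMIT:
            break
        if (not hairpin) and (not clamped) and F >= f_stop:
            end = END_FORCE_CAP
            break
        if n_ev >= max_events:
            end = END_OVERFLOW
            break
    return n_ev, end, t


_run_ssa_jit = _maybe_njit(_run_ssa)


def run_ssa(*args, compiled: bool = True):
    """Dispatch to the jitted kernel when available."""
    kernel = _run_ssa_jit if compiled else _run_ssa
    return kernel(*args)
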