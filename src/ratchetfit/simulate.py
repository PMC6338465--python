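"""Synthetic single-molecule traces and the stochastic velocity oracle.

Emulates passive-mode dual-trap optical-tweezers experiments on a stepping
helicase: the enzyme's mechano-chemical cycle is simulated exactly
(Gillespie SSA) inside a fixed-trap tether, the force is re-solved from the
passive-mode force balance after every step, and the measured channels
(extension, force) are rendered on a uniform 2,500 Hz grid with Gaussian
measurement noise.

Two tether layouts are supported. In the ``opposing_force`` layout the
enzyme shortens a dsDNA tether by ``delta`` bp per step, so the force rises
along the trace until it is capped (or the enzyme dissociates, typically at
42-50 pN when the optional Bell off-rate is enabled). In the
``hairpin_assisting`` layout each unwound bp releases two ssDNA
nucleotides into the tether, so the extension rises and the force falls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _ssa
from .kinetics import GeometryContext, RateSet, transition_rates
from .polymer import PolymerParams
from .schemes import SchemeSpec

__all__ = [
    "TrapModel",
    "Dissociation",
    "Trace",
    "gillespie_run",
    "ensemble_velocities",
    "render_trace",
    "generate_dataset",
    "simulate_trace",
]


@dataclass(frozen=True)
class TrapModel:
    """Passive-mode trap and tether composition.

    ``k_eff``: combined trap stiffness (pN/nm, both traps in series).
    ``handles_bp``: total dsDNA contour engaged in the tether (bp) — the
    stem+tracks in the opposing layout, the two handles in the hairpin
    layout. ``hairpin_bp``: hairpin stem size (bp; hairpin layout only).
    ``separation_nm``: trap separation; computed from ``f_start`` when None.
    """

    k_eff: float = 0.4
    handles_bp: float = 1450.0
    hairpin_bp: float = 500.0
    separation_nm: float | None = None
    f_start: float = 5.0
    f_stop: float = 50.0
    #: when set, dataset generation draws each trace's starting force
    #: uniformly from this range (activity bursts engage the fork at
    #: varying positions, hence varying initial tension)
    f_start_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.1 <= self.k_eff <= 2.0):
            raise ValueError("k_eff outside the instrument's 0.1-2 pN/nm range")
        if self.handles_bp <= 0:
            raise ValueError("handles_bp must be positive")

    def to_dict(self) -> dict:
        return {
            "k_eff": self.k_eff,
            "handles_bp": self.handles_bp,
            "hairpin_bp": self.hairpin_bp,
            "separation_nm": self.separation_nm,
            "f_start": self.f_start,
            "f_stop": self.f_stop,
        }


@dataclass(frozen=True)
class Dissociation:
    """Bell off-rate k_off(F) = k0 * exp(F / f_scale), terminating a trace."""

    k0: float = 1e-4  # s^-1 at zero force
    f_scale: float = 3.0  # pN


@dataclass
class Trace:
    """One rendered tether time series with metadata and truth annotations."""

    time: np.ndarray  # s, uniform
    extension_nm: np.ndarray
    force_pN: np.ndarray
    geometry: str
    atp: float  # M
    fs: float = 2500.0
    meta: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dt = np.diff(self.time)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 / self.fs):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0


def _compile_transitions(scheme: SchemeSpec, rates: RateSet, atp: float):
    """Flatten the scheme into the kernel's transition tables."""
    n = len(scheme.transitions)
    frm = np.empty(n, dtype=np.int64)
    to = np.empty(n, dtype=np.int64)
    base = np.empty(n, dtype=np.float64)
    mod = np.zeros(n, dtype=np.int64)
    move = np.zeros(n, dtype=np.float64)
    k = {
        "bind": rates.k_plus_b * atp,
        "unbind": rates.k_minus_b,
        "hydrolysis": rates.k_h,
        "release": rates.k_r,
    }
    if scheme.uses_translocation_rates:
        if rates.k_plus_tr is None or rates.k_minus_tr is None:
            raise ValueError(f"scheme {scheme.scheme_id} needs translocation rates")
        k["tr_fwd"] = rates.k_plus_tr
        k["tr_bwd"] = rates.k_minus_tr
    for i, t in enumerate(scheme.transitions):
        frm[i] = scheme.state_index(t.frm)
        to[i] = scheme.state_index(t.to)
        base[i] = k[t.role]
        mod[i] = 1 if t.move > 0 else (2 if t.move < 0 else 0)
        move[i] = t.move * rates.delta
    n_states = scheme.n_states
    max_out = max(np.sum(frm == s) for s in range(n_states))
    out_idx = np.zeros((n_states, max_out), dtype=np.int64)
    out_n = np.zeros(n_states, dtype=np.int64)
    for i in range(n):
        s = frm[i]
        out_idx[s, out_n[s]] = i
        out_n[s] += 1
    return frm, to, base, mod, move, out_idx, out_n


def _mech_params(geometry: GeometryContext, trap: TrapModel,
                 polymer: PolymerParams):
    poly = geometry.polymer or polymer or PolymerParams()
    L_ds0 = trap.handles_bp * poly.nm_per_bp
    if geometry.is_opposing:
        geom = _ssa.GEOM_OPPOSING
        n_nt0 = 0.0
        pos_max = trap.handles_bp  # cannot consume more contour than exists
    else:
        geom = _ssa.GEOM_HAIRPIN
        n_nt0 = 0.0
        pos_max = trap.hairpin_bp
    sep = trap.separation_nm
    if sep is None:
        x0 = _ssa._x_total(trap.f_start, L_ds0, n_nt0, poly.lp_ds, poly.s_ds,
                           poly.nm_per_nt, poly.kuhn_ss, poly.kbt)
        sep = x0 + trap.f_start / trap.k_eff
    return geom, poly, L_ds0, pos_max, float(sep)


def gillespie_run(scheme: SchemeSpec, rates: RateSet, geometry: GeometryContext,
                  trap: TrapModel, atp: float, duration: float, seed: int,
                  polymer: PolymerParams | None = None,
                  dissociation: Dissociation | None = None,
                  force_clamp: float | None = None,
                  state_burn_in: float = 0.2) -> dict:
    """Exact stochastic simulation of one run; returns the event list.

    The returned dict carries ``times`` (s), ``positions`` (bp advanced /
    unwound), ``forces`` (pN, re-solved from the passive-mode force balance
    after every step), the end reason and the inputs needed for rendering.
    Identical arguments (including seed) give identical events.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    tables = _compile_transitions(scheme, rates, atp)
    frm, to, base, mod, move, out_idx, out_n = tables
    geom, poly, L_ds0, pos_max, sep = _mech_params(geometry, trap,
                                                   polymer or PolymerParams())
    if force_clamp is not None:
        geom = (_ssa.GEOM_CLAMPED_OPPOSING if geometry.is_opposing
                else _ssa.GEOM_CLAMPED_HAIRPIN)
    fork = geometry.fork_for(rates)
    a_fwd = rates.xd * geometry.nm_per_bp / geometry.kbt
    a_bwd = (rates.delta - rates.xd) * geometry.nm_per_bp / geometry.kbt
    koff0 = dissociation.k0 if dissociation else 0.0
    f_scale = dissociation.f_scale if dissociation else 1.0

    n_alloc = 1 << 17
    while True:
        times = np.empty(n_alloc, dtype=np.float64)
        poss = np.empty(n_alloc, dtype=np.float64)
        forces = np.empty(n_alloc, dtype=np.float64)
        n_ev, end, t_end = _ssa.run_ssa(
            frm, to, base, mod, move, out_idx, out_n,
            np.int64(geom), a_fwd, a_bwd,
            fork.dg_bp, fork.dG_dest, np.int64(fork.n_step),
            np.int64(fork.m_window),
            poly.nm_per_nt, poly.kuhn_ss, poly.kbt,
            trap.k_eff, sep, L_ds0, poly.nm_per_bp, poly.lp_ds, poly.s_ds,
            2.0, pos_max, trap.f_stop,
            float(force_clamp if force_clamp is not None else 0.0),
            koff0, f_scale,
            float(duration), np.int64(seed), np.int64(n_alloc),
            float(state_burn_in),
            times, poss, forces,
        )
        if end != _ssa.END_OVERFLOW:
            break
        if n_alloc >= 1 << 24:
            raise RuntimeError(
                "simulation exceeded the event budget; state dump: "
                f"scheme={scheme.scheme_id} atp={atp} last_F={forces[n_ev - 1]:.2f} "
                f"last_pos={poss[n_ev - 1]:.1f}"
            )
        n_alloc <<= 2
    return {
        "times": times[:n_ev].copy(),
        "positions": poss[:n_ev].copy(),
        "forces": forces[:n_ev].copy(),
        "end": int(end),
        "t_end": float(t_end),
        "geometry": geometry.mode,
        "separation_nm": sep,
        "trap": trap,
        "polymer": poly,
        "atp": atp,
        "seed": int(seed),
        "scheme_id": scheme.scheme_id,
        "rates": rates,
    }


def ensemble_velocities(scheme: SchemeSpec, rates: RateSet, force: float,
                        atp: float, geometry: GeometryContext, n_runs: int,
                        duration: float, seed: int,
                        burn_in: float = 0.15) -> np.ndarray:
    """Mean velocities (bp/s) of ``n_runs`` force-clamped Gillespie runs.

    A vectorized exact SSA at fixed force: rates are constant, so the chain
    is sampled for all runs simultaneously. A burn-in period relaxes the
    initial condition to stationarity before displacement is accumulated.
    Serves as the independent stochastic oracle for the analytic velocity.
    """
    tr = transition_rates(scheme, rates, force, atp, geometry)
    tr = np.atleast_1d(np.asarray(tr, dtype=float)).reshape(-1)
    n_t = len(scheme.transitions)
    frm = np.array([scheme.state_index(t.frm) for t in scheme.transitions])
    to = np.array([scheme.state_index(t.to) for t in scheme.transitions])
    move = np.array([t.move * rates.delta for t in scheme.transitions])
    S = scheme.n_states
    max_out = max(int(np.sum(frm == s)) for s in range(S))
    out_idx = np.zeros((S, max_out), dtype=np.int64)
    out_n = np.zeros(S, dtype=np.int64)
    for i in range(n_t):
        s = frm[i]
        out_idx[s, out_n[s]] = i
        out_n[s] += 1
    rate_tab = np.zeros((S, max_out))
    for s in range(S):
        for k in range(out_n[s]):
            rate_tab[s, k] = tr[out_idx[s, k]]
    cum = np.cumsum(rate_tab, axis=1)
    lam = cum[:, -1]
    if np.all(lam <= 0):
        return np.zeros(n_runs)

    rng = np.random.default_rng(seed)
    state = np.zeros(n_runs, dtype=np.int64)
    pos = np.zeros(n_runs)

    def _phase(state, pos, T, track):
        t = np.zeros(n_runs)
        active = np.ones(n_runs, dtype=bool)
        # all runs advance together; finished runs draw dead random numbers
        # but skip the state/position update, keeping the loop branch-free
        for _ in range(400_000_000 // max(n_runs, 1)):
            if not active.any():
                return state, pos
            lam_a = lam[state]
            safe = lam_a > 0
            t_new = t + rng.exponential(1.0, size=n_runs) / np.where(
                safe, lam_a, 1.0)
            fire = active & safe & (t_new <= T)
            active &= safe & (t_new <= T)
            u = (rng.random(n_runs) * lam_a)[:, None]
            pick = (u < cum[state]).argmax(axis=1)
            j = out_idx[state, pick]
            t[fire] = t_new[fire]
            if track:
                pos[fire] += move[j[fire]]
            state[fire] = to[j[fire]]
        raise RuntimeError("ensemble SSA exceeded its iteration budget")

    if burn_in > 0:
        state, pos = _phase(state, pos, burn_in, track=False)
    pos[:] = 0.0
    state, pos = _phase(state, pos, duration, track=True)
    return pos / duration


def render_trace(events: dict, sigma_nm: float = 2.0, fs: float = 2500.0,
                 seed: int | None = None) -> Trace:
    """Sample an event list onto the uniform measurement grid.

    Position is piecewise constant between events; the noiseless extension
    is ``separation - F/k_eff``. Gaussian noise of ``sigma_nm`` is added to
    the extension and propagated to the force channel through the trap
    stiffness (a +eps extension error reads as a -k_eff*eps force error).
    """
    trap: TrapModel = events["trap"]
    t_end = events["t_end"]
    n_samp = max(int(math.floor(t_end * fs)) + 1, 2)
    t = np.arange(n_samp) / fs
    idx = np.searchsorted(events["times"], t, side="right") - 1
    idx = np.clip(idx, 0, len(events["times"]) - 1)
    F = events["forces"][idx]
    x = events["separation_nm"] - F / trap.k_eff
    if sigma_nm > 0:
        rng = np.random.default_rng(events["seed"] + 1 if seed is None else seed)
        eps = rng.normal(0.0, sigma_nm, size=n_samp)
        x_meas = x + eps
        F_meas = F - trap.k_eff * eps
    else:
        x_meas, F_meas = x, F
    steps = events["positions"]
    moved = np.flatnonzero(np.diff(steps) != 0.0) + 1
    return Trace(
        time=t,
        extension_nm=x_meas,
        force_pN=np.maximum(F_meas, 0.0),
        geometry=events["geometry"],
        atp=events["atp"],
        fs=fs,
        meta={
            "seed": events["seed"],
            "sigma_nm": sigma_nm,
            "scheme_id": events["scheme_id"],
            "rates": events["rates"].to_dict(),
            "trap": trap.to_dict(),
            "separation_nm": events["separation_nm"],
            "handles_bp": trap.handles_bp,
            "end": events["end"],
        },
        annotations={
            "step_times": events["times"][moved],
            "step_positions": steps[moved],
        },
    )


def simulate_trace(scheme: SchemeSpec, rates: RateSet, geometry: GeometryContext,
                   trap: TrapModel, atp: float, duration: float, seed: int,
                   polymer: PolymerParams | None = None,
                   sigma_nm: float = 2.0, fs: float = 2500.0,
                   dissociation: Dissociation | None = None) -> Trace:
    """Convenience: gillespie_run followed by render_trace."""
    ev = gillespie_run(scheme, rates, geometry, trap, atp, duration, seed,
                       polymer=polymer, dissociation=dissociation)
    return render_trace(ev, sigma_nm=sigma_nm, fs=fs)


def generate_dataset(plan: Sequence[tuple[GeometryContext, TrapModel, RateSet, float, int]],
                     scheme: SchemeSpec, seed: int, duration: float = 3.0,
                     sigma_nm: float = 2.0, fs: float = 2500.0,
                     polymer: PolymerParams | None = None,
                     dissociation: Dissociation | None = None) -> list[Trace]:
    """Reproducible multi-condition dataset.

    ``plan`` rows are ``(geometry, trap, rates, atp_M, n_traces)``; per-trace
    seeds are derived deterministically from the master ``seed`` so the same
    master seed always yields an identical dataset.
    """
    if not plan:
        raise ValueError("plan must be non-empty")
    ss = np.random.SeedSequence(seed)
    traces: list[Trace] = []
    for (geometry, trap, rates, atp, n_traces) in plan:
        for _ in range(n_traces):
            child = ss.spawn(1)[0]
            run_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            tr = trap
            if trap.f_start_range is not None:
                lo, hi = trap.f_start_range
                f0 = float(np.random.default_rng(run_seed + 7).uniform(lo, hi))
                tr = replace(trap, f_start=f0, f_start_range=None)
            traces.append(
                simulate_trace(scheme, rates, geometry, tr, atp, duration,
                               run_seed, polymer=polymer, sigma_nm=sigma_nm,
                               fs=fs, dissociation=dissociation)
            )
    return traces
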