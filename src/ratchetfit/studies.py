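"""Canonical validation studies of the whole pipeline.

These are the package's self-checks, each a seeded, deterministic study
run at the reference conditions of :mod:`ratchetfit.conditions`:

* analytic steady-state velocities against the exact stochastic oracle;
* the Michaelis-Menten functional form of every cycle;
* the logistic force-velocity reduction of power-stroke-like cycles;
* end-to-end closure of simulate -> process against the analytic surface;
* parameter recovery and scheme selection on replicate synthetic studies;
* the two-context ratchet-equilibrium contrast.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import conditions as C
from .fitting import FitResult, global_fit, select_model
from .kinetics import (GeometryContext, fit_logistic, fit_mm_curve,
                       steady_state_velocity, velocity_grid)
from .pipeline import ForceVelocityDataset, process_traces
from .schemes import SchemeSpec, enumerate_schemes, get_scheme
from .simulate import ensemble_velocities

__all__ = [
    "oracle_equivalence_study",
    "mm_form_study",
    "logistic_reduction_study",
    "closure_study",
    "closure_zscores",
    "recovery_selection_study",
    "context_contrast_study",
]

OPPOSING_FORCES = (0.0, 8.0, 16.0, 24.0, 32.0)
HAIRPIN_FORCES = (2.0, 6.0, 10.0, 13.0, 15.0)

TRUTH_SCHEME_ID = "br-binding"


def _context(geom_name: str):
    if geom_name == "opposing":
        return C.geometry_in_complex(), C.rates_in_complex(), OPPOSING_FORCES
    return C.geometry_isolated(), C.rates_isolated(), HAIRPIN_FORCES


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _steady_state_event_rate(scheme, rates, F, atp, geom) -> float:
    """Expected SSA events per second at stationarity (all transitions)."""
    from .kinetics import _steady_state_occupancy, transition_rates

    tr = np.atleast_1d(transition_rates(scheme, rates, F, atp, geom)).ravel()
    pi = _steady_state_occupancy(scheme,
                                 transition_rates(scheme, rates, F, atp, geom))
    total = 0.0
    for i, t in enumerate(scheme.transitions):
        total += pi[..., scheme.state_index(t.frm)] * tr[i]
    return float(total)


def oracle_equivalence_study(seed: int, n_runs: int = 200,
                             schemes: list[SchemeSpec] | None = None,
                             atp_grid=C.ATP_GRID_M) -> pd.DataFrame:
    """Analytic velocity vs Gillespie ensemble mean over the full grid.

    Every scheme x geometry x (5 force x 5 [ATP]) cell is simulated with
    ``n_runs`` force-clamped runs; the run length is scaled so that slow
    cells still accumulate enough steps for a meaningful standard error.
    Returns one row per cell with the z-score of the discrepancy.
    """
    schemes = schemes or enumerate_schemes()
    rows = []
    cell_seeds = iter(_spawn_seeds(seed, len(schemes) * 2 * 25))
    for scheme in schemes:
        for geom_name in ("opposing", "hairpin"):
            geom, rates, forces = _context(geom_name)
            for F in forces:
                for atp in atp_grid:
                    s = next(cell_seeds)
                    va = steady_state_velocity(scheme, rates, F, atp, geom)
                    # aim for ~30 steps per run, within practical bounds,
                    # and cap the expected event count per run (ratchet
                    # flip-flops can outnumber productive steps 1000-fold)
                    T = float(np.clip(30 * rates.delta / max(abs(va), 0.5),
                                      0.4, 20.0))
                    ev_rate = _steady_state_event_rate(scheme, rates, F, atp,
                                                       geom)
                    T = min(T, max(1e4 / max(ev_rate, 1.0), 0.02))
                    v = ensemble_velocities(scheme, rates, F, atp, geom,
                                            n_runs=n_runs, duration=T, seed=s)
                    sem = float(v.std(ddof=1) / math.sqrt(n_runs))
                    dev = float(v.mean() - va)
                    z = dev / sem if sem > 0 else (0.0 if dev == 0 else np.inf)
                    rows.append({
                        "scheme": scheme.scheme_id, "geometry": geom.mode,
                        "force": F, "atp": atp, "v_analytic": va,
                        "v_sim": float(v.mean()), "sem": sem, "z": z,
                        "duration": T,
                    })
    return pd.DataFrame(rows)


def mm_form_study() -> pd.DataFrame:
    """R^2 of a Michaelis-Menten fit to every scheme's analytic v([ATP])."""
    rows = []
    for scheme in enumerate_schemes():
        for geom_name in ("opposing", "hairpin"):
            geom, rates, forces = _context(geom_name)
            for F in forces[:4]:
                T = np.logspace(-6, -1.3, 25)
                v = velocity_grid(scheme, rates, F, T, geom)
                mm = fit_mm_curve(T, v)
                resid = v - mm.velocity(T)
                ssv = np.sum((v - v.mean()) ** 2)
                r2 = 1 - np.sum(resid**2) / ssv if ssv > 0 else 1.0
                rows.append({"scheme": scheme.scheme_id, "geometry": geom.mode,
                             "force": F, "r2": r2})
    return pd.DataFrame(rows)


def logistic_reduction_study(atp: float = 2e-3) -> pd.DataFrame:
    """Max relative deviation of saturating-[ATP] v(F) from the logistic law.

    Covers the three power-stroke cycles and, with a forward-loaded barrier
    (x_dagger = delta) and translocation attempt rates far above the
    chemical rates, the three Brownian-ratchet cycles.
    """
    F = np.linspace(0.0, 60.0, 31)
    rows = []
    base = C.rates_in_complex()
    for scheme in enumerate_schemes():
        if scheme.uses_translocation_rates:
            rates = base.with_(k_plus_tr=1e12, k_minus_tr=1e11)
            case = "fast ratchet, x_dagger = delta"
        else:
            rates = base
            case = "power stroke"
        v = velocity_grid(scheme, rates, F, atp)
        if np.ptp(v) <= 1e-9 * np.abs(v).max():
            # a force-insensitive curve is the degenerate logistic limit
            rows.append({"scheme": scheme.scheme_id, "case": case,
                         "max_rel_err": 0.0})
            continue
        fit = fit_logistic(F, v)
        pred = fit.v0 / (1.0 + np.exp((F - fit.F_half) / fit.F0))
        rel = np.abs(pred - v) / np.maximum(np.abs(v), 1e-300)
        rows.append({"scheme": scheme.scheme_id, "case": case,
                     "max_rel_err": float(rel.max())})
    return pd.DataFrame(rows)


def closure_study(seed: int, n_traces: int = 10):
    """Simulate the full study, process it, and z-score every bin.

    Returns ``(dataset, zscores)`` where ``zscores`` has one row per
    (geometry, [ATP], force-bin) with the measured and analytic velocity.
    """
    traces = C.make_study_traces(seed, n_traces=n_traces,
                                 scheme=get_scheme(TRUTH_SCHEME_ID))
    dataset = process_traces(traces)
    return dataset, closure_zscores(dataset)


def closure_zscores(dataset: ForceVelocityDataset) -> pd.DataFrame:
    scheme = get_scheme(TRUTH_SCHEME_ID)
    rows = []
    for _, row in dataset.table.iterrows():
        if row["geometry"] == "opposing_force":
            geom, rates = C.geometry_in_complex(), C.rates_in_complex()
        else:
            geom, rates = C.geometry_isolated(), C.rates_isolated()
        va = float(velocity_grid(scheme, rates, row["f_mean"], row["atp"],
                                 geom))
        z = (row["v_mean"] - va) / row["v_sem"]
        rows.append({"geometry": row["geometry"], "atp": row["atp"],
                     "f_bin": row["f_bin"], "f_mean": row["f_mean"],
                     "v_mean": row["v_mean"], "v_sem": row["v_sem"],
                     "v_analytic": va, "z": z})
    return pd.DataFrame(rows)


def recovery_selection_study(seed: int, n_replicates: int = 10,
                             n_traces: int = 10, n_starts: int = 6
                             ) -> pd.DataFrame:
    """Replicate parameter-recovery and scheme-selection study.

    Each replicate simulates a fresh two-geometry study from the reference
    truth, processes it, fits all six schemes (shared-chemistry mode,
    1/s.e.m.^2 weights), and records the ranking plus the truth-scheme
    parameter estimates.
    """
    truth = get_scheme(TRUTH_SCHEME_ID)
    truth_rates = C.rates_in_complex()
    g_op, g_hp = C.geometry_in_complex(), C.geometry_isolated()
    rows = []
    for i, rep_seed in enumerate(_spawn_seeds(seed, n_replicates)):
        traces = C.make_study_traces(rep_seed, n_traces=n_traces,
                                     scheme=truth)
        ds = process_traces(traces)
        ranking = select_model([ds, ds], [g_op, g_hp],
                               mode="shared_chemistry", n_starts=n_starts,
                               seed=rep_seed, weights="sem")
        fit = next(f for f in ranking if f.scheme_id == truth.scheme_id)
        r_op = fit.rates["opposing_force"]
        r_hp = fit.rates["hairpin_assisting"]
        rows.append({
            "replicate": i,
            "top_scheme": ranking[0].scheme_id,
            "truth_ranked_first": ranking[0].scheme_id == truth.scheme_id,
            "delta_fit": r_op.delta,
            "delta_rel_err": abs(r_op.delta / truth_rates.delta - 1.0),
            "keq_op": r_op.k_eq,
            "keq_op_factor": max(r_op.k_eq / truth_rates.k_eq,
                                 truth_rates.k_eq / r_op.k_eq),
            "keq_hp": r_hp.k_eq,
            "dG_dest": r_hp.dG_dest,
            "sse": fit.sse,
            "r2": fit.r2,
        })
    return pd.DataFrame(rows)


def context_contrast_study(seed: int, n_replicates: int = 3,
                           n_traces: int = 20, n_starts: int = 8):
    """Recover the ratchet-equilibrium shift between the two enzyme contexts.

    Simulates replicate paired studies (identical chemistry, 200-fold
    translocation-equilibrium shift, different geometry), fits the truth
    scheme in shared-chemistry mode, and reports the per-replicate and
    geometric-mean K_eq ratio together with the last replicate's fit.
    """
    truth = get_scheme(TRUTH_SCHEME_ID)
    g_op, g_hp = C.geometry_in_complex(), C.geometry_isolated()
    ratios, fits = [], []
    for rep_seed in _spawn_seeds(seed + 1, n_replicates):
        traces = C.make_study_traces(rep_seed, n_traces=n_traces,
                                     scheme=truth)
        ds = process_traces(traces)
        fit = global_fit(truth, [ds, ds], [g_op, g_hp],
                         mode="shared_chemistry", n_starts=n_starts,
                         seed=rep_seed, weights="sem")
        r_op = fit.rates["opposing_force"]
        r_hp = fit.rates["hairpin_assisting"]
        ratios.append(r_hp.k_eq / r_op.k_eq)
        fits.append(fit)
    geo_mean = float(np.exp(np.mean(np.log(ratios))))
    return {"ratios": ratios, "ratio_geo_mean": geo_mean, "fits": fits}


def fitted_velocity_curve(fit: FitResult, geometry: GeometryContext,
                          forces, atp: float = 2e-3) -> np.ndarray:
    """Velocity of a fitted model along a force axis at fixed [ATP]."""
    scheme = get_scheme(fit.scheme_id)
    rates = fit.rates[geometry.mode]
    return np.asarray(velocity_grid(scheme, rates, np.asarray(forces, float),
                                    atp, geometry))
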