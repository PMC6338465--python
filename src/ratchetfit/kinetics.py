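"""Steady-state kinetics of the candidate cycles under force.

The cycle of a :class:`~ratchetfit.schemes.SchemeSpec` is a single-loop
continuous-time Markov chain. Its steady-state occupancies solve
``pi Q = 0`` with ``sum(pi) = 1``; the unwinding velocity is the step size
times the net probability flux through the translocation-carrying
transition. Force enters in one of two ways, depending on the assay
geometry:

* ``opposing_force`` (helicase translocating against the tether tension):
  Bell/Kramers factors on the translocation transition — the forward rate
  is reduced by ``exp(-F x‡ / kBT)`` and the backward rate increased by
  ``exp(+F (δ - x‡) / kBT)``, with ``x‡`` the distance to the transition
  state and ``δ`` the step, both expressed as distances along the DNA.

* ``hairpin_assisting`` (hairpin under tension ahead of the helicase):
  the forward translocation rate is multiplied by the fork-opening
  probability ``P_open(F)``; force does not otherwise enter the cycle.

All rates in s^-1 (ATP binding second order, M^-1 s^-1), forces in pN,
velocities in bp/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .polymer import KBT_PN_NM, NM_PER_BP, ForkParams, PolymerParams, p_open
from .schemes import SchemeSpec

__all__ = [
    "RateSet",
    "GeometryContext",
    "MMParams",
    "LogisticParams",
    "bell_factors",
    "equilibrium_shift",
    "transition_rates",
    "steady_state_velocity",
    "velocity_grid",
    "mm_parameters",
    "logistic_velocity",
    "fit_logistic",
]


@dataclass(frozen=True)
class RateSet:
    """Microscopic rate constants and coupling parameters for one enzyme context.

    Parameters
    ----------
    k_plus_b, k_minus_b:
        ATP binding (M^-1 s^-1) and unbinding (s^-1) rates.
    k_h, k_r:
        Irreversible hydrolysis and product-release rates (s^-1).
    k_plus_tr, k_minus_tr:
        Forward/backward translocation attempt rates (s^-1); required for
        Brownian-ratchet schemes, ignored by power-stroke schemes.
    delta:
        Step size (bp), > 0.
    x_dagger:
        Distance to the translocation transition state (bp); defaults to
        ``delta`` (fully forward-loaded barrier).
    dG_dest:
        Fork destabilization free energy contributed by the enzyme (kBT).
    """

    k_plus_b: float
    k_minus_b: float
    k_h: float
    k_r: float
    delta: float = 3.3
    k_plus_tr: float | None = None
    k_minus_tr: float | None = None
    x_dagger: float | None = None
    dG_dest: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_plus_b", "k_minus_b", "k_h", "k_r", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("k_plus_tr", "k_minus_tr"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dG_dest < 0:
            raise ValueError("dG_dest must be >= 0")
        xd = self.x_dagger
        if xd is not None and not (0 < xd <= self.delta):
            raise ValueError("x_dagger must satisfy 0 < x_dagger <= delta")

    @property
    def xd(self) -> float:
        """Effective transition-state distance (bp); defaults to ``delta``."""
        return self.delta if self.x_dagger is None else self.x_dagger

    @property
    def k_eq(self) -> float:
        """Zero-force translocation equilibrium constant k-tr / k+tr."""
        if self.k_plus_tr is None or self.k_minus_tr is None:
            raise ValueError("translocation rates not set (power-stroke context?)")
        return self.k_minus_tr / self.k_plus_tr

    @property
    def k_c_eff(self) -> float:
        """Effective catalytic rate kh*kr / (kh + kr), <= min(kh, kr)."""
        return self.k_h * self.k_r / (self.k_h + self.k_r)

    def with_(self, **kw) -> "RateSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "k_plus_b": self.k_plus_b,
            "k_minus_b": self.k_minus_b,
            "k_h": self.k_h,
            "k_r": self.k_r,
            "k_plus_tr": self.k_plus_tr,
            "k_minus_tr": self.k_minus_tr,
            "delta": self.delta,
            "x_dagger": self.x_dagger,
            "dG_dest": self.dG_dest,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        return cls(**{k: d.get(k) for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class GeometryContext:
    """How the applied force couples to the cycle in one assay geometry.

    ``opposing_force``: Bell factors on the translocation transition.
    ``hairpin_assisting``: forward translocation multiplied by P_open(F),
    computed from ``fork`` and ``polymer`` (the enzyme's ``dG_dest``
    overrides the fork default when set on the :class:`RateSet`).
    """

    mode: str = "opposing_force"
    kbt: float = KBT_PN_NM
    nm_per_bp: float = NM_PER_BP
    fork: ForkParams | None = None
    polymer: PolymerParams | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("opposing_force", "hairpin_assisting"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")

    @property
    def is_opposing(self) -> bool:
        return self.mode == "opposing_force"

    def fork_for(self, rates: RateSet) -> ForkParams:
        fork = self.fork or ForkParams()
        if rates.dG_dest != fork.dG_dest:
            fork = fork.with_(dG_dest=rates.dG_dest)
        return fork


OPPOSING = GeometryContext(mode="opposing_force")


def bell_factors(force, delta: float, x_dagger: float,
                 kbt: float = KBT_PN_NM, nm_per_bp: float = NM_PER_BP):
    """Bell multipliers (forward, backward) for a translocation step under load.

    forward = exp(-F x‡ / kBT), backward = exp(+F (δ - x‡) / kBT), with the
    bp distances converted at ``nm_per_bp``. Their ratio satisfies
    forward/backward = exp(-F δ / kBT) for every x‡.
    """
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    if not (0 < x_dagger <= delta):
        raise ValueError("x_dagger must satisfy 0 < x_dagger <= delta")
    fwd = np.exp(-F * x_dagger * nm_per_bp / kbt)
    bwd = np.exp(F * (delta - x_dagger) * nm_per_bp / kbt)
    return fwd, bwd


def equilibrium_shift(k_eq, force, delta: float,
                      kbt: float = KBT_PN_NM, nm_per_bp: float = NM_PER_BP):
    """Force-shifted translocation equilibrium constant K -> K exp(F δ / kBT)."""
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    if np.any(np.asarray(k_eq) <= 0):
        raise ValueError("k_eq must be positive")
    return k_eq * np.exp(F * delta * nm_per_bp / kbt)


def transition_rates(scheme: SchemeSpec, rates: RateSet, force, atp,
                     geometry: GeometryContext = OPPOSING) -> np.ndarray:
    """Propensity of every directed transition of ``scheme``, broadcast over inputs.

    Returns an array of shape ``broadcast(force, atp).shape + (n_transitions,)``
    ordered as ``scheme.transitions``.
    """
    F, T = np.broadcast_arrays(np.asarray(force, dtype=float),
                               np.asarray(atp, dtype=float))
    if np.any(T < 0):
        raise ValueError("[ATP] must be >= 0")
    base = {
        "bind": rates.k_plus_b,  # times [ATP] below
        "unbind": rates.k_minus_b,
        "hydrolysis": rates.k_h,
        "release": rates.k_r,
    }
    if scheme.uses_translocation_rates:
        if rates.k_plus_tr is None or rates.k_minus_tr is None:
            raise ValueError(f"scheme {scheme.scheme_id} needs k_plus_tr/k_minus_tr")
        base["tr_fwd"] = rates.k_plus_tr
        base["tr_bwd"] = rates.k_minus_tr

    if geometry.is_opposing:
        fwd_mod, bwd_mod = bell_factors(F, rates.delta, rates.xd,
                                        geometry.kbt, geometry.nm_per_bp)
    else:
        fork = geometry.fork_for(rates)
        fwd_mod = np.asarray(p_open(F, fork, geometry.polymer))
        bwd_mod = np.ones_like(F)

    out = np.empty(F.shape + (len(scheme.transitions),), dtype=float)
    for i, t in enumerate(scheme.transitions):
        k = base[t.role]
        r = k * T if t.role == "bind" else np.full_like(F, k)
        if t.move > 0:
            r = r * fwd_mod
        elif t.move < 0:
            r = r * bwd_mod
        out[..., i] = r
    return out


def _steady_state_occupancy(scheme: SchemeSpec, trans_rates: np.ndarray) -> np.ndarray:
    """Occupancies pi (shape ``batch + (n_states,)``) from per-transition rates."""
    S = scheme.n_states
    batch = trans_rates.shape[:-1]
    Q = np.zeros(batch + (S, S), dtype=float)
    for i, t in enumerate(scheme.transitions):
        a, b = scheme.state_index(t.frm), scheme.state_index(t.to)
        Q[..., a, b] += trans_rates[..., i]
        Q[..., a, a] -= trans_rates[..., i]
    # Solve pi Q = 0 with normalization: replace one column of Q^T by ones.
    A = np.swapaxes(Q, -1, -2).copy()
    A[..., -1, :] = 1.0
    rhs = np.zeros(batch + (S,), dtype=float)
    rhs[..., -1] = 1.0
    try:
        pi = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as err:
        raise ArithmeticError(
            f"singular steady-state generator for scheme {scheme.scheme_id}"
        ) from err
    if not np.all(np.isfinite(pi)):
        raise ArithmeticError(
            f"ill-conditioned steady-state solve for scheme {scheme.scheme_id}"
        )
    return pi


def velocity_grid(scheme: SchemeSpec, rates: RateSet, force, atp,
                  geometry: GeometryContext = OPPOSING) -> np.ndarray:
    """Steady-state unwinding velocity (bp/s), broadcast over force/atp arrays."""
    tr = transition_rates(scheme, rates, force, atp, geometry)
    pi = _steady_state_occupancy(scheme, tr)
    flux = np.zeros(tr.shape[:-1], dtype=float)
    for i, t in enumerate(scheme.transitions):
        if t.move:
            flux += t.move * pi[..., scheme.state_index(t.frm)] * tr[..., i]
    return rates.delta * flux


def steady_state_velocity(scheme: SchemeSpec, rates: RateSet, force: float,
                          atp: float, geometry: GeometryContext = OPPOSING) -> float:
    """Scalar steady-state velocity (bp/s) at one (force, [ATP]) condition."""
    return float(velocity_grid(scheme, rates, force, atp, geometry))


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters at one force: v = v_max [T] / (K_M + [T])."""

    v_max: float  # bp/s
    K_M: float  # M
    force: float  # pN
    v_max_err: float | None = None
    K_M_err: float | None = None

    def velocity(self, atp):
        T = np.asarray(atp, dtype=float)
        return self.v_max * T / (self.K_M + T)


def mm_parameters(scheme: SchemeSpec, rates: RateSet, force: float,
                  geometry: GeometryContext = OPPOSING,
                  sat_rtol: float = 1e-6, km_rtol: float = 1e-8) -> MMParams:
    """Force-dependent v_max and K_M of a scheme, computed numerically.

    v_max is the saturating-[ATP] limit (scanned decade by decade until the
    relative change drops below ``sat_rtol``); K_M is bracketed and bisected
    to relative tolerance ``km_rtol`` as the [ATP] at half-maximal velocity.
    """
    T = 1e-6
    v_prev = steady_state_velocity(scheme, rates, force, T, geometry)
    for _ in range(20):
        T *= 10.0
        v = steady_state_velocity(scheme, rates, force, T, geometry)
        if v > 0 and abs(v - v_prev) <= sat_rtol * v:
            break
        v_prev = v
    else:
        raise ArithmeticError("v_max limit did not converge within 20 decades")
    v_max = v

    def half(t):
        return steady_state_velocity(scheme, rates, force, t, geometry) - 0.5 * v_max

    lo, hi = 1e-15, T
    km = brentq(half, lo, hi, rtol=km_rtol)
    return MMParams(v_max=v_max, K_M=float(km), force=float(force))


@dataclass(frozen=True)
class LogisticParams:
    """Logistic force-velocity law v(F) = v0 / (1 + exp[(F - F_half)/F0])."""

    v0: float  # bp/s
    F_half: float  # pN
    F0: float  # pN (thermal force scale kBT / delta)
    v0_err: float | None = None
    F_half_err: float | None = None
    F0_err: float | None = None


def logistic_velocity(force, params: LogisticParams):
    """Evaluate the logistic force-velocity law; exactly v0/2 at F = F_half."""
    F = np.asarray(force, dtype=float)
    return params.v0 / (1.0 + np.exp((F - params.F_half) / params.F0))


def fit_logistic(force: Sequence[float], velocity: Sequence[float],
                 sem: Sequence[float] | None = None,
                 p0: tuple[float, float, float] | None = None) -> LogisticParams:
    """Weighted least-squares fit of the logistic law to a force-velocity curve.

    Weights are 1/sem^2 when ``sem`` is given. Raises on degenerate
    (constant-velocity) curves rather than returning silently absurd scales.
    """
    F = np.asarray(force, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if F.size < 4:
        raise ValueError("need at least 4 force bins to fit the logistic law")
    if np.ptp(v) <= 1e-12 * max(1.0, np.abs(v).max()):
        raise ValueError("degenerate force-velocity curve: velocity is constant")
    if p0 is None:
        v0 = float(v.max())
        below = F[v < 0.5 * v0]
        fh = float(below.min()) if below.size else float(F.max())
        p0 = (v0, fh, 4.0)
    sigma = np.asarray(sem, dtype=float) if sem is not None else None

    def model(f, v0, fh, f0):
        return v0 / (1.0 + np.exp((f - fh) / f0))

    popt, pcov = curve_fit(model, F, v, p0=p0, sigma=sigma,
                           absolute_sigma=sigma is not None, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    return LogisticParams(v0=popt[0], F_half=popt[1], F0=popt[2],
                          v0_err=perr[0], F_half_err=perr[1], F0_err=perr[2])


def thermal_force_scale(delta_bp: float, kbt: float = KBT_PN_NM,
                        nm_per_bp: float = NM_PER_BP) -> float:
    """F0 = kBT / (delta * nm_per_bp), the force scale of the logistic law (pN)."""
    return kbt / (delta_bp * nm_per_bp)


def fit_mm_curve(atp: Sequence[float], velocity: Sequence[float],
                 sem: Sequence[float] | None = None,
                 force: float = math.nan) -> MMParams:
    """Weighted Michaelis-Menten fit v = v_max T / (K_M + T) across [ATP].

    Used both on analytic v([ATP]) curves (MM-form property checks) and on
    binned experimental data at one force. Flags non-identifiable designs
    through large reported standard errors rather than failing silently.
    """
    T = np.asarray(atp, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if T.size < 3:
        raise ValueError("need >= 3 [ATP] values for a Michaelis-Menten fit")
    sigma = np.asarray(sem, dtype=float) if sem is not None else None
    vmax0 = float(v.max()) if v.max() > 0 else 1.0
    km0 = float(np.median(T))

    def model(t, vmax, km):
        return vmax * t / (km + t)

    popt, pcov = curve_fit(model, T, v, p0=(vmax0, km0), sigma=sigma,
                           absolute_sigma=sigma is not None, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    return MMParams(v_max=float(popt[0]), K_M=float(popt[1]), force=force,
                    v_max_err=float(perr[0]), K_M_err=float(perr[1]))
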