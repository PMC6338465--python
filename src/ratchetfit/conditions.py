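"""Reference enzyme contexts and experimental designs.

Raw single-molecule traces for RecD are not publicly available, so the
package carries a pair of synthetic ground-truth contexts whose *derived*
behavior matches the literature scales: a fast, force-insensitive-then-
falling unwinder when the helicase subunit operates inside the full
complex, and a weak, fork-limited unwinder when isolated. Both share the
same chemistry and differ only in the translocation equilibrium constant
(200-fold, post-translocation favored in complex) and in the geometry they
are probed in, mirroring the two assays:

* in-complex: opposing-force layout, zero-force velocity ~410 bp/s at
  2 mM ATP, K_M ~ 65 uM, half-velocity force ~21 pN;
* isolated: hairpin-under-tension layout with a fork destabilization
  energy of 0.6 kBT, near-zero velocity at low force rising to a plateau.

Step size is 3.3 bp with x_dagger = delta (forward-loaded barrier).
"""

from __future__ import annotations

import numpy as np

from .kinetics import GeometryContext, RateSet
from .polymer import ForkParams, PolymerParams
from .simulate import Dissociation, TrapModel, generate_dataset

__all__ = [
    "KEQ_SHIFT",
    "make_study_traces",
    "dissociation_isolated",
    "ATP_GRID_M",
    "rates_in_complex",
    "rates_isolated",
    "geometry_in_complex",
    "geometry_isolated",
    "trap_in_complex",
    "trap_isolated",
    "default_plan",
]

#: fold-change of the translocation equilibrium constant between contexts
KEQ_SHIFT = 200.0

#: the experimental [ATP] design, 20 uM - 2 mM
ATP_GRID_M = (20e-6, 100e-6, 350e-6, 1000e-6, 2000e-6)


def rates_in_complex() -> RateSet:
    """Ground-truth rates for the subunit operating inside the full complex."""
    return RateSet(
        k_plus_b=5e6,  # M^-1 s^-1
        k_minus_b=300.0,
        k_h=200.0,
        k_r=370.0,  # k_c_eff ~ 130 s^-1 -> v_max ~ 430 bp/s
        k_plus_tr=1e5,
        k_minus_tr=1e4,  # K_eq = 0.1, post-translocation favored
        delta=3.3,
        x_dagger=3.3,
        dG_dest=0.0,
    )


def rates_isolated() -> RateSet:
    """Ground-truth rates for the isolated subunit: same chemistry, shifted ratchet."""
    base = rates_in_complex()
    return base.with_(
        k_minus_tr=base.k_minus_tr * KEQ_SHIFT,  # K_eq = 20
        dG_dest=0.6,  # weak intrinsic fork destabilization (kBT)
    )


def fork_params() -> ForkParams:
    return ForkParams(dg_bp=2.3, dG_dest=0.0, n_step=3, m_window=20)


def geometry_in_complex() -> GeometryContext:
    return GeometryContext(mode="opposing_force")


def geometry_isolated(polymer: PolymerParams | None = None) -> GeometryContext:
    return GeometryContext(mode="hairpin_assisting", fork=fork_params(),
                           polymer=polymer or PolymerParams())


def trap_in_complex() -> TrapModel:
    # stem + tracks engaged as dsDNA contour; trace climbs from 5 pN to the
    # 50 pN cap as the tether is reeled in
    return TrapModel(k_eff=0.4, handles_bp=1450.0, f_start=5.0, f_stop=50.0)


def trap_isolated() -> TrapModel:
    # long handles soften the tether so unwinding sweeps the force range
    # slowly downward; each burst engages the fork at a different tension
    return TrapModel(k_eff=0.4, handles_bp=3400.0, hairpin_bp=500.0,
                     f_start=15.0, f_start_range=(6.0, 15.0), f_stop=1e9)


def dissociation_isolated() -> Dissociation:
    """Force-independent off-rate giving ~1 s activity bursts.

    The isolated subunit is poorly processive: its hairpin activity appears
    as short unwinding events terminated by dissociation, not as long
    continuous runs. Burst-like traces are the realistic study condition.
    """
    return Dissociation(k0=0.8, f_scale=1e9)


def default_plan(n_traces: int = 10, atp_grid=ATP_GRID_M,
                 contexts: str = "both") -> list[tuple]:
    """The reference force x [ATP] experimental design as a generate_dataset plan."""
    plan = []
    if contexts in ("both", "in_complex"):
        g, t, r = geometry_in_complex(), trap_in_complex(), rates_in_complex()
        plan += [(g, t, r, atp, n_traces) for atp in atp_grid]
    if contexts in ("both", "isolated"):
        g, t, r = geometry_isolated(), trap_isolated(), rates_isolated()
        plan += [(g, t, r, atp, n_traces) for atp in atp_grid]
    return plan


def make_study_traces(seed: int, n_traces: int = 10, atp_grid=ATP_GRID_M,
                      contexts: str = "both", scheme=None,
                      sigma_nm: float = 2.0,
                      duration_opposing: float = 3.0,
                      duration_hairpin: float = 3.0) -> list:
    """Generate the full synthetic study: both assays at the [ATP] design.

    Opposing-force traces run until the force cap or ``duration_opposing``;
    hairpin traces are dissociation-terminated bursts (capped at
    ``duration_hairpin``) starting at per-trace forces drawn from the trap's
    ``f_start_range``.
    """
    from .schemes import get_scheme

    scheme = scheme or get_scheme("br-binding")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)]
    traces = []
    if contexts in ("both", "in_complex"):
        traces += generate_dataset(
            default_plan(n_traces, atp_grid, "in_complex"), scheme,
            seed=seeds[0], duration=duration_opposing, sigma_nm=sigma_nm)
    if contexts in ("both", "isolated"):
        traces += generate_dataset(
            default_plan(n_traces, atp_grid, "isolated"), scheme,
            seed=seeds[1], duration=duration_hairpin, sigma_nm=sigma_nm,
            dissociation=dissociation_isolated())
    return traces
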