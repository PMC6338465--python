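"""Candidate mechano-chemical cycles for a translocating helicase.

A processive helicase couples a minimal three-step ATPase cycle,

    R + T  <=>  R.T  -->  R.D.Pi  -->  R + D + Pi
         (k+b, k-b)   (kh)        (kr)

to a physical translocation of ``delta`` base pairs per turnover. Two
questions define a mechano-chemical scheme: the *mechanism* of the
translocation step (power stroke vs Brownian ratchet) and its *placement*
within the chemical cycle (with/before ATP binding, hydrolysis, or product
release). A power-stroke (PS) scheme marks one chemical transition as
directly carrying the motion; a Brownian-ratchet (BR) scheme inserts a
rapid, reversible pre <=> post translocation transition immediately before
the rectifying chemical step. Crossing the two mechanisms with the three
placements yields exactly six candidate schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Transition",
    "SchemeSpec",
    "enumerate_schemes",
    "get_scheme",
    "MECHANISMS",
    "COUPLING_STEPS",
]

MECHANISMS = ("brownian_ratchet", "power_stroke")
COUPLING_STEPS = ("binding", "hydrolysis", "release")

#: rate-role labels understood by the kinetics/simulation layers
RATE_ROLES = ("bind", "unbind", "hydrolysis", "release", "tr_fwd", "tr_bwd")


@dataclass(frozen=True)
class Transition:
    """One directed transition of a cycle.

    Parameters
    ----------
    frm, to:
        State labels.
    role:
        Which microscopic rate constant drives the transition (one of
        :data:`RATE_ROLES`). ``bind`` is the only ATP-dependent role; its
        propensity is ``k_plus_b * [ATP]``.
    move:
        Signed translocation carried by the transition, in units of the
        step size ``delta`` (+1 forward, -1 backward, 0 purely chemical).
    reversible:
        Whether a partner transition runs in the opposite direction.
    """

    frm: str
    to: str
    role: str
    move: int = 0
    reversible: bool = False


@dataclass(frozen=True)
class SchemeSpec:
    """A labeled state graph for one mechano-chemical cycle."""

    mechanism: str
    coupling_step: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.coupling_step not in COUPLING_STEPS:
            raise ValueError(f"unknown coupling step {self.coupling_step!r}")
        atp_dep = [t for t in self.transitions if t.role == "bind"]
        if len(atp_dep) != 1:
            raise ValueError("exactly one transition must consume ATP")
        for t in self.transitions:
            if t.role in ("hydrolysis", "release") and t.reversible:
                raise ValueError(f"{t.role} must be irreversible")
            if t.frm not in self.states or t.to not in self.states:
                raise ValueError(f"transition {t} references unknown state")

    @property
    def scheme_id(self) -> str:
        tag = "br" if self.mechanism == "brownian_ratchet" else "ps"
        return f"{tag}-{self.coupling_step}"

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def uses_translocation_rates(self) -> bool:
        """True for BR schemes, which carry explicit k+tr / k-tr rates."""
        return self.mechanism == "brownian_ratchet"

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "coupling_step": self.coupling_step,
            "states": list(self.states),
            "transitions": [
                {
                    "from": t.frm,
                    "to": t.to,
                    "role": t.role,
                    "move": t.move,
                    "reversible": t.reversible,
                }
                for t in self.transitions
            ],
        }


def _power_stroke(coupling: str) -> SchemeSpec:
    states = ("apo", "atp", "adp_pi")
    mv = {"binding": 0, "hydrolysis": 0, "release": 0}
    mv[coupling] = 1
    transitions = (
        Transition("apo", "atp", "bind", mv["binding"], reversible=True),
        Transition("atp", "apo", "unbind", -mv["binding"], reversible=True),
        Transition("atp", "adp_pi", "hydrolysis", mv["hydrolysis"]),
        Transition("adp_pi", "apo", "release", mv["release"]),
    )
    return SchemeSpec("power_stroke", coupling, states, transitions)


def _brownian_ratchet(coupling: str) -> SchemeSpec:
    # The pre <=> post fluctuation sits immediately before the rectifying
    # chemical step; the chemical steps themselves carry no motion.
    if coupling == "binding":
        states = ("apo_pre", "apo_post", "atp", "adp_pi")
        transitions = (
            Transition("apo_pre", "apo_post", "tr_fwd", 1, reversible=True),
            Transition("apo_post", "apo_pre", "tr_bwd", -1, reversible=True),
            Transition("apo_post", "atp", "bind", reversible=True),
            Transition("atp", "apo_post", "unbind", reversible=True),
            Transition("atp", "adp_pi", "hydrolysis"),
            Transition("adp_pi", "apo_pre", "release"),
        )
    elif coupling == "hydrolysis":
        states = ("apo", "atp_pre", "atp_post", "adp_pi")
        transitions = (
            Transition("apo", "atp_pre", "bind", reversible=True),
            Transition("atp_pre", "apo", "unbind", reversible=True),
            Transition("atp_pre", "atp_post", "tr_fwd", 1, reversible=True),
            Transition("atp_post", "atp_pre", "tr_bwd", -1, reversible=True),
            Transition("atp_post", "adp_pi", "hydrolysis"),
            Transition("adp_pi", "apo", "release"),
        )
    else:  # release
        states = ("apo", "atp", "adp_pi_pre", "adp_pi_post")
        transitions = (
            Transition("apo", "atp", "bind", reversible=True),
            Transition("atp", "apo", "unbind", reversible=True),
            Transition("atp", "adp_pi_pre", "hydrolysis"),
            Transition("adp_pi_pre", "adp_pi_post", "tr_fwd", 1, reversible=True),
            Transition("adp_pi_post", "adp_pi_pre", "tr_bwd", -1, reversible=True),
            Transition("adp_pi_post", "apo", "release"),
        )
    return SchemeSpec("brownian_ratchet", coupling, states, transitions)


def enumerate_schemes(
    mechanism: str | None = None, coupling_step: str | None = None
) -> list[SchemeSpec]:
    """Return the candidate cycles, in a stable (mechanism, placement) order.

    With no filter this is the full set of six (2 mechanisms x 3 placements).
    """
    schemes: list[SchemeSpec] = []
    for mech in MECHANISMS:
        if mechanism is not None and mech != mechanism:
            continue
        builder = _brownian_ratchet if mech == "brownian_ratchet" else _power_stroke
        for step in COUPLING_STEPS:
            if coupling_step is not None and step != coupling_step:
                continue
            schemes.append(builder(step))
    return schemes


def get_scheme(scheme_id: str) -> SchemeSpec:
    """Look a scheme up by its short id, e.g. ``"br-binding"``."""
    for s in enumerate_schemes():
        if s.scheme_id == scheme_id:
            return s
    raise KeyError(f"unknown scheme id {scheme_id!r}")


def scheme_ids(schemes: Iterable[SchemeSpec] | None = None) -> list[str]:
    return [s.scheme_id for s in (schemes or enumerate_schemes())]
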