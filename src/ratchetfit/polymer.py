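"""Tether elasticity and fork-opening thermodynamics.

dsDNA segments are described by the extensible worm-like chain (eWLC) in
its high-force interpolation,

    x(F) = L * [1 - (1/2) * sqrt(kBT / (F * Lp)) + F / S],

with persistence length ``Lp`` and stretching modulus ``S``; ssDNA by a
freely-jointed chain (FJC) with Kuhn length ``b`` and contour ``l_c`` per
nucleotide. The fork-opening probability ``p_open`` — the probability that
at least ``n_step`` base pairs ahead of the helicase are transiently
unpaired — couples the applied force to unwinding in the hairpin-under-
tension assay: force stored in the released ssDNA lowers the per-bp opening
free energy, and the helicase may contribute a destabilization energy
``dG_dest`` of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KBT_PN_NM",
    "NM_PER_BP",
    "PolymerParams",
    "ForkParams",
    "ewlc_extension",
    "ewlc_inverse",
    "fjc_extension_per_nt",
    "ss_release_energy",
    "p_open",
]

#: thermal energy at 25 C, pN nm
KBT_PN_NM = 4.11
#: contour rise of B-form dsDNA, nm per bp
NM_PER_BP = 0.34


@dataclass(frozen=True)
class PolymerParams:
    """Elastic parameters of the tether polymers.

    dsDNA: persistence length ``lp_ds`` (nm), stretching modulus ``s_ds``
    (pN), contour ``nm_per_bp``. ssDNA: Kuhn length ``kuhn_ss`` (nm) and
    contour ``nm_per_nt`` per nucleotide. ``kbt`` is the thermal energy in
    pN nm.
    """

    lp_ds: float = 40.0
    s_ds: float = 1000.0
    nm_per_bp: float = NM_PER_BP
    kuhn_ss: float = 1.5
    nm_per_nt: float = 0.59
    kbt: float = KBT_PN_NM

    def __post_init__(self) -> None:
        for name in ("lp_ds", "s_ds", "nm_per_bp", "kuhn_ss", "nm_per_nt", "kbt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "PolymerParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ForkParams:
    """Thermodynamics of the unwinding fork.

    ``dg_bp``: sequence-averaged base-pairing free energy per bp (kBT,
    positive = duplex favored). ``dG_dest``: helicase destabilization energy
    per open bp (kBT, >= 0). ``n_step``: helicase step size in bp — the fork
    must present at least this many open bp for a forward step.
    ``m_window``: maximum number of transiently open bp retained in the
    zipper partition function.
    """

    dg_bp: float = 2.3
    dG_dest: float = 0.0
    n_step: int = 3
    m_window: int = 20

    def __post_init__(self) -> None:
        if self.dg_bp <= 0:
            raise ValueError("dg_bp must be positive")
        if self.dG_dest < 0:
            raise ValueError("dG_dest must be >= 0")
        if not (1 <= self.n_step <= self.m_window):
            raise ValueError("need 1 <= n_step <= m_window")

    def with_(self, **kw) -> "ForkParams":
        return replace(self, **kw)


def ewlc_extension(force, params: PolymerParams | None = None, contour_nm: float = 1.0):
    """Extension (nm) of a dsDNA segment of contour ``contour_nm`` at ``force`` (pN).

    High-force extensible Marko-Siggia interpolation; valid above ~0.5 pN.
    Raises on non-positive forces, whose samples must be filtered upstream.
    """
    params = params or PolymerParams()
    F = np.asarray(force, dtype=float)
    if np.any(F <= 0):
        raise ValueError("ewlc_extension requires force > 0")
    if contour_nm <= 0:
        raise ValueError("contour must be positive")
    rel = 1.0 - 0.5 * np.sqrt(params.kbt / (F * params.lp_ds)) + F / params.s_ds
    return contour_nm * rel


def ewlc_inverse(extension_nm, force, params: PolymerParams | None = None):
    """Contour length (nm) of dsDNA with ``extension_nm`` measured at ``force`` (pN).

    Exact algebraic inverse of :func:`ewlc_extension` at known force.
    """
    params = params or PolymerParams()
    F = np.asarray(force, dtype=float)
    if np.any(F <= 0):
        raise ValueError("ewlc_inverse requires force > 0")
    rel = 1.0 - 0.5 * np.sqrt(params.kbt / (F * params.lp_ds)) + F / params.s_ds
    return np.asarray(extension_nm, dtype=float) / rel


def fjc_extension_per_nt(force, params: PolymerParams | None = None):
    """FJC extension per ssDNA nucleotide (nm) at ``force`` (pN); 0 at F=0."""
    params = params or PolymerParams()
    F = np.asarray(force, dtype=float)
    u = params.kuhn_ss * F / params.kbt
    with np.errstate(divide="ignore", invalid="ignore"):
        lang = 1.0 / np.tanh(u) - 1.0 / u
    # Langevin function ~ u/3 - u^3/45 for small u
    small = np.abs(u) < 1e-4
    lang = np.where(small, u / 3.0 - u**3 / 45.0, lang)
    return params.nm_per_nt * lang


def ss_release_energy(force, params: PolymerParams | None = None, nt: float = 1.0):
    """Stretching free energy (kBT) gained by releasing ``nt`` nucleotides at ``force``.

    The work integral ``nt * int_0^F x_nt(F') dF' / kBT`` of the FJC has the
    closed form ``(l_c / b) * ln(sinh(u) / u)`` per nucleotide, with
    ``u = b F / kBT``. Monotone non-decreasing in F, zero at F = 0.
    """
    params = params or PolymerParams()
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    u = params.kuhn_ss * F / params.kbt
    # ln(sinh u / u), numerically safe at both ends:
    #   small u: u^2/6 - u^4/180;  large u: u - ln(2u)
    out = np.empty_like(u)
    small = u < 1e-4
    big = u > 30.0
    mid = ~(small | big)
    out[small] = u[small] ** 2 / 6.0 - u[small] ** 4 / 180.0
    out[big] = u[big] - np.log(2.0 * u[big])
    um = u[mid]
    out[mid] = np.log(np.sinh(um) / um)
    res = nt * (params.nm_per_nt / params.kuhn_ss) * out
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(res)
    return res


def p_open(force, fork: ForkParams | None = None, polymer: PolymerParams | None = None):
    """Probability that >= ``n_step`` bp ahead of the fork are transiently open.

    Single-exponential zipper: opening ``j`` bp costs ``j * dg(F)`` with the
    per-bp free energy ``dg(F) = dg_bp - dG_dest - 2 * w_ss(F)`` (two
    nucleotides of ssDNA are released per opened bp, each gaining the FJC
    stretching energy ``w_ss``). Then

        p_open = sum_{j=n}^{m} e^{-j dg} / sum_{j=0}^{m} e^{-j dg}.

    Bounded in [0, 1]; non-decreasing in force and ``dG_dest``,
    non-increasing in ``n_step`` and ``dg_bp``.
    """
    fork = fork or ForkParams()
    polymer = polymer or PolymerParams()
    F = np.atleast_1d(np.asarray(force, dtype=float))
    dg = fork.dg_bp - fork.dG_dest - 2.0 * np.asarray(
        ss_release_energy(F, polymer, nt=1.0)
    )
    j = np.arange(fork.m_window + 1)[:, None]
    # log-sum-exp over the open-bp count for stability at large |dg|
    loga = -j * dg[None, :]
    ref = loga.max(axis=0, keepdims=True)
    denom = np.exp(loga - ref).sum(axis=0)
    numer = np.exp(loga[fork.n_step :] - ref).sum(axis=0)
    res = numer / denom
    if np.isscalar(force) or np.ndim(force) == 0:
        return float(res[0])
    return res
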