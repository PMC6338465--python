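"""Global fitting of the candidate cycles and model selection.

Each scheme's steady-state velocity surface v(F, [ATP]) is fitted to one or
both binned force-velocity datasets by minimizing the (unweighted) sum of
squared errors with a multi-start trust-region least-squares optimizer
over log-transformed rates. When both assay geometries are fitted, the
``separate`` mode duplicates the microscopic rates per geometry (sharing
the step size and, in the hairpin geometry, the destabilization energy) —
the strategy that succeeds when the second context alters rates rather
than the reaction pathway. Schemes are ranked by total minimized SSE;
goodness of fit is reported as R^2 = 1 - SSE/SST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetics import GeometryContext, RateSet, velocity_grid
from .pipeline import ForceVelocityDataset
from .schemes import SchemeSpec, enumerate_schemes

__all__ = ["FitBounds", "FitResult", "sse", "r_squared", "global_fit",
           "select_model"]

_RATE_NAMES = ("k_plus_b", "k_minus_b", "k_h", "k_r")
_TR_NAMES = ("k_plus_tr", "k_minus_tr")


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the fit parameters (rates are searched in log10)."""

    rate: tuple[float, float] = (1e-2, 1e8)
    k_plus_b: tuple[float, float] = (1e3, 1e9)  # second order, M^-1 s^-1
    delta: tuple[float, float] = (0.5, 10.0)
    dG_dest: tuple[float, float] = (0.0, 5.0)


@dataclass
class FitResult:
    """Outcome of fitting one scheme to one or two datasets."""

    scheme_id: str
    mode: str  # "joint" or "separate"
    rates: dict[str, RateSet]  # per geometry
    sse: float  # unweighted sum of squared velocity errors
    objective: float  # minimized objective (equals sse for unweighted fits)
    r2: float
    n_points: int
    n_parameters: int
    success: bool
    n_starts: int
    start_sses: list[float] = field(default_factory=list)
    uncertainties: dict[str, dict[str, float]] | None = None
    aic: float | None = None
    bic: float | None = None

    @property
    def k_eq(self) -> dict[str, float]:
        out = {}
        for g, r in self.rates.items():
            if r.k_plus_tr is not None and r.k_minus_tr is not None:
                out[g] = r.k_eq
        return out

    def to_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "mode": self.mode,
            "rates": {g: r.to_dict() for g, r in self.rates.items()},
            "sse": self.sse,
            "objective": self.objective,
            "r2": self.r2,
            "n_points": self.n_points,
            "n_parameters": self.n_parameters,
            "success": self.success,
            "n_starts": self.n_starts,
            "aic": self.aic,
            "bic": self.bic,
            "uncertainties": self.uncertainties,
        }


def _dataset_arrays(dataset: ForceVelocityDataset, geometry: GeometryContext,
                    force_column: str, weights: str = "none"):
    t = dataset.subset(geometry=geometry.mode)
    if t.empty:
        raise ValueError(f"dataset has no rows for geometry {geometry.mode}")
    F = t[force_column if force_column in ("f_mean", "f_bin") else "f_mean"]
    if weights == "sem":
        sem = t["v_sem"].to_numpy().copy()
        good = np.isfinite(sem) & (sem > 0)
        sem[~good] = np.nanmedian(sem[good]) if good.any() else 1.0
        w = 1.0 / sem
    else:
        w = np.ones(len(t))
    return F.to_numpy(), t["atp"].to_numpy(), t["v_mean"].to_numpy(), w


def _model_velocities(scheme: SchemeSpec, rates: RateSet, F, atp,
                      geometry: GeometryContext) -> np.ndarray:
    try:
        v = velocity_grid(scheme, rates, F, atp, geometry)
    except (ArithmeticError, np.linalg.LinAlgError):
        return np.full(np.broadcast(F, atp).shape, 1e6)
    v = np.asarray(v, dtype=float)
    v[~np.isfinite(v)] = 1e6
    return v


def sse(scheme: SchemeSpec, rates: RateSet, dataset: ForceVelocityDataset,
        geometry: GeometryContext, force_column: str = "f_mean") -> float:
    """Sum of squared velocity errors of one scheme over one dataset."""
    F, atp, v, _ = _dataset_arrays(dataset, geometry, force_column)
    vm = _model_velocities(scheme, rates, F, atp, geometry)
    return float(np.sum((v - vm) ** 2))


def r_squared(total_sse: float, datasets: list[ForceVelocityDataset],
              geometries: list[GeometryContext]) -> float:
    """R^2 = 1 - SSE/SST about the grand mean of all fitted velocities."""
    v = np.concatenate([
        d.subset(geometry=g.mode)["v_mean"].to_numpy()
        for d, g in zip(datasets, geometries)
    ])
    sst = float(np.sum((v - v.mean()) ** 2))
    if sst <= 0:
        raise ValueError("zero-variance dataset: R^2 undefined")
    return 1.0 - total_sse / sst


class _ParamPack:
    """Maps the optimizer vector onto per-geometry RateSets.

    Rates are log10-transformed; delta (and x_dagger, when fitted) and
    dG_dest are linear. Modes: ``joint`` shares every rate across
    geometries; ``separate`` duplicates all microscopic rates per geometry;
    ``shared_chemistry`` shares the chemical rates (binding, unbinding,
    hydrolysis, release) but gives each geometry its own translocation
    rates — the parameterization matched to the hypothesis that a second
    context shifts the ratchet equilibrium rather than the chemistry. The
    step size is always shared; dG_dest applies to hairpin geometries.
    """

    def __init__(self, scheme: SchemeSpec, geometries: list[GeometryContext],
                 mode: str, bounds: FitBounds, fit_x_dagger: bool = False):
        self.scheme = scheme
        self.geometries = geometries
        self.mode = mode
        self.fit_x_dagger = fit_x_dagger
        rate_names = list(_RATE_NAMES)
        if scheme.uses_translocation_rates:
            rate_names += list(_TR_NAMES)
        self.rate_names = rate_names
        self.any_hairpin = any(not g.is_opposing for g in geometries)
        n_geo = len(geometries)

        def n_ctx(rn: str) -> int:
            if mode == "joint":
                return 1
            if mode == "shared_chemistry":
                return n_geo if rn in _TR_NAMES else 1
            return n_geo  # separate

        names, lo, hi = [], [], []
        self._index: dict[tuple[int, str], int] = {}
        for rn in rate_names:
            b = bounds.k_plus_b if rn == "k_plus_b" else bounds.rate
            for c in range(n_ctx(rn)):
                tag = f"[{c}]" if n_ctx(rn) > 1 else ""
                for ci in range(n_geo):
                    if n_ctx(rn) == 1 or ci == c:
                        self._index[(ci, rn)] = len(names)
                names.append(rn + tag)
                lo.append(math.log10(b[0]))
                hi.append(math.log10(b[1]))
        self._i_delta = len(names)
        names.append("delta")
        lo.append(bounds.delta[0])
        hi.append(bounds.delta[1])
        self._i_xd = None
        if fit_x_dagger:
            self._i_xd = len(names)
            names.append("x_dagger_frac")  # fraction of delta in (0, 1]
            lo.append(0.05)
            hi.append(1.0)
        self._i_dg = None
        if self.any_hairpin:
            self._i_dg = len(names)
            names.append("dG_dest")
            lo.append(bounds.dG_dest[0])
            hi.append(bounds.dG_dest[1])
        self.names = names
        self.lo = np.array(lo)
        self.hi = np.array(hi)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def unpack(self, x: np.ndarray) -> dict[str, RateSet]:
        delta = float(np.clip(x[self._i_delta], self.lo[self._i_delta],
                              self.hi[self._i_delta]))
        if self._i_xd is not None:
            xd = delta * float(np.clip(x[self._i_xd], 0.05, 1.0))
        else:
            xd = delta
        dg = 0.0
        if self._i_dg is not None:
            dg = float(np.clip(x[self._i_dg], 0.0, None))
        out = {}
        for ci, g in enumerate(self.geometries):
            vals = {rn: 10.0 ** x[self._index[(ci, rn)]]
                    for rn in self.rate_names}
            out[g.mode] = RateSet(delta=delta, x_dagger=xd,
                                  dG_dest=dg if not g.is_opposing else 0.0,
                                  **vals)
        return out

    def pack_start(self, rng: np.random.Generator, n: int) -> np.ndarray:
        # scrambled Halton: for a fixed seed the first n points are a prefix
        # of the same stream, so the best-of-n SSE is monotone in n
        sampler = qmc.Halton(d=self.n_params, seed=rng)
        u = sampler.random(n)
        return self.lo + u * (self.hi - self.lo)


def _residuals(x, pack: _ParamPack, data):
    rates = pack.unpack(x)
    res = []
    for (F, atp, v, w), g in zip(data, pack.geometries):
        vm = _model_velocities(pack.scheme, rates[g.mode], F, atp, g)
        res.append(w * (vm - v))
    return np.concatenate(res)


def global_fit(scheme: SchemeSpec, datasets: list[ForceVelocityDataset],
               geometries: list[GeometryContext], mode: str = "separate",
               bounds: FitBounds | None = None, n_starts: int = 50,
               seed: int = 0, fit_x_dagger: bool = False,
               force_column: str = "f_mean", weights: str = "none",
               n_boot: int = 0) -> FitResult:
    """Multi-start least-squares fit of one scheme to one or two datasets.

    Deterministic for a fixed seed; the best of ``n_starts`` Latin-
    hypercube starts is returned. ``n_boot`` > 0 adds residual-bootstrap
    standard errors for every parameter (resampled residuals are added to
    the best-fit model and the fit re-run from the best parameters).
    """
    if mode not in ("joint", "separate", "shared_chemistry"):
        raise ValueError("mode must be joint, separate, or shared_chemistry")
    if len(datasets) != len(geometries) or not datasets:
        raise ValueError("need one dataset per geometry context")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bounds = bounds or FitBounds()
    if weights not in ("none", "sem"):
        raise ValueError("weights must be 'none' or 'sem'")
    pack = _ParamPack(scheme, geometries, mode, bounds, fit_x_dagger)
    data = [_dataset_arrays(d, g, force_column, weights)
            for d, g in zip(datasets, geometries)]
    rng = np.random.default_rng(seed)
    starts = pack.pack_start(rng, n_starts)

    best = None
    start_sses = []
    for x0 in starts:
        try:
            sol = least_squares(_residuals, x0, args=(pack, data),
                                bounds=(pack.lo, pack.hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                max_nfev=400 * pack.n_params)
        except Exception:
            start_sses.append(float("inf"))
            continue
        s_obj = float(np.sum(sol.fun**2))
        start_sses.append(s_obj)
        if best is None or s_obj < best[0]:
            best = (s_obj, sol)
    if best is None:
        raise RuntimeError(
            f"all {n_starts} starts failed for scheme {scheme.scheme_id}; "
            f"per-start log: {start_sses}"
        )
    _, sol = best
    rates = pack.unpack(sol.x)
    s_best = 0.0
    for (F, atp, v, _w), g in zip(data, pack.geometries):
        vm = _model_velocities(scheme, rates[g.mode], F, atp, g)
        s_best += float(np.sum((vm - v) ** 2))
    n_points = sum(len(d[2]) for d in data)
    r2 = r_squared(s_best, datasets, geometries)
    k = pack.n_params
    # Gaussian log-likelihood information criteria (informational only;
    # selection is strictly by SSE)
    aic = n_points * math.log(max(s_best, 1e-300) / n_points) + 2 * k
    bic = n_points * math.log(max(s_best, 1e-300) / n_points) + k * math.log(n_points)

    unc = None
    if n_boot > 0:
        unc = _bootstrap_errors(pack, data, sol.x, n_boot, rng)

    return FitResult(
        scheme_id=scheme.scheme_id, mode=mode, rates=rates, sse=s_best,
        objective=best[0], r2=r2, n_points=n_points, n_parameters=k,
        success=bool(sol.success or s_best < float("inf")),
        n_starts=n_starts, start_sses=start_sses, uncertainties=unc,
        aic=aic, bic=bic,
    )


def _bootstrap_errors(pack: _ParamPack, data, x_best, n_boot: int,
                      rng: np.random.Generator):
    """Residual-bootstrap standard errors, re-fitting from the optimum."""
    res0 = _residuals(x_best, pack, data)
    # model values per block (residuals are in weighted units; divide out)
    sizes = [len(d[2]) for d in data]
    model_v = []
    off = 0
    for (F, atp, v, w), n in zip(data, sizes):
        model_v.append(res0[off:off + n] / w + v)
        off += n
    raw_res = np.concatenate([res0[sum(sizes[:i]):sum(sizes[:i + 1])] / d[3]
                              for i, d in enumerate(data)])
    samples = []
    for _ in range(n_boot):
        data_b = []
        for (F, atp, v, w), mv in zip(data, model_v):
            resamp = rng.choice(raw_res, size=len(mv), replace=True)
            data_b.append((F, atp, mv + resamp, w))
        try:
            sol = least_squares(_residuals, x_best, args=(pack, data_b),
                                bounds=(pack.lo, pack.hi), method="trf",
                                xtol=1e-8, ftol=1e-8, max_nfev=100 * pack.n_params)
            samples.append(sol.x)
        except Exception:
            continue
    if len(samples) < max(10, n_boot // 4):
        return None
    arr = np.array(samples)
    out: dict[str, dict[str, float]] = {}
    for i, name in enumerate(pack.names):
        vals = arr[:, i]
        if name.startswith("k_"):  # log10-space parameter
            out[name] = {"estimate": float(10.0 ** x_best[i]),
                         "se_log10": float(vals.std(ddof=1))}
        else:
            out[name] = {"estimate": float(x_best[i]),
                         "se": float(vals.std(ddof=1))}
    return out


def select_model(datasets: list[ForceVelocityDataset],
                 geometries: list[GeometryContext],
                 schemes: list[SchemeSpec] | None = None,
                 mode: str = "separate", n_starts: int = 12, seed: int = 0,
                 **kwargs) -> list[FitResult]:
    """Fit every candidate scheme and rank by total minimized SSE.

    Returns the full ranking (best first), never only the winner; schemes
    whose optimization fails outright are reported with infinite SSE.
    """
    schemes = schemes or enumerate_schemes()
    if len(schemes) < 2:
        raise ValueError("model selection needs at least two candidate schemes")
    results = []
    ss = np.random.SeedSequence(seed)
    for scheme, child in zip(schemes, ss.spawn(len(schemes))):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        try:
            fit = global_fit(scheme, datasets, geometries, mode=mode,
                             n_starts=n_starts, seed=sub_seed, **kwargs)
        except RuntimeError:
            fit = FitResult(scheme_id=scheme.scheme_id, mode=mode, rates={},
                            sse=float("inf"), objective=float("inf"),
                            r2=-float("inf"),
                            n_points=0, n_parameters=0, success=False,
                            n_starts=n_starts)
        results.append(fit)
    # rank by the minimized objective (identical to SSE for unweighted fits)
    results.sort(key=lambda f: f.objective)
    return results
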