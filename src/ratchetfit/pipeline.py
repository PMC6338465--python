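"""Trace processing: smoothing, contour conversion, force-velocity estimation.

The chain mirrors standard passive-mode tweezers practice: raw 2,500 Hz
channels are smoothed with a moving-average filter to 250 Hz, the extension
is converted to enzyme progress in bp, instantaneous velocities are taken
as ordinary-least-squares slopes in non-overlapping 100 ms windows (with a
median filter of one tenth of the per-trace point count), and the pooled
(force, velocity) points are quantized into 0-60 pN force bins (3 pN for
the opposing layout, 2 pN for the hairpin layout) as mean +- s.e.m. over
the ensemble of traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import MMParams, fit_mm_curve
from .polymer import PolymerParams, ewlc_inverse, ewlc_extension, fjc_extension_per_nt
from .simulate import Trace

__all__ = [
    "ForceVelocityDataset",
    "smooth_to_bandwidth",
    "to_contour",
    "instantaneous_fv",
    "trace_fv_points",
    "bin_fv",
    "process_traces",
    "fit_mm_per_force",
    "DEFAULT_BIN_WIDTH",
]

#: default force-bin widths (pN) per geometry
DEFAULT_BIN_WIDTH = {"opposing_force": 3.0, "hairpin_assisting": 2.0}
#: samples below this force (pN) are outside the eWLC conversion domain
LOW_FORCE_CUTOFF = 0.5


@dataclass
class ForceVelocityDataset:
    """Binned mean +- s.e.m. velocity over a force x [ATP] grid.

    ``table`` columns: geometry, atp (M), f_bin (bin center, pN), f_mean
    (mean in-bin force, pN), v_mean (bp/s), v_sem, n (point count).
    """

    table: pd.DataFrame
    bin_edges: np.ndarray
    min_count: int = 5
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"geometry", "atp", "f_bin", "f_mean", "v_mean", "v_sem", "n"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset table missing columns {sorted(missing)}")

    @property
    def geometries(self) -> list[str]:
        return sorted(self.table["geometry"].unique())

    @property
    def atp_values(self) -> np.ndarray:
        return np.sort(self.table["atp"].unique())

    def subset(self, geometry: str | None = None, atp: float | None = None,
               f_bin: float | None = None) -> pd.DataFrame:
        t = self.table
        if geometry is not None:
            t = t[t["geometry"] == geometry]
        if atp is not None:
            t = t[np.isclose(t["atp"], atp)]
        if f_bin is not None:
            t = t[np.isclose(t["f_bin"], f_bin)]
        return t

    def force_column(self, use: str = "f_mean") -> np.ndarray:
        if use not in ("f_mean", "f_bin"):
            raise ValueError("use must be 'f_mean' or 'f_bin'")
        return self.table[use].to_numpy()


def smooth_to_bandwidth(trace: Trace, f_c: float = 250.0) -> Trace:
    """Moving-average filter to bandwidth ``f_c`` (window round(fs/f_c) samples).

    Length preserving; the window shrinks symmetrically at the edges.
    """
    if f_c >= trace.fs / 2:
        raise ValueError(f"f_c={f_c} must be below the Nyquist rate {trace.fs / 2}")
    w = int(round(trace.fs / f_c))
    if w <= 1:
        return trace

    def _smooth(y: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(y)))
        half = w // 2
        n = y.size
        i = np.arange(n)
        lo = np.maximum(i - half, 0)
        hi = np.minimum(i + (w - half), n)
        return (c[hi] - c[lo]) / (hi - lo)

    return Trace(
        time=trace.time,
        extension_nm=_smooth(trace.extension_nm),
        force_pN=_smooth(trace.force_pN),
        geometry=trace.geometry,
        atp=trace.atp,
        fs=trace.fs,
        meta={**trace.meta, "f_c": f_c},
        annotations=trace.annotations,
    )


def to_contour(trace: Trace, polymer: PolymerParams | None = None,
               low_force_cutoff: float = LOW_FORCE_CUTOFF) -> np.ndarray:
    """Per-sample enzyme progress (bp), masked (NaN) below the force cutoff.

    Opposing layout: the extension is inverted through the eWLC to dsDNA
    contour; progress is the contour *consumed*, ``(L(0) - L(t)) / 0.34``,
    so unwinding always reads as positive velocity. Hairpin layout: the
    tether is the fixed dsDNA handles plus two released ssDNA nucleotides
    per unwound bp, so progress is
    ``(x - x_handles(F)) / (2 x_nt(F))`` with FJC nucleotide extension.
    """
    polymer = polymer or PolymerParams()
    F = trace.force_pN
    x = trace.extension_nm
    valid = F > low_force_cutoff
    if not valid.any():
        raise ValueError(
            f"all samples below the {low_force_cutoff} pN conversion cutoff"
        )
    out = np.full(F.shape, np.nan)
    if trace.geometry == "opposing_force":
        L = ewlc_inverse(x[valid], F[valid], polymer)
        bp = L / polymer.nm_per_bp
        out[valid] = -(bp - bp[0])
    elif trace.geometry == "hairpin_assisting":
        handles_bp = trace.meta.get("handles_bp")
        if handles_bp is None:
            raise ValueError("hairpin trace lacks handles_bp metadata")
        xh = ewlc_extension(F[valid], polymer,
                            contour_nm=handles_bp * polymer.nm_per_bp)
        per_bp = 2.0 * fjc_extension_per_nt(F[valid], polymer)
        out[valid] = (x[valid] - xh) / per_bp
    else:
        raise ValueError(f"unknown geometry {trace.geometry!r}")
    return out


def _median_filter_edges_passthrough(v: np.ndarray, length: int) -> np.ndarray:
    """Running median applied only where the full window fits.

    Edge points are passed through unfiltered: a shrinking or reflected
    window systematically drags the ends of a trending sequence toward its
    interior, which biases the first and last windows of every trace (the
    velocity sequence of a passive-mode trace is monotone in time in both
    layouts).
    """
    if length <= 1:
        return v.copy()
    half = length // 2
    out = v.copy()
    n = v.size
    for i in range(half, n - half):
        out[i] = np.median(v[i - half:i + half + 1])
    return out


def instantaneous_fv(contour_bp: np.ndarray, force_pN: np.ndarray, fs: float,
                     window_s: float = 0.1,
                     median_fraction: float = 0.1
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(force, velocity, entry force) per non-overlapping ``window_s`` window.

    Velocity is the OLS slope of contour vs time inside the window, force
    the window mean; windows containing masked (NaN) samples are dropped.
    A running median filter of length ``median_fraction`` times the point
    count is applied to the velocity sequence. The entry force (first
    sample of the window) is reported alongside: downstream binning groups
    windows by entry force, which is set by the trace's past and therefore
    independent of the window's own velocity fluctuation — grouping by the
    window-mean force would over-represent slow excursions, because how
    long a self-driven sweep lingers near a force depends on its own
    stochastic velocity.
    """
    n_w = int(round(window_s * fs))
    if n_w < 2:
        raise ValueError("window too short for the sampling rate")
    n = (contour_bp.size // n_w) * n_w
    if n < 2 * n_w:
        raise ValueError("need at least two full windows")
    c = contour_bp[:n].reshape(-1, n_w)
    f = force_pN[:n].reshape(-1, n_w)
    good = ~np.isnan(c).any(axis=1)
    c, f = c[good], f[good]
    if c.shape[0] < 2:
        raise ValueError("fewer than two unmasked windows")
    # OLS slope against the in-window time axis
    tt = (np.arange(n_w) - (n_w - 1) / 2.0) / fs
    denom = np.sum(tt * tt)
    slope = (c - c.mean(axis=1, keepdims=True)) @ tt / denom
    f_mean = f.mean(axis=1)
    f_entry = f[:, 0]
    m = max(1, int(round(median_fraction * slope.size)))
    slope = _median_filter_edges_passthrough(slope, m)
    return f_mean, slope, f_entry


def trace_fv_points(trace: Trace, polymer: PolymerParams | None = None,
                    f_c: float = 250.0, window_s: float = 0.1,
                    median_fraction: float = 0.1
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full per-trace chain: smooth -> contour -> windowed (F, v, F_entry)."""
    sm = smooth_to_bandwidth(trace, f_c)
    contour = to_contour(sm, polymer)
    return instantaneous_fv(contour, sm.force_pN, sm.fs, window_s,
                            median_fraction)


def bin_fv(points: Sequence[tuple],
           bin_width: dict | float | None = None,
           f_range: tuple[float, float] = (0.0, 60.0),
           min_count: int = 5,
           average: str = "ensemble") -> ForceVelocityDataset:
    """Quantize (force, velocity) points into a binned dataset.

    ``points`` rows are ``(geometry, atp, forces, velocities)`` or
    ``(geometry, atp, forces, velocities, entry_forces)`` — one row per
    trace. When entry forces are present they define bin membership (see
    :func:`instantaneous_fv`); the reported per-bin force is always the
    mean window force.

    ``average="ensemble"`` (default) quantizes each trace's curve first and
    averages across traces, with the s.e.m. taken over the independent
    trace-level means; ``average="pooled"`` pools all windows of a
    condition with equal weight (the windows of one trace are serially
    correlated through the median filter, so the pooled s.e.m. understates
    the uncertainty). Bins with fewer than ``min_count`` points are
    dropped; ensemble bins seen by a single trace fall back to pooled
    statistics.
    """
    if average not in ("ensemble", "pooled"):
        raise ValueError("average must be 'ensemble' or 'pooled'")
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH
    rows = []
    provenance = []
    conditions: dict[tuple[str, float], list] = {}
    for i, row in enumerate(points):
        geom, atp, f, v = row[:4]
        f_entry = row[4] if len(row) > 4 else f
        conditions.setdefault((geom, float(atp)), []).append((i, f, v, f_entry))
    all_edges = {}
    for (geom, atp), entries in sorted(conditions.items()):
        bw = bin_width[geom] if isinstance(bin_width, dict) else float(bin_width)
        edges = np.arange(f_range[0], f_range[1] + bw / 2, bw)
        all_edges[geom] = edges
        provenance.extend(e[0] for e in entries)
        n_bins = edges.size - 1
        per_trace_mean = []  # list over traces of length-n_bins arrays
        f_sum = np.zeros(n_bins)
        v_sum = np.zeros(n_bins)
        v_sq = np.zeros(n_bins)
        count = np.zeros(n_bins, dtype=int)
        for (_, f, v, fe) in entries:
            which = np.digitize(fe, edges) - 1
            tmean = np.full(n_bins, np.nan)
            for b in np.unique(which):
                if not (0 <= b < n_bins):
                    continue
                sel = which == b
                tmean[b] = v[sel].mean()
                f_sum[b] += f[sel].sum()
                v_sum[b] += v[sel].sum()
                v_sq[b] += (v[sel] ** 2).sum()
                count[b] += int(sel.sum())
            per_trace_mean.append(tmean)
        tmat = np.array(per_trace_mean)  # (n_traces, n_bins)
        for b in range(n_bins):
            n = int(count[b])
            if n < min_count:
                continue
            tvals = tmat[:, b]
            tvals = tvals[~np.isnan(tvals)]
            pooled_mean = v_sum[b] / n
            pooled_var = (v_sq[b] - n * pooled_mean**2) / (n - 1) if n > 1 else np.nan
            pooled_sem = float(np.sqrt(max(pooled_var, 0.0) / n)) if n > 1 else np.nan
            if average == "ensemble" and tvals.size >= 2:
                vm = float(tvals.mean())
                sem = float(tvals.std(ddof=1) / np.sqrt(tvals.size))
                # with a handful of traces the between-trace s.e.m. can be
                # accidentally tiny; floor it with the pooled estimate
                if np.isfinite(pooled_sem):
                    sem = max(sem, pooled_sem)
            else:
                vm = float(pooled_mean)
                sem = pooled_sem
            rows.append({
                "geometry": geom, "atp": atp,
                "f_bin": float(0.5 * (edges[b] + edges[b + 1])),
                "f_mean": float(f_sum[b] / n),
                "v_mean": vm, "v_sem": sem, "n": n,
            })
    if not rows:
        raise ValueError("no force bin reached the minimum point count")
    edges = next(iter(all_edges.values()))
    return ForceVelocityDataset(table=pd.DataFrame(rows), bin_edges=edges,
                                min_count=min_count, provenance=provenance)


def process_traces(traces: Sequence[Trace], polymer: PolymerParams | None = None,
                   f_c: float = 250.0, window_s: float = 0.1,
                   median_fraction: float = 0.1,
                   bin_width: dict | float | None = None,
                   f_range: tuple[float, float] = (0.0, 60.0),
                   min_count: int = 5,
                   average: str = "ensemble") -> ForceVelocityDataset:
    """Traces -> binned force-velocity dataset with the standard defaults.

    Traces too short to yield two full analysis windows (e.g. bursts
    terminated early by dissociation) are skipped; processing fails only
    if no trace survives.
    """
    points = []
    for tr in traces:
        try:
            f, v, fe = trace_fv_points(tr, polymer, f_c, window_s,
                                       median_fraction)
        except ValueError:
            continue
        points.append((tr.geometry, tr.atp, f, v, fe))
    if not points:
        raise ValueError("no trace yielded at least two analysis windows")
    return bin_fv(points, bin_width, f_range, min_count, average)


def fit_mm_per_force(dataset: ForceVelocityDataset, geometry: str,
                     f_bin: float, force_column: str = "f_mean") -> MMParams:
    """Michaelis-Menten fit across [ATP] inside one force bin (weighted WLS)."""
    t = dataset.subset(geometry=geometry, f_bin=f_bin)
    if t["atp"].nunique() < 3:
        raise ValueError("need >= 3 distinct [ATP] values in the force bin")
    force = float(t[force_column].mean())
    return fit_mm_curve(t["atp"].to_numpy(), t["v_mean"].to_numpy(),
                        sem=t["v_sem"].to_numpy(), force=force)
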