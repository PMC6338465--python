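"""File formats: traces, binned force-velocity tables, fit reports, config.

Everything is plain text: tab-separated series with a JSON metadata
sidecar (traces) or an embedded ``#``-prefixed JSON header (binned
datasets), and JSON documents for configurations and fit results. Unknown
columns are preserved on round-trip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import ForceVelocityDataset
from .simulate import Trace

__all__ = [
    "write_trace", "read_trace", "write_fv", "read_fv",
    "write_json", "read_json", "config_hash",
]

_TRACE_COLUMNS = ("time_s", "extension_nm", "force_pN")


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a trace as TSV plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time,
        "extension_nm": trace.extension_nm,
        "force_pN": trace.force_pN,
    })
    for k, v in trace.meta.get("extra_columns", {}).items():
        df[k] = v
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    sidecar = {
        "geometry": trace.geometry,
        "atp": trace.atp,
        "fs": trace.fs,
        "meta": _jsonable(trace.meta),
        "annotations": {k: np.asarray(v).tolist()
                        for k, v in trace.annotations.items()},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`; schema-validated."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in _TRACE_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: malformed numeric cell in column {col!r}, "
                f"first bad row {bad.index[0] + 2}"
            )
    side = Path(str(path) + ".json")
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar {side} not found")
    meta = json.loads(side.read_text())
    extra = {c: df[c].to_numpy() for c in df.columns if c not in _TRACE_COLUMNS}
    m = dict(meta.get("meta", {}))
    if extra:
        m["extra_columns"] = extra
    return Trace(
        time=df["time_s"].to_numpy(),
        extension_nm=df["extension_nm"].to_numpy(),
        force_pN=df["force_pN"].to_numpy(),
        geometry=meta["geometry"],
        atp=float(meta["atp"]),
        fs=float(meta["fs"]),
        meta=m,
        annotations={k: np.asarray(v)
                     for k, v in meta.get("annotations", {}).items()},
    )


def write_fv(dataset: ForceVelocityDataset, path: str | Path) -> Path:
    """Binned dataset as TSV with a ``#``-prefixed JSON header line."""
    path = Path(path)
    header = {
        "bin_edges": np.asarray(dataset.bin_edges).tolist(),
        "min_count": dataset.min_count,
        "provenance": list(dataset.provenance),
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        dataset.table.to_csv(fh, sep="\t", index=False, float_format="%.9g")
    return path


def read_fv(path: str | Path) -> ForceVelocityDataset:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        table = pd.read_csv(fh, sep="\t")
    return ForceVelocityDataset(
        table=table,
        bin_edges=np.asarray(header["bin_edges"], dtype=float),
        min_count=int(header.get("min_count", 5)),
        provenance=header.get("provenance", []),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict, for artifact provenance."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
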