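"""Container readers/writers and report serialization.

Native containers are HDF5 with the layout::

    /fields/{ex,ey,ez}    complex [Nc, nx, ny, nz]
    /tissue/{sigma,rho,mask}
    /q10g/entries         complex [Nv, Nc, Nc]
    /q10g/voxel_index     int [Nv, 3]
    /vops/{entries,source_index,provenance,delta_term}

with attributes ``voxel_size`` (meters), ``units`` and ``averaged``.  A
MATLAB compatibility reader accepts Q/VOP sets stored as cell arrays or
3-D complex arrays (both ``(Nc, Nc, Nv)`` and ``(Nv, Nc, Nc)``
orientations), v5 via scipy and v7.3 via h5py.

Reports (worst-case and bounds comparisons) serialize to JSON or CSV with
a stamped schema version, floats at 12 significant digits, and a
provenance block (seed, config hash, versions) sufficient to reproduce
deterministic runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .bounds import BoundsReport
from .compress import VOPSet
from .qmodel import (
    ChannelFieldSet,
    DriveVector,
    QMatrixSet,
    TissueGrid,
    ValidationError,
)
from .trigmax import TrigMaxConfig, WorstCaseResult

SCHEMA_VERSION = "1.0"

#: minimal shipped schema for JSON reports (validated by validate_report_dict)
REPORT_SCHEMA: dict[str, Any] = {
    "required": ["schema_version", "kind", "provenance", "data"],
    "properties": {
        "schema_version": "str",
        "kind": "str",
        "provenance": "dict",
        "data": "dict",
    },
}


class ParseError(ValueError):
    """Raised when a container does not match its declared dialect."""


def _sig12(x: float) -> float:
    """Round to 12 significant digits for stable serialization."""
    return float(f"{float(x):.12g}")


def config_hash(obj: Any) -> str:
    """Stable short hash of a configuration object."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_block(seed: int | None = None, config: Any = None) -> dict[str, Any]:
    from . import __version__

    return {
        "package": "trigsar",
        "version": __version__,
        "numpy": np.__version__,
        "seed": seed,
        "config_hash": None if config is None else config_hash(config),
    }


# ---------------------------------------------------------------------------
# HDF5 containers


def write_fields(path: str | Path, fields: ChannelFieldSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("fields")
        g.create_dataset("ex", data=fields.ex)
        g.create_dataset("ey", data=fields.ey)
        g.create_dataset("ez", data=fields.ez)
        t = f.create_group("tissue")
        t.create_dataset("sigma", data=fields.grid.sigma)
        t.create_dataset("rho", data=fields.grid.rho)
        t.create_dataset("mask", data=fields.grid.body_mask)
        f.attrs["voxel_size"] = fields.grid.voxel_size
        f.attrs["units"] = "E: V/m per sqrt(W); sigma: S/m; rho: kg/m^3"


def read_fields(path: str | Path) -> ChannelFieldSet:
    with h5py.File(path, "r") as f:
        for name in ("fields/ex", "fields/ey", "fields/ez", "tissue/sigma"):
            if name not in f:
                raise ParseError(f"missing dataset '/{name}' in {path}")
        grid = _read_tissue(f)
        return ChannelFieldSet(
            grid=grid,
            ex=f["fields/ex"][()],
            ey=f["fields/ey"][()],
            ez=f["fields/ez"][()],
        )


def _read_tissue(f: h5py.File) -> TissueGrid:
    return TissueGrid(
        voxel_size=tuple(f.attrs["voxel_size"]),
        sigma=f["tissue/sigma"][()],
        rho=f["tissue/rho"][()],
        body_mask=f["tissue/mask"][()].astype(bool),
    )


def write_qset(
    path: str | Path, qset: QMatrixSet, grid: TissueGrid | None = None
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("q10g")
        g.create_dataset("entries", data=qset.entries)
        g.create_dataset("voxel_index", data=qset.voxel_index)
        if qset.cube_side is not None:
            g.create_dataset("cube_side", data=qset.cube_side)
        f.attrs["averaged"] = bool(qset.averaged)
        f.attrs["units"] = "Q: W/kg per W"
        if grid is not None:
            t = f.create_group("tissue")
            t.create_dataset("sigma", data=grid.sigma)
            t.create_dataset("rho", data=grid.rho)
            t.create_dataset("mask", data=grid.body_mask)
            f.attrs["voxel_size"] = grid.voxel_size


def read_tissue_grid(path: str | Path) -> TissueGrid:
    with h5py.File(path, "r") as f:
        if "tissue/sigma" not in f:
            raise ParseError(f"no tissue group in {path}")
        return _read_tissue(f)


def read_qset(
    path: str | Path, dialect: str = "native_h5", validate: bool = True
) -> QMatrixSet:
    """Load a Q-matrix set; Hermitian/PSD validation applied by default."""
    if dialect == "native_h5":
        qset = _read_qset_native(path)
    elif dialect == "matlab":
        qset = _read_qset_matlab(path)
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    if validate:
        qset.validate()
    return qset


def _read_qset_native(path: str | Path) -> QMatrixSet:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ParseError(f"cannot open {path} as HDF5: {exc}") from exc
    with f:
        if "q10g/entries" not in f:
            raise ParseError(f"missing dataset '/q10g/entries' in {path}")
        entries = f["q10g/entries"][()]
        vidx = f["q10g/voxel_index"][()] if "q10g/voxel_index" in f else None
        cube = f["q10g/cube_side"][()] if "q10g/cube_side" in f else None
        return QMatrixSet(
            entries=entries,
            voxel_index=vidx,
            averaged=bool(f.attrs.get("averaged", True)),
            cube_side=cube,
        )


def _matlab_to_entries(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == object:  # cell array of Nc x Nc matrices
        mats = [np.asarray(m, dtype=complex) for m in arr.ravel()]
        return np.stack(mats)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return arr[None].astype(complex)
    if arr.ndim != 3:
        raise ParseError("MATLAB Q container must be a cell or 3-D array")
    # accept (Nc, Nc, Nv) (typical MATLAB layout) or (Nv, Nc, Nc)
    if arr.shape[0] == arr.shape[1] and arr.shape[2] != arr.shape[1]:
        return np.transpose(arr, (2, 0, 1)).astype(complex)
    if arr.shape[1] == arr.shape[2]:
        return arr.astype(complex)
    if arr.shape[0] == arr.shape[1] == arr.shape[2]:
        return np.transpose(arr, (2, 0, 1)).astype(complex)
    raise ParseError(f"cannot identify matrix axes in shape {arr.shape}")


def _read_qset_matlab(path: str | Path) -> QMatrixSet:
    import scipy.io

    try:
        mat = scipy.io.loadmat(path)
    except NotImplementedError:
        return _read_qset_matlab_v73(path)
    except Exception as exc:
        raise ParseError(f"cannot read {path} as a MATLAB container: {exc}") from exc
    for key, val in mat.items():
        if key.startswith("__"):
            continue
        if isinstance(val, np.ndarray) and (val.dtype == object or val.ndim >= 2):
            return QMatrixSet(entries=_matlab_to_entries(val), averaged=True)
    raise ParseError(f"no Q-matrix variable found in {path}")


def _read_qset_matlab_v73(path: str | Path) -> QMatrixSet:
    with h5py.File(path, "r") as f:
        for key in f:
            ds = f[key]
            if isinstance(ds, h5py.Dataset) and ds.ndim == 3:
                arr = ds[()]
                if arr.dtype.names and set(arr.dtype.names) >= {"real", "imag"}:
                    arr = arr["real"] + 1j * arr["imag"]
                return QMatrixSet(entries=_matlab_to_entries(arr), averaged=True)
    raise ParseError(f"no 3-D Q dataset found in {path}")


def write_vopset(path: str | Path, vops: VOPSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("vops")
        g.create_dataset("entries", data=vops.vops)
        g.create_dataset("source_index", data=vops.source_index)
        g.create_dataset("provenance", data=vops.provenance)
        g.create_dataset("delta_term", data=vops.delta_term)
        f.attrs["delta"] = vops.delta
        f.attrs["lambda_bar"] = vops.lambda_bar
        f.attrs["units"] = "Q: W/kg per W"


def read_vopset(path: str | Path) -> VOPSet:
    with h5py.File(path, "r") as f:
        if "vops/entries" not in f:
            raise ParseError(f"missing dataset '/vops/entries' in {path}")
        return VOPSet(
            vops=f["vops/entries"][()],
            delta=float(f.attrs["delta"]),
            lambda_bar=float(f.attrs["lambda_bar"]),
            provenance=f["vops/provenance"][()],
            source_index=f["vops/source_index"][()],
        )


# ---------------------------------------------------------------------------
# drive CSV files


def write_drives_csv(path: str | Path, drives: list[DriveVector]) -> None:
    rows = []
    for i, d in enumerate(drives):
        for c in range(d.n_channels):
            row = {"drive": i, "channel": c, "amplitude": d.amplitudes[c]}
            if d.phases is not None:
                row["phase"] = d.phases[c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_drives_csv(path: str | Path) -> list[DriveVector]:
    """Read drives: one row per channel, columns ``amplitude`` (sqrt W) and
    optional ``phase`` (rad); a ``drive`` column groups multiple drives."""
    df = pd.read_csv(path)
    if "amplitude" not in df.columns:
        raise ParseError(f"{path} has no 'amplitude' column")
    groups = df.groupby("drive", sort=True) if "drive" in df.columns else [(0, df)]
    drives = []
    for _, g in groups:
        if "channel" in g.columns:
            g = g.sort_values("channel")
        amps = g["amplitude"].to_numpy(dtype=float)
        phases = g["phase"].to_numpy(dtype=float) if "phase" in g.columns else None
        drives.append(DriveVector(amplitudes=amps, phases=phases))
    return drives


def read_trajectory_csv(path: str | Path):
    """Trajectory CSV: columns ``step``, ``amplitude``, ``duration`` (s),
    one row per channel per time step; returns (amplitudes (T, Nc),
    durations (T,))."""
    df = pd.read_csv(path)
    for col in ("step", "amplitude", "duration"):
        if col not in df.columns:
            raise ParseError(f"{path} has no '{col}' column")
    amps, durs = [], []
    for _, g in df.groupby("step", sort=True):
        if "channel" in g.columns:
            g = g.sort_values("channel")
        amps.append(g["amplitude"].to_numpy(dtype=float))
        durs.append(float(g["duration"].iloc[0]))
    return np.array(amps), np.array(durs)


# ---------------------------------------------------------------------------
# report serialization


def _report_payload(report: BoundsReport | WorstCaseResult) -> tuple[str, dict]:
    if isinstance(report, WorstCaseResult):
        data = {
            "peak_sar": _sig12(report.peak_sar),
            "argmax": int(report.argmax),
            "peak_voxel": None
            if report.peak_voxel is None
            else [int(v) for v in report.peak_voxel],
            "amplitudes": [_sig12(v) for v in report.amplitudes],
            "max_sar": [_sig12(v) for v in report.max_sar],
            "phases": [[_sig12(p) for p in row] for row in report.phases],
            "iterations": [int(i) for i in report.iterations],
            "converged": [bool(c) for c in report.converged],
        }
        return "worst_case", data
    if isinstance(report, BoundsReport):
        data: dict[str, Any] = {"n_drives": int(report.n_drives)}
        if report.actual is not None:
            data["actual"] = [_sig12(v) for v in report.actual]
        for m in report.available_methods():
            data[m] = [_sig12(v) for v in getattr(report, m)]
        return "bounds_report", data
    raise ValidationError(f"cannot serialize object of type {type(report)!r}")


def write_report(
    report: BoundsReport | WorstCaseResult,
    path: str | Path,
    format: str = "json",
    seed: int | None = None,
    config: Any = None,
) -> None:
    """Serialize a report with schema version and provenance stamped."""
    kind, data = _report_payload(report)
    if format == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "kind": kind,
            "provenance": provenance_block(seed=seed, config=config),
            "data": data,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    elif format == "csv":
        if kind == "worst_case":
            df = pd.DataFrame(
                {
                    "matrix": np.arange(len(data["max_sar"])),
                    "max_sar": data["max_sar"],
                    "iterations": data["iterations"],
                    "converged": data["converged"],
                }
            )
        else:
            cols = {"drive": np.arange(data["n_drives"])}
            for key in ("actual", "tm", "rp", "tp", "lb", "ub"):
                if key in data:
                    cols[key] = data[key]
            df = pd.DataFrame(cols)
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    validate_report_dict(doc)
    return doc


def validate_report_dict(doc: dict) -> None:
    """Check a JSON report against the shipped minimal schema."""
    for key in REPORT_SCHEMA["required"]:
        if key not in doc:
            raise ParseError(f"report missing required key {key!r}")
    for key, typ in REPORT_SCHEMA["properties"].items():
        expected = {"str": str, "dict": dict}[typ]
        if not isinstance(doc[key], expected):
            raise ParseError(f"report key {key!r} must be {typ}")


def write_histogram_csv(
    path: str | Path, report: BoundsReport, bins: int = 50
) -> None:
    """Overestimation histogram export: shared bin edges, one count column
    per method."""
    methods = report.available_methods()
    allvals = np.concatenate([report.overestimation(m) for m in methods])
    edges = np.histogram_bin_edges(allvals, bins=bins)
    cols = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for m in methods:
        cols[f"count_{m}"], _ = np.histogram(report.overestimation(m), bins=edges)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """CLI run configuration (YAML/JSON loadable)."""

    qset_path: str | None = None
    output_path: str | None = None
    solver: TrigMaxConfig = field(default_factory=TrigMaxConfig)
    delta: float = 0.05
    n_drives: int = 1000
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ParseError(f"{path} does not contain a mapping")
        solver = TrigMaxConfig(**raw.pop("solver", {}))
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(solver=solver, **known)
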