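"""Plain-text readers and writers for curves, maps, fields and ensembles.

Force curves are CSV with an explicit unit header (`separation_m,force_N`
or `separation_nm,force_nN`; the nm/nN variant is converted on read).
Grids (elasticity maps, exponent fields) are tab-separated numeric blocks
with a `#`-prefixed header. Every file gets a JSON sidecar with the same
basename carrying full parameter provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from .gel import ElasticityMap, ExponentField
from .hertz import ForceCurve, ProbeSpec


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_force_curve(curve: ForceCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"separation_m": curve.separation_m, "force_N": curve.force_N}
    ).to_csv(path, index=False)
    meta = {
        "direction": curve.direction,
        "setpoint_N": curve.setpoint_N,
        "probe": {
            "radius_m": curve.probe.radius_m,
            "poisson_ratio": curve.probe.poisson_ratio,
            "spring_constant_N_per_m": curve.probe.spring_constant_N_per_m,
        },
        "metadata": curve.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_force_curve(path) -> ForceCurve:
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] == ["separation_m", "force_N"]:
        sep, force = df["separation_m"].to_numpy(), df["force_N"].to_numpy()
    elif cols[:2] == ["separation_nm", "force_nN"]:
        sep = df["separation_nm"].to_numpy() * 1e-9
        force = df["force_nN"].to_numpy() * 1e-9
    else:
        raise DomainError(f"unrecognized force-curve header {cols!r}")
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        probe = ProbeSpec(**meta["probe"])
        return ForceCurve(
            separation_m=sep,
            force_N=force,
            direction=meta["direction"],
            probe=probe,
            setpoint_N=meta["setpoint_N"],
            metadata=meta.get("metadata", {}),
        )
    return ForceCurve(separation_m=sep, force_N=force)


def _write_grid(values: np.ndarray, path: Path, header: dict) -> Path:
    lines = [f"# {k}={json.dumps(v)}" for k, v in sorted(header.items())]
    body = "\n".join(
        "\t".join(repr(float(v)) for v in row) for row in np.asarray(values)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def _read_grid(path: Path):
    header: dict = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, raw = line[1:].strip().partition("=")
            header[key.strip()] = json.loads(raw)
        elif line.strip():
            rows.append([float(v) for v in line.split("\t")])
    return np.asarray(rows), header


def write_map(emap: ElasticityMap, path) -> Path:
    path = Path(path)
    header = {
        "kind": "elasticity_map",
        "pixel_size_m": emap.pixel_size_m,
        "provenance": emap.provenance,
    }
    _write_grid(emap.moduli_Pa, path, header)
    sidecar = {
        "pixel_size_m": emap.pixel_size_m,
        "provenance": emap.provenance,
        "metadata": emap.metadata,
        "degraded_mask": None
        if emap.degraded_mask is None
        else emap.degraded_mask.astype(int).tolist(),
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_map(path) -> ElasticityMap:
    path = Path(path)
    values, header = _read_grid(path)
    if header.get("kind") != "elasticity_map":
        raise DomainError(f"{path} is not an elasticity map")
    mask = None
    metadata: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        metadata = side.get("metadata", {})
        if side.get("degraded_mask") is not None:
            mask = np.asarray(side["degraded_mask"], dtype=bool)
    return ElasticityMap(
        moduli_Pa=values,
        pixel_size_m=header["pixel_size_m"],
        provenance=header["provenance"],
        metadata=metadata,
        degraded_mask=mask,
    )


def write_field(fld: ExponentField, path) -> Path:
    path = Path(path)
    header = {
        "kind": "exponent_field",
        "pixel_size_m": fld.pixel_size_m,
        "f_mean": fld.f_mean,
        "f_sd": fld.f_sd,
        "correlation_length_px": fld.correlation_length_px,
        "seed": fld.seed,
    }
    _write_grid(fld.values, path, header)
    _sidecar(path).write_text(json.dumps(header, indent=2, sort_keys=True))
    return path


def read_field(path) -> ExponentField:
    path = Path(path)
    values, header = _read_grid(path)
    if header.get("kind") != "exponent_field":
        raise DomainError(f"{path} is not an exponent field")
    return ExponentField(
        values=values,
        f_mean=header["f_mean"],
        f_sd=header["f_sd"],
        correlation_length_px=header["correlation_length_px"],
        pixel_size_m=header["pixel_size_m"],
        seed=header.get("seed"),
    )


def write_ensemble(values: np.ndarray, path, provenance: dict) -> Path:
    path = Path(path)
    pd.DataFrame({"value": np.asarray(values, dtype=float)}).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return path


def read_ensemble(path):
    path = Path(path)
    values = pd.read_csv(path)["value"].to_numpy()
    sidecar = _sidecar(path)
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, provenance
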