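"""File formats: bead-model PDB, scattering text, p(r) text, CSV, JSON.

Conventions
-----------
* Bead models are PDB files with one HETATM per bead: the bead radius (Å)
  is stored in the B-factor column and the scattering weight in the
  occupancy column.  Coordinates in Å.  Subunit labels map to residue
  names (E2 → "E2 ", E3BP → "E3B", arm → "ARM", other → "BEA").
* Scattering curves and p(r) are whitespace-delimited text columns
  (q I [sigma]; r p), with '#'-prefixed header lines preserved on rewrite.
* Sedimentation-equilibrium and unfolding datasets are CSV with
  '#'-prefixed metadata rows before the header.
* JSON reports are written canonically (sorted keys, fixed separators) so
  identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .assembly import BeadModel
from .equilibrium import SEDataset, rpm_to_omega
from .scattering import DistanceDistribution, ScatteringCurve
from .unfolding import UnfoldingCurve

__all__ = [
    "write_bead_model", "read_bead_model",
    "write_curve", "read_curve",
    "write_pr", "read_pr",
    "write_se_csv", "read_se_csv",
    "write_unfolding_csv", "read_unfolding_csv",
    "write_json_report",
]

PathLike = Union[str, Path]

_LABEL_TO_RES = {"E2": "E2", "E3BP": "E3B", "arm": "ARM"}
_RES_TO_LABEL = {v: k for k, v in _LABEL_TO_RES.items()}


class FormatError(ValueError):
    """Malformed input file (message carries the offending line number)."""


def write_bead_model(model: BeadModel, path: PathLike) -> None:
    """Write a bead model as a PDB file (radius → B-factor, weight → occupancy)."""
    n = model.n_beads
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.atom_name[:] = "C"
    arr.element[:] = "C"
    arr.chain_id[:] = "A"
    arr.hetero[:] = True
    arr.res_id[:] = (model.chain_ids % 9999) + 1
    arr.res_name[:] = [_LABEL_TO_RES.get(str(l), "BEA") for l in model.labels]
    arr.set_annotation("occupancy", model.weights.astype(float))
    arr.set_annotation("b_factor", model.radii.astype(float))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_bead_model(path: PathLike, label: str = "") -> BeadModel:
    """Read a bead-model PDB written by :func:`write_bead_model`."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, extra_fields=["occupancy", "b_factor"])
    if arr.array_length() == 0:
        raise FormatError(f"{path}: no atom records found")
    radii = np.asarray(arr.b_factor, dtype=float)
    if np.any(radii <= 0):
        raise FormatError(
            f"{path}: non-positive bead radius in B-factor column")
    labels = np.array([_RES_TO_LABEL.get(rn, "bead") for rn in arr.res_name],
                      dtype=object)
    return BeadModel(np.asarray(arr.coord, dtype=float), radii,
                     np.asarray(arr.occupancy, dtype=float), labels,
                     label=label or Path(path).stem,
                     chain_ids=np.asarray(arr.res_id, dtype=np.int64) - 1)


def _read_columns(path: PathLike, n_min: int, n_max: int):
    headers, rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                headers.append(line.rstrip("\n"))
                continue
            parts = s.split()
            if not n_min <= len(parts) <= n_max:
                raise FormatError(
                    f"{path}:{ln}: expected {n_min}–{n_max} columns, "
                    f"got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = max(len(r) for r in rows)
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: inconsistent column counts")
    return headers, np.asarray(rows)


def write_curve(curve: ScatteringCurve, path: PathLike,
                headers: Sequence[str] = ()) -> None:
    """Write a scattering curve as 3-column text (q, I, sigma)."""
    cols = [curve.q, curve.I]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    with open(path, "w") as fh:
        for h in headers:
            fh.write(h if h.startswith("#") else "# " + h)
            fh.write("\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.10e")


def read_curve(path: PathLike) -> tuple[ScatteringCurve, list]:
    """Read (q, I[, sigma]) text; returns the curve and its header lines."""
    headers, data = _read_columns(path, 2, 3)
    try:
        curve = ScatteringCurve(data[:, 0], data[:, 1],
                                data[:, 2] if data.shape[1] == 3 else None)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    return curve, headers


def write_pr(dist: DistanceDistribution, path: PathLike,
             headers: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in headers:
            fh.write(h if h.startswith("#") else "# " + h)
            fh.write("\n")
        fh.write(f"# Dmax {dist.Dmax:.10e}\n")
        np.savetxt(fh, np.column_stack([dist.r, dist.p]), fmt="%.10e")


def read_pr(path: PathLike) -> DistanceDistribution:
    headers, data = _read_columns(path, 2, 3)
    dmax = None
    for h in headers:
        parts = h.lstrip("# ").split()
        if parts and parts[0] == "Dmax":
            dmax = float(parts[1])
    if dmax is None:
        dmax = float(data[:, 0].max())
    return DistanceDistribution(data[:, 0], data[:, 1], Dmax=dmax)


def write_se_csv(dataset: SEDataset, path: PathLike, vbar: float) -> None:
    """SE scan as CSV (r_cm, signal) with metadata header rows."""
    with open(path, "w") as fh:
        fh.write(f"# omega_rpm,{dataset.omega * 60 / (2 * np.pi):.6f}\n")
        fh.write(f"# temperature_C,{dataset.T - 273.15:.4f}\n")
        fh.write(f"# vbar,{vbar:.6f}\n")
        fh.write(f"# r_ref_cm,{dataset.r_ref:.6f}\n")
        fh.write(f"# loading_concentration,{dataset.loading_concentration:.6g}\n")
        pd.DataFrame({"r_cm": dataset.r, "signal": dataset.signal}).to_csv(
            fh, index=False, float_format="%.10g")


def read_se_csv(path: PathLike) -> tuple[SEDataset, float]:
    """Read an SE CSV; returns (dataset, vbar)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for ln, line in enumerate(lines):
        if line.startswith("#"):
            try:
                key, val = line.lstrip("# ").strip().split(",")
                meta[key] = float(val)
            except ValueError:
                raise FormatError(f"{path}:{ln + 1}: bad metadata row") from None
            body_start = ln + 1
        else:
            break
    for key in ("omega_rpm", "temperature_C", "vbar"):
        if key not in meta:
            raise FormatError(f"{path}: missing metadata '{key}'")
    df = pd.read_csv(path, skiprows=body_start)
    if list(df.columns) != ["r_cm", "signal"]:
        raise FormatError(f"{path}: expected columns r_cm,signal")
    try:
        ds = SEDataset(df["r_cm"].to_numpy(), df["signal"].to_numpy(),
                       omega=rpm_to_omega(meta["omega_rpm"]),
                       T=meta["temperature_C"] + 273.15,
                       r_ref=meta.get("r_ref_cm", float(df["r_cm"].iloc[0])),
                       loading_concentration=meta.get("loading_concentration", 1.0))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    return ds, meta["vbar"]


def write_unfolding_csv(curve: UnfoldingCurve, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# channel,{curve.channel}\n")
        pd.DataFrame({"c_M": curve.c, "y": curve.y}).to_csv(
            fh, index=False, float_format="%.10g")


def read_unfolding_csv(path: PathLike) -> UnfoldingCurve:
    channel = ""
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if line.lstrip("# ").startswith("channel,"):
                    channel = line.lstrip("# ").strip().split(",", 1)[1]
            else:
                break
    df = pd.read_csv(path, skiprows=skip)
    if list(df.columns) != ["c_M", "y"]:
        raise FormatError(f"{path}: expected columns c_M,y")
    try:
        return UnfoldingCurve(df["c_M"].to_numpy(), df["y"].to_numpy(),
                              channel=channel)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_json_report(obj: dict, path: PathLike) -> None:
    """Canonical JSON: sorted keys, fixed separators → byte-reproducible."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
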