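"""Snapshot-series persistence and visualisation exports.

The structured store is HDF5 (one group per frame, event tables as CSV
payloads, run configuration as JSON attributes) written with
``track_times=False`` so identical content produces identical bytes.
Per-frame XYZ text and legacy-ASCII VTK structured-points files are
exported for visualisation.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .agents import AgentState
from .config import Domain, Parameters

__all__ = ["save_series", "load_series", "write_xyz", "write_vtk_scalar",
           "write_field_csv", "SnapshotIOError"]


class SnapshotIOError(RuntimeError):
    pass


def _df_to_csv(df: pd.DataFrame) -> str:
    return df.to_csv(index=False)


def _csv_to_df(text: str) -> pd.DataFrame:
    if not text.strip():
        return pd.DataFrame()
    return pd.read_csv(_io.StringIO(text), float_precision="round_trip")


def save_series(series, path) -> None:
    """Write a SnapshotSeries to HDF5 (lossless, byte-stable)."""
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format"] = "biofilmdem-series-1"
        f.attrs["params"] = json.dumps(dataclasses.asdict(series.params), sort_keys=True)
        f.attrs["domain"] = json.dumps(dataclasses.asdict(series.domain), sort_keys=True)
        f.attrs["scenario"] = json.dumps(series.scenario_info, sort_keys=True)
        f.attrs["seed"] = series.seed
        f.attrs["events"] = _df_to_csv(series.events)
        f.attrs["detach_events"] = _df_to_csv(series.detach_events)
        f.attrs["metrics"] = _df_to_csv(series.metrics)
        f.attrs["removed_mass"] = series.removed_mass
        frames = f.create_group("frames")
        for k, fr in enumerate(series.frames):
            g = frames.create_group(f"{k:05d}")
            g.attrs["time"] = fr.time
            g.attrs["t_flow"] = fr.t_flow
            a = fr.agents
            for name, arr in (("id", a.id), ("group", a.group),
                              ("position", a.position), ("mass", a.mass),
                              ("eps_shell", a.eps_shell), ("velocity", a.velocity)):
                g.create_dataset(name, data=arr, track_times=False)
        fields = f.create_group("fields")
        for name, arr in (series.fields or {}).items():
            fields.create_dataset(name, data=arr, track_times=False)


def load_series(path):
    """Read a SnapshotSeries back; raises SnapshotIOError on malformed files."""
    from .scenarios import Frame, SnapshotSeries   # avoid import cycle
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "biofilmdem-series-1":
                raise SnapshotIOError(f"{path}: not a biofilmdem series file")
            params = Parameters(**json.loads(f.attrs["params"]))
            domain = Domain(**json.loads(f.attrs["domain"]))
            scenario_info = json.loads(f.attrs["scenario"])
            frames = []
            for key in sorted(f["frames"]):
                g = f["frames"][key]
                agents = AgentState(g["id"][...], g["group"][...],
                                    g["position"][...], g["mass"][...],
                                    g["eps_shell"][...], g["velocity"][...])
                frames.append(Frame(float(g.attrs["time"]),
                                    float(g.attrs["t_flow"]), agents))
            fields = {name: f["fields"][name][...] for name in f["fields"]}
            return SnapshotSeries(
                frames=frames,
                events=_csv_to_df(f.attrs["events"]),
                detach_events=_csv_to_df(f.attrs["detach_events"]),
                metrics=_csv_to_df(f.attrs["metrics"]),
                fields=fields, params=params, domain=domain,
                scenario_info=scenario_info, seed=int(f.attrs["seed"]),
                removed_mass=float(f.attrs["removed_mass"]))
    except (KeyError, OSError, ValueError) as exc:
        raise SnapshotIOError(f"{path}: malformed snapshot store ({exc})") from exc


def write_xyz(agents: AgentState, p, path, comment: str = "") -> None:
    """One XYZ frame: count, comment, then `id group x y z radius` rows."""
    rc = agents.contact_radius(p)
    with open(path, "w") as fh:
        fh.write(f"{agents.n}\n{comment}\n")
        for k in range(agents.n):
            x, y, z = agents.position[k]
            fh.write(f"{agents.id[k]} {agents.group[k]} "
                     f"{x:.6f} {y:.6f} {z:.6f} {rc[k]:.6f}\n")


def write_vtk_scalar(field: np.ndarray, domain: Domain, path,
                     name: str = "S") -> None:
    """Legacy-ASCII VTK STRUCTURED_POINTS file of one voxel scalar field."""
    field = np.asarray(field)
    if field.shape != domain.shape:
        raise SnapshotIOError(
            f"field shape {field.shape} != grid {domain.shape}")
    hx, hy, hz = domain.voxel
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {domain.N_x} {domain.N_y} {domain.N_z}\n")
        fh.write(f"ORIGIN {hx / 2:.6g} {hy / 2:.6g} {hz / 2:.6g}\n")
        fh.write(f"SPACING {hx:.6g} {hy:.6g} {hz:.6g}\n")
        fh.write(f"POINT_DATA {field.size}\n")
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        # VTK expects x fastest
        for k in range(domain.N_z):
            for j in range(domain.N_y):
                for i in range(domain.N_x):
                    fh.write(f"{field[i, j, k]:.9g}\n")


def write_field_csv(field: np.ndarray, domain: Domain, path,
                    name: str = "S") -> None:
    """Flat CSV: voxel indices and concentration."""
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in domain.shape), indexing="ij")
    pd.DataFrame({"i": ii.ravel(), "j": jj.ravel(), "k": kk.ravel(),
                  name: np.asarray(field).ravel()}).to_csv(path, index=False)
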