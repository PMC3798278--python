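"""File output and configuration: VTK/PLY/OFF meshes, CSV observables,
JSON run manifests and YAML parameter files."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contact import MDParams
from .cortex import CortexParams
from .dynamics import DynamicsParams
from .mesh import TriMesh


# ---------------------------------------------------------------------------
# mesh writers
# ---------------------------------------------------------------------------

def write_vtk(path, mesh: TriMesh, point_data: dict | None = None) -> None:
    """Legacy ASCII VTK polydata with optional scalar point data.

    Point fields (cortex tension, stretch, normal pressure, ...) become
    POINT_DATA scalars so snapshots can be rendered directly.
    """
    path = Path(path)
    x = mesh.nodes
    tri = mesh.triangles
    lines = [
        "# vtk DataFile Version 3.0",
        "mdcell snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(x)} double",
    ]
    lines += [" ".join(f"{v:.10e}" for v in row) for row in x]
    lines.append(f"POLYGONS {len(tri)} {4 * len(tri)}")
    lines += ["3 " + " ".join(str(i) for i in row) for row in tri]
    if point_data:
        lines.append(f"POINT_DATA {len(x)}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10e}" for v in values]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.10e}" for v in row) for row in values]
    path.write_text("\n".join(lines) + "\n")


def write_pvd(path, entries: list[tuple[float, str]]) -> None:
    """PVD collection indexing a VTK time series (time, relative path)."""
    body = "\n".join(
        f'    <DataSet timestep="{t}" file="{f}"/>' for t, f in entries
    )
    Path(path).write_text(
        '<?xml version="1.0"?>\n<VTKFile type="Collection" version="0.1">\n'
        f"  <Collection>\n{body}\n  </Collection>\n</VTKFile>\n"
    )


def write_ply(path, mesh: TriMesh) -> None:
    mesh.to_trimesh().export(str(path), file_type="ply", encoding="ascii")


def write_off(path, mesh: TriMesh) -> None:
    # full-precision OFF (library writers truncate metre-scale coordinates)
    lines = ["OFF", f"{mesh.n_nodes} {mesh.n_triangles} 0"]
    lines += [" ".join(f"{v:.17g}" for v in row) for row in mesh.nodes]
    lines += ["3 " + " ".join(str(i) for i in row) for row in mesh.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def read_off(path) -> TriMesh:
    import trimesh as _trimesh

    tm = _trimesh.load(str(path), file_type="off", process=False)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def spreading_to_frame(curve) -> pd.DataFrame:
    """SpreadingCurve → DataFrame with SI columns t_s, A_contact_m2, r_c_m."""
    return pd.DataFrame(
        {"t_s": curve.times, "A_contact_m2": curve.contact_areas,
         "r_c_m": curve.contact_radii}
    )


def write_observables(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def patch_diagnostics(state, time: float | None = None) -> pd.DataFrame:
    """Per-triangle contact diagnostics of a simulation state: time, patch
    area and force magnitude, plus the total contact area (streamable to
    CSV step by step)."""
    rows = [{
        "t_s": state.time if time is None else time,
        "triangle": p.triangle,
        "A_contact_m2": p.A_contact,
        "F_N": float(np.linalg.norm(p.F)),
    } for p in state.patches]
    frame = pd.DataFrame(rows, columns=["t_s", "triangle", "A_contact_m2", "F_N"])
    frame.attrs["total_contact_area_m2"] = float(frame["A_contact_m2"].sum()) \
        if len(frame) else 0.0
    return frame


# ---------------------------------------------------------------------------
# configuration and manifests
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


_SECTIONS = {"cortex": CortexParams, "contact": MDParams, "dynamics": DynamicsParams}


def params_from_dict(cfg: dict):
    """Build (CortexParams, MDParams, DynamicsParams) from a nested dict.

    Unknown keys raise ConfigError naming the offending path, so typos in
    parameter files fail loudly.
    """
    out = {}
    for section, cls in _SECTIONS.items():
        sub = dict(cfg.get(section, {}) or {})
        names = {f.name for f in dataclasses.fields(cls)}
        for key in sub:
            if key not in names:
                raise ConfigError(f"unknown key '{section}.{key}'")
        out[section] = cls(**sub)
    extra = set(cfg) - set(_SECTIONS) - {"protocol"}
    if extra:
        raise ConfigError(f"unknown section(s): {sorted(extra)}")
    return out["cortex"], out["contact"], out["dynamics"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def write_manifest(path, config: dict, seed: int | None = None,
                   extra: dict | None = None) -> None:
    """JSON run manifest: full configuration, seed and library versions."""
    import scipy
    import trimesh

    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "mdcell": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "trimesh": trimesh.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=float) + "\n")
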