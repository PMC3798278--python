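"""The three cell-scale experiments: stretching, relaxation and spreading.

Stretching mimics optical-tweezer assays: opposite forces pulled on the
outermost 5 % of nodes on either side of a biconcave cell until equilibrium,
recording axial and transversal diameters.  Relaxation releases a stretched
cell and fits the exponential recovery of the axial diameter.  Spreading
places a cell one half adhesive-range above a rigid plane and records the
growth of the contact radius r_c = sqrt(sum of contact areas / pi), whose
early regime follows the universal r_c ~ t^(1/2) law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .contact import MDParams, Plane
from .cortex import CortexParams
from .dynamics import DynamicsParams, Simulation
from .mesh import (DeflationParams, RestState, TriMesh, deflate_to_biconcave,
                   icosphere)


@dataclass
class ProtocolConfig:
    """Run description shared by all protocols.

    ``subdiv`` counts icosahedron subdivisions the way the RBC literature
    does (4 → 642 nodes, 5 → 2562 nodes); the mesh itself is built with
    ``icosphere(subdiv - 1, ...)`` whose node count is 10·4^n + 2.
    """

    protocol: str = "spread"            # stretch | relax | spread
    subdiv: int = 4
    radius: float = 3.25e-6             # m
    shape: str = "sphere"               # sphere | biconcave
    volume_fraction: float = 0.6        # biconcave deflation target
    t_end: float = 1.2                  # s
    dt: float | None = None             # default: DynamicsParams.dt
    observe_every: int = 50
    cortex: CortexParams = field(default_factory=CortexParams)
    contact: MDParams = field(default_factory=MDParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    # stretch / relax
    forces: tuple = (0.0, 25e-12, 50e-12, 100e-12, 150e-12)   # N
    pull_fraction: float = 0.05
    force_ramp_time: float = 5e-3       # s, linear ramp of the pulling force
    equil_speed: float = 1e-9           # m/s, sustained equilibrium criterion
    equil_hold_steps: int = 1000
    equil_max_steps: int = 200_000
    relax_target_DA: float = 8.9e-6     # m, pre-release axial diameter
    relax_force: float = 40e-12         # N, stretching force before release
    # spreading
    initial_gap: float | None = None    # default h0 / 2
    fit_window: tuple = (0.15, 0.5)     # r_c window (fractions of final r_c)
    cap_fraction: float = 0.5           # node fraction for the sphere fit
    snapshot_dir: str | None = None     # write a final VTK snapshot here

    def build_mesh(self) -> TriMesh:
        n = self.subdiv - 1
        mesh = icosphere(n, self.radius)
        if self.shape == "biconcave":
            mesh = deflate_to_biconcave(mesh, self.volume_fraction)
        elif self.shape != "sphere":
            raise ValueError(f"unknown shape '{self.shape}'")
        return mesh


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

@dataclass
class SpreadingCurve:
    """Contact-area history of one spreading run."""

    times: np.ndarray
    contact_areas: np.ndarray
    contact_radii: np.ndarray
    exponent: float | None = None
    exponent_stderr: float | None = None
    fit_window: tuple | None = None
    flags: list = field(default_factory=list)
    sim: object | None = None      # the Simulation at the final state

    @classmethod
    def from_rows(cls, rows) -> "SpreadingCurve":
        arr = np.asarray(rows, dtype=float)
        return cls(times=arr[:, 0], contact_areas=arr[:, 1],
                   contact_radii=np.sqrt(arr[:, 1] / np.pi))


@dataclass
class StretchResult:
    force: float          # N (total per side)
    D_A: float            # m, axial diameter (pull direction)
    D_T: float            # m, transversal diameter
    equilibrated: bool


def diameters(mesh: TriMesh, axis: int = 0) -> tuple[float, float]:
    """Axial (along ``axis``) and transversal (max other extent) diameters."""
    x = mesh.nodes
    d = x.max(axis=0) - x.min(axis=0)
    d_a = float(d[axis])
    d_t = float(np.max(np.delete(d, axis)))
    return d_a, d_t


def powerlaw_fit(curve: SpreadingCurve, window: tuple = (0.15, 0.5)):
    """OLS slope of log r_c vs log t inside the stated r_c window.

    The window is given as fractions of the final contact radius; at least
    10 samples are required.  Returns (exponent, stderr).
    """
    t = np.asarray(curve.times, dtype=float)
    r = np.asarray(curve.contact_radii, dtype=float)
    r_final = r[-1]
    lo, hi = window[0] * r_final, window[1] * r_final
    mask = (r >= lo) & (r <= hi) & (t > 0) & (r > 0)
    if mask.sum() < 10:
        raise ValueError(
            f"power-law window {window} contains only {int(mask.sum())} "
            "samples (need >= 10)"
        )
    res = stats.linregress(np.log(t[mask]), np.log(r[mask]))
    return float(res.slope), float(res.stderr)


def contact_angle(mesh, cap_fraction: float = 0.5,
                  max_residual: float = 0.2) -> float:
    """Effective contact angle (degrees) of a spread cell on z = 0.

    A sphere is least-squares fitted through the top ``cap_fraction`` of the
    nodes (by height); the angle between the fitted sphere and the plane at
    their intersection circle is arccos(-z_center / R_fit): 90° for a
    hemisphere, 180° for a tangent full sphere.  ``mesh`` may be a TriMesh
    or a bare (N, 3) coordinate array.
    """
    x = mesh.nodes if hasattr(mesh, "nodes") else np.asarray(mesh, dtype=float)
    z_sorted = np.sort(x[:, 2])
    cut = z_sorted[int((1.0 - cap_fraction) * (len(z_sorted) - 1))]
    pts = x[x[:, 2] >= cut]
    # algebraic sphere fit: |p|² = 2 p·c + (R² - |c|²)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center, k = sol[:3], sol[3]
    R_fit = math.sqrt(max(k + center @ center, 0.0))
    resid = np.abs(np.linalg.norm(pts - center, axis=1) - R_fit)
    if resid.max() > max_residual * R_fit:
        raise ValueError(
            f"sphere fit residual {resid.max():.3e} m exceeds "
            f"{max_residual:.2f}·R_fit = {max_residual * R_fit:.3e} m"
        )
    ratio = np.clip(-center[2] / R_fit, -1.0, 1.0)
    return math.degrees(math.acos(ratio))


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _pull_sets(mesh: TriMesh, fraction: float, axis: int = 0):
    x = mesh.nodes[:, axis]
    n_sel = max(int(round(fraction * len(x))), 1)
    lo = np.argsort(x)[:n_sel]
    hi = np.argsort(x)[-n_sel:]
    return lo, hi


def _make_sim(config: ProtocolConfig, mesh: TriMesh, plane=None,
              external_force=None, rest: RestState | None = None) -> Simulation:
    return Simulation(mesh, rest=rest, cortex=config.cortex, md=config.contact,
                      dyn=config.dynamics, plane=plane,
                      external_force=external_force)


def _equilibrate(sim: Simulation, config: ProtocolConfig, dt: float) -> bool:
    """Step until the max node speed stays below equil_speed; True if reached."""
    hold = 0
    need = max(config.equil_hold_steps, 1)
    for _ in range(config.equil_max_steps):
        sim.step_adaptive(dt)
        if sim.state.time <= config.force_ramp_time:
            continue
        if float(np.linalg.norm(sim.state.velocities, axis=1).max()) < config.equil_speed:
            hold += 1
            if hold >= need:
                return True
        else:
            hold = 0
    return False


def stretch_protocol(config: ProtocolConfig) -> list[StretchResult]:
    """Force sweep of the optical-tweezer stretching experiment.

    For every force level the outermost 5 % of the nodes on each x side are
    pulled apart with the total force split equally; the run continues to
    equilibrium and the axial/transversal diameters are recorded.
    """
    base_mesh = config.build_mesh()
    dt = config.dt or config.dynamics.dt
    results = []
    for F in config.forces:
        mesh = base_mesh.copy()
        rest = RestState.from_mesh(base_mesh)
        lo, hi, F_node = _stretch_force_sets(mesh, config, F)

        def pull(state, lo=lo, hi=hi, F_node=F_node):
            s = min(state.time / config.force_ramp_time, 1.0) \
                if config.force_ramp_time > 0 else 1.0
            f = np.zeros_like(state.mesh.nodes)
            f[lo, 0] = -s * F_node[0]
            f[hi, 0] = s * F_node[1]
            return f

        sim = _make_sim(config, mesh, external_force=pull if F else None,
                        rest=rest)
        ok = _equilibrate(sim, config, dt) if F else True
        d_a, d_t = diameters(sim.state.mesh, axis=0)
        results.append(StretchResult(force=F, D_A=d_a, D_T=d_t, equilibrated=ok))
    return results


def _stretch_force_sets(mesh, config, F):
    lo, hi = _pull_sets(mesh, config.pull_fraction, axis=0)
    return lo, hi, (F / len(lo), F / len(hi))


def relax_protocol(config: ProtocolConfig):
    """Stretch-and-release: returns (times, D_A(t), fitted relaxation time).

    The cell is stretched with ``relax_force`` until the axial diameter
    reaches ``relax_target_DA`` (or equilibrium), the force is removed at
    t = 0 and D_A(t) is recorded; an exponential decay toward the rest
    diameter is fitted by log-linear least squares.
    """
    mesh = config.build_mesh()
    rest = RestState.from_mesh(mesh)
    D_rest, _ = diameters(mesh, axis=0)
    dt = config.dt or config.dynamics.dt
    lo, hi, F_node = _stretch_force_sets(mesh, config, config.relax_force)

    def pull(state):
        s = min(state.time / config.force_ramp_time, 1.0) \
            if config.force_ramp_time > 0 else 1.0
        f = np.zeros_like(state.mesh.nodes)
        f[lo, 0] = -s * F_node[0]
        f[hi, 0] = s * F_node[1]
        return f

    sim = _make_sim(config, mesh, external_force=pull, rest=rest)
    for _ in range(config.equil_max_steps):
        sim.step_adaptive(dt)
        if diameters(sim.state.mesh, axis=0)[0] >= config.relax_target_DA:
            break
        if sim.state.time <= config.force_ramp_time:
            continue          # still ramping the load: not an equilibrium
        if float(np.linalg.norm(sim.state.velocities, axis=1).max()) < config.equil_speed:
            break

    # release
    sim.external_force = None
    sim.state.time = 0.0
    times, DA = [], []

    def obs(state):
        times.append(state.time)
        DA.append(diameters(state.mesh, axis=0)[0])

    sim.run(config.t_end, dt=dt, observer=obs,
            observe_every=config.observe_every, adaptive=True)
    times = np.asarray(times)
    DA = np.asarray(DA)

    # log-linear fit of (D_A - D_rest) over the decaying part
    excess = DA - D_rest
    e0 = excess[0]
    mask = excess > 0.05 * e0
    if mask.sum() >= 3 and e0 > 0:
        res = stats.linregress(times[mask], np.log(excess[mask]))
        tau = -1.0 / res.slope if res.slope < 0 else math.inf
    else:
        tau = math.nan
    return times, DA, float(tau)


def spread_protocol(config: ProtocolConfig) -> SpreadingCurve:
    """Adhesion-driven spreading on the rigid plane z = 0.

    The cell starts with its lowest node half an adhesive range above the
    plane and zero velocity; r_c(t) is recorded on the observation cadence
    and the early power-law exponent fitted in the configured window.
    """
    mesh = config.build_mesh()
    gap = config.initial_gap if config.initial_gap is not None else config.contact.h0 / 2
    mesh.nodes[:, 2] += gap - mesh.nodes[:, 2].min()
    rest = RestState.from_mesh(mesh)
    sim = _make_sim(config, mesh, plane=Plane(), rest=rest)
    dt = config.dt or config.dynamics.dt

    rows = []

    def obs(state):
        rows.append((state.time, sim.contact_area()))

    sim.run(config.t_end, dt=dt, observer=obs,
            observe_every=config.observe_every, adaptive=True)
    curve = SpreadingCurve.from_rows(rows)
    curve.sim = sim                # final state, for field inspection
    if config.snapshot_dir is not None:
        _write_spread_snapshot(sim, config)
    if curve.contact_areas[-1] <= 0.0:
        curve.flags.append("detached")
        return curve
    try:
        exp, err = powerlaw_fit(curve, config.fit_window)
        curve.exponent, curve.exponent_stderr = exp, err
        curve.fit_window = config.fit_window
    except ValueError as e:
        curve.flags.append(str(e))
    return curve


def _write_spread_snapshot(sim: Simulation, config: ProtocolConfig) -> None:
    """Final-state VTK snapshot with the standard point fields (cortex
    tension, node-averaged stretch, normal pressure) plus per-patch
    contact diagnostics as CSV."""
    from pathlib import Path

    from .cortex import cortex_tension
    from .io import patch_diagnostics, write_vtk

    outdir = Path(config.snapshot_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    st = sim.state
    mesh = st.mesh
    L = mesh.edge_lengths()
    stretch_edge = L / st.rest.L0
    node_stretch = np.zeros(mesh.n_nodes)
    cnt = np.zeros(mesh.n_nodes)
    np.add.at(node_stretch, mesh.edges.ravel(), np.repeat(stretch_edge, 2))
    np.add.at(cnt, mesh.edges.ravel(), 1.0)
    node_stretch /= np.maximum(cnt, 1.0)
    fields = {
        "cortex_tension": cortex_tension(mesh, st.rest, sim.cortex, L=L),
        "stretch": node_stretch,
        "normal_pressure": sim.normal_pressure(),
    }
    write_vtk(outdir / f"spread_t{st.time:.4f}.vtk", mesh, fields)
    patch_diagnostics(st).to_csv(outdir / "contact_diagnostics.csv",
                                 index=False)


SWEEPABLE = {
    "W": ("contact", "W"),
    "ks": ("cortex", "ks"),
    "x0": ("cortex", "x0"),
    "kb": ("cortex", "kb"),
    "gamma_n": ("dynamics", "gamma_n"),
    "ka_local": ("cortex", "ka_local"),
}


def parameter_sweep(config: ProtocolConfig, parameter: str, values):
    """One spreading curve per parameter value plus a summary table.

    ``parameter`` is one of W, ks, x0, kb, gamma_n, ka_local — the knobs
    with the strongest influence on spreading.  Failed members are reported
    in the summary with their flag instead of aborting the sweep.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"parameter must be one of {sorted(SWEEPABLE)}")
    section, attr = SWEEPABLE[parameter]
    curves, records = {}, []
    for v in values:
        cfg = replace(config)
        setattr(cfg, section, replace(getattr(config, section), **{attr: v}))
        try:
            curve = spread_protocol(cfg)
            curves[v] = curve
            records.append({
                parameter: v,
                "final_r_c": float(curve.contact_radii[-1]),
                "exponent": curve.exponent,
                "flags": ";".join(curve.flags),
            })
        except Exception as exc:  # a failed member must not kill the sweep
            records.append({parameter: v, "final_r_c": np.nan,
                            "exponent": np.nan, "flags": f"failed: {exc}"})
    return curves, pd.DataFrame.from_records(records)
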