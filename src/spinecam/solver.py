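"""Coupled membrane / reaction-diffusion time integration on the spine mesh.

Spatial discretisation: P1 (linear tetrahedral) finite elements with lumped
mass.  Time integration: first-order operator splitting at a fixed step
equal to the configured maximum (default 10 µs) — an implicit-Euler
diffusion solve per mobile species (prefactorised sparse LU, exactly mass
conservative with lumped mass) followed by a per-node backward-Euler
reaction solve (damped Newton, preserves the network's linear invariants).
The membrane ODEs advance with exact exponential-relaxation updates, with
SK gating driven by the Ca2+ concentration at a probe 20 nm inside the SK
cluster.  Boundary conditions are zero flux everywhere except the channel
cluster patches, which inject the instantaneous channel Ca2+ currents.

Accuracy is governed by the step/tolerance convergence and conservation
contracts (tested), not by the integrator's formal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from . import channels as ch
from . import chemistry as chem
from .geometry import (Mesh, ProbeSet, build_spine_mesh, place_probes,
                       mesh_spec_for_level)

__all__ = [
    "SolverConfig",
    "FieldState",
    "SimOutput",
    "assemble",
    "step",
    "run_protocol",
    "solve_steady_state",
    "Simulation",
]


@dataclass(frozen=True)
class SolverConfig:
    """Time-integration settings (printed solver parameters as defaults)."""

    max_step_us: float = 10.0    # maximum (and actual) time step, µs
    abs_tol: float = 1e-3        # scaled tolerance; Newton uses 1e-7 x this
    order_cap: int = 2           # retained for configuration compatibility
    t_end: float = 60.0          # ms
    output_dt: float = 0.05      # ms
    snapshot_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.max_step_us <= 0 or self.abs_tol <= 0:
            raise ValueError("max step and tolerance must be > 0")

    @property
    def dt(self) -> float:
        return self.max_step_us * 1e-3  # ms

    @property
    def newton_tol(self) -> float:
        return 1e-7 * self.abs_tol


@dataclass
class FieldState:
    """All unknowns at one instant: nodal concentration fields plus the
    membrane state.  CaM is carried as the two lobe marginals (exact, see
    chemistry module)."""

    t: float
    fields: dict[str, np.ndarray]       # 'Ca', buffer names, 'cam_N', 'cam_C'
    membrane: ch.MembraneState

    def copy(self) -> "FieldState":
        return FieldState(self.t, {k: v.copy() for k, v in self.fields.items()},
                          replace(self.membrane))


@dataclass
class SimOutput:
    """Sampled time series of a protocol run (units annotated in ``units``)."""

    t: np.ndarray
    V: np.ndarray
    s: np.ndarray
    currents: dict[str, np.ndarray]
    global_avg: dict[str, np.ndarray]
    probes: dict[str, dict[str, np.ndarray]]
    total_ca: np.ndarray        # volume integral of free+bound Ca, µM·µm³
    influx_cum: np.ndarray      # cumulative boundary influx, µM·µm³
    extrusion_cum: np.ndarray   # cumulative extrusion minus basal, µM·µm³
    snapshots: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    units: dict = field(default_factory=lambda: {
        "t": "ms", "V": "mV", "currents": "pA", "concentrations": "µM",
        "totals": "µM·µm³"})

    def to_frame(self):
        """Flat pandas DataFrame of all time series."""
        import pandas as pd
        data = {"t": self.t, "V": self.V, "s": self.s}
        for k, v in self.currents.items():
            data[k] = v
        for k, v in self.global_avg.items():
            data[f"global_{k}"] = v
        for pname, series in self.probes.items():
            for k, v in series.items():
                data[f"probe_{pname}_{k}"] = v
        data["total_ca"] = self.total_ca
        data["influx_cum"] = self.influx_cum
        return pd.DataFrame(data)

    def save_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_hdf5(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs.update({k: str(v) for k, v in self.meta.items()})
            f["t"] = self.t
            f["V"] = self.V
            f["s"] = self.s
            for grp, d in (("currents", self.currents),
                           ("global", self.global_avg)):
                g = f.create_group(grp)
                for k, v in d.items():
                    g[k] = v
            g = f.create_group("probes")
            for pname, series in self.probes.items():
                pg = g.create_group(pname)
                for k, v in series.items():
                    pg[k] = v
            f["total_ca"] = self.total_ca
            f["influx_cum"] = self.influx_cum
            if self.snapshots:
                g = f.create_group("snapshots")
                for tsnap, fields_ in self.snapshots.items():
                    sg = g.create_group(f"t_{tsnap:g}")
                    for k, v in fields_.items():
                        sg[k] = v


# ---------------------------------------------------------------------------
# FEM assembly
# ---------------------------------------------------------------------------

def _p1_stiffness(mesh: Mesh) -> sp.csr_matrix:
    """Assemble the P1 stiffness matrix (unit diffusivity), vectorised."""
    pts = mesh.points
    tets = mesh.tets
    X = pts[tets]  # (T,4,3)
    # gradients of barycentric basis: solve per tet
    E = X[:, 1:] - X[:, 0:1]                    # (T,3,3) edge matrix rows
    Einv = np.linalg.inv(E)                     # (T,3,3)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(Einv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    V = mesh.cell_volumes
    Kloc = np.einsum("tid,tjd,t->tij", g, g, V)  # (T,4,4)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix((Kloc.reshape(-1), (rows, cols)),
                      shape=(mesh.n_points, mesh.n_points)).tocsr()
    return K


def _patch_weight_vector(mesh: Mesh, cluster_index: int | None) -> np.ndarray:
    """Nodal weights distributing a unit total molar rate over a patch
    (or over the entire boundary when ``cluster_index`` is None)."""
    w = np.zeros(mesh.n_points)
    if cluster_index is None:
        sel = np.arange(len(mesh.boundary_faces))
    else:
        sel = mesh.patch_faces(cluster_index)
        if len(sel) == 0:
            raise ValueError(f"cluster {cluster_index} has no boundary faces")
    areas = mesh.face_areas[sel]
    np.add.at(w, mesh.boundary_faces[sel].ravel(),
              np.repeat(areas / 3.0, 3))
    return w / w.sum()


def assemble(mesh: Mesh, spec: chem.ChemistrySpec) -> dict:
    """Discrete operators: stiffness ``K`` (unit D), lumped mass ``M``
    (node volumes), per-cluster patch weight vectors and the uniform
    boundary weight vector."""
    K = _p1_stiffness(mesh)
    ops = {
        "K": K,
        "M": mesh.node_volumes.copy(),
        "patch_weights": {c.kind: _patch_weight_vector(mesh, i)
                          for i, c in enumerate(mesh.clusters)},
        "uniform_weights": _patch_weight_vector(mesh, None),
        "species_D": _species_diffusivities(spec),
    }
    return ops


def _species_diffusivities(spec: chem.ChemistrySpec) -> dict[str, float]:
    """Diffusivity (µm²/ms) per mobile field."""
    d = {"Ca": spec.ca_diffusivity * 1e-3}
    for b in spec.buffers:
        if b.diffusivity > 0:
            d[b.name] = b.diffusivity * 1e-3
    if spec.cam is not None:
        d["cam_N"] = spec.cam.diffusivity * 1e-3
        d["cam_C"] = spec.cam.diffusivity * 1e-3
    return d


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

class Simulation:
    """Holds the mesh, operators, factorisations and probes for one run."""

    def __init__(self, mesh: Mesh, spec: chem.ChemistrySpec,
                 params: ch.ChannelParams, config: SolverConfig,
                 sk_probe_nm: float = 20.0, probe_nm: float = 20.0,
                 extra_probes: dict[str, np.ndarray] | None = None):
        self.mesh = mesh
        self.spec = spec
        self.params = params
        self.config = config
        self.ops = assemble(mesh, spec)
        self.reactions = chem.ReactionSystem(spec)
        self.dt = config.dt
        self._factors = {}
        M = self.ops["M"]
        K = self.ops["K"]
        for name, D in self.ops["species_D"].items():
            key = round(D, 12)
            if key not in self._factors:
                A = sp.diags(M) + self.dt * D * K
                self._factors[key] = splu(A.tocsc())
        self.readout_probes = place_probes(mesh, distance_nm=probe_nm,
                                           extra_points=extra_probes)
        sk = [c for c in mesh.clusters if c.kind == "SK"]
        self.sk_probe = (place_probes(mesh, clusters=sk, distance_nm=sk_probe_nm)
                         if sk else None)
        self.uniform_vgcc = any(c.kind == "VGCC" and c.uniform
                                for c in mesh.clusters)
        # resting channel currents (e.g. the small T-type window current)
        # are folded into the basal balance so that the unstimulated spine
        # is an exact steady state: boundary fluxes inject I(t) - I_rest
        rest = ch.channel_currents(
            ch.MembraneState.resting(params, spec.ca_rest), params)
        self._rest_n = rest["I_N_Ca"]
        self._rest_v = rest["I_CaT"] + rest["I_CaL"]

    # -- state ------------------------------------------------------------
    def initial_state(self) -> FieldState:
        eq = chem.equilibrium_init(self.spec.ca_rest, self.spec)
        n = self.mesh.n_points
        fields = {}
        fields["Ca"] = np.full(n, float(eq["Ca"]))
        for b in self.spec.buffers:
            fields[b.name] = np.full(n, float(eq[b.name]))
        if self.spec.cam is not None:
            fields["cam_N"] = np.tile(eq["cam_N"], (n, 1))
            fields["cam_C"] = np.tile(eq["cam_C"], (n, 1))
        mem = ch.MembraneState.resting(self.params, self.spec.ca_rest)
        return FieldState(t=0.0, fields=fields, membrane=mem)

    # -- one split step ---------------------------------------------------
    def step(self, state: FieldState, stim: ch.StimulusCommand,
             dt: float | None = None) -> tuple[FieldState, dict[str, float], float]:
        """Advance one step; returns (new_state, currents, boundary_influx)."""
        dt = dt or self.dt
        if dt > self.config.dt * (1 + 1e-9):
            raise ValueError("dt exceeds configured maximum step")
        p = self.params
        mem = state.membrane
        # SK gating from the nanodomain probe (local [Ca2+] at the cluster)
        if self.sk_probe is not None:
            ca_sk = float(self.sk_probe.evaluate(state.fields["Ca"])[0])
        else:
            ca_sk = self.spec.ca_rest
        mem = replace(mem, s=ch.sk_update(mem.s, max(ca_sk, 0.0), p, dt))
        currents = ch.channel_currents(mem, p, sk_blocked=stim.sk_blocked)
        mem = ch.update_voltage(mem, p, stim, dt)

        # boundary Ca2+ influx (pA -> µM·µm³/ms), inward currents negative,
        # measured relative to the resting leak (see __init__) and floored
        # at zero: channels do not export Ca2+, and a transiently
        # sub-resting current must not drain the nanometre-scale patch nodes
        rate_n = max(-(currents["I_N_Ca"] - self._rest_n), 0.0) \
            * ch.PA_TO_UMOL_FLUX
        rate_v = max(-(currents["I_CaT"] + currents["I_CaL"]
                       - self._rest_v), 0.0) * ch.PA_TO_UMOL_FLUX
        b = np.zeros(self.mesh.n_points)
        pw = self.ops["patch_weights"]
        if "NMDAR" in pw:
            b += rate_n * pw["NMDAR"]
        if self.uniform_vgcc:
            b += rate_v * self.ops["uniform_weights"]
        elif "VGCC" in pw:
            b += rate_v * pw["VGCC"]
        influx = rate_n + rate_v  # µM·µm³/ms

        M = self.ops["M"]
        fields = state.fields
        new_fields = {}
        # implicit diffusion per mobile species; immobile species unchanged
        for name, arr in fields.items():
            D = self.ops["species_D"].get(name, 0.0)
            if D == 0.0:
                new_fields[name] = arr.copy()
                continue
            lu = self._factors[round(D, 12)]
            if arr.ndim == 1:
                rhs = M * arr
                if name == "Ca":
                    rhs = rhs + dt * b
                new_fields[name] = lu.solve(rhs)
            else:  # lobe marginals (n, 3) solve column-wise
                out = np.empty_like(arr)
                for k in range(arr.shape[1]):
                    out[:, k] = lu.solve(M * arr[:, k])
                new_fields[name] = out

        # local reactions (backward Euler, vectorised over nodes)
        Y0 = self.reactions.pack(new_fields, self.mesh.n_points)
        Y1 = self.reactions.step_be(Y0, dt, tol=self.config.newton_tol)
        reacted = self.reactions.unpack(Y1)
        for k, v in reacted.items():
            new_fields[k] = v

        return (FieldState(t=state.t + dt, fields=new_fields, membrane=mem),
                currents, influx * dt)

    # -- full protocol -----------------------------------------------------
    def run(self, events: Sequence[tuple[str, float]],
            sk_blocked: bool = False) -> SimOutput:
        cfg = self.config
        n_steps = int(round(cfg.t_end / self.dt))
        sample_every = max(1, int(round(cfg.output_dt / self.dt)))
        state = self.initial_state()
        M = self.ops["M"]
        vol = M.sum()
        snap_left = sorted(cfg.snapshot_times)

        ts, Vs, ss = [], [], []
        cur_keys = ["I_A", "I_N", "I_N_Ca", "I_CaT", "I_CaL", "I_SK", "I_L"]
        cur = {k: [] for k in cur_keys}
        glb: dict[str, list] = {"Ca": []}
        for b in self.spec.buffers:
            glb[b.name] = []
        has_cam = self.spec.cam is not None
        if has_cam:
            for k in ("CaM_fully_active", "CaM_N_full", "CaM_C_full"):
                glb[k] = []
        probes: dict[str, dict[str, list]] = {
            name: {"Ca": []} for name in self.readout_probes.names}
        if has_cam:
            for d in probes.values():
                for k in ("CaM_fully_active", "CaM_N_full", "CaM_C_full"):
                    d[k] = []
        tot_ca, influx_cum_l, extr_cum_l = [], [], []
        influx_cum = 0.0
        extr_cum = 0.0
        snapshots: dict[float, dict[str, np.ndarray]] = {}
        last_currents = ch.channel_currents(state.membrane, self.params,
                                            sk_blocked=sk_blocked)

        def sample():
            ts.append(state.t)
            Vs.append(state.membrane.V)
            ss.append(state.membrane.s)
            for k in cur_keys:
                cur[k].append(last_currents[k])
            ca = state.fields["Ca"]
            glb["Ca"].append(float(M @ ca / vol))
            for b in self.spec.buffers:
                glb[b.name].append(float(M @ state.fields[b.name] / vol))
            if has_cam:
                nN, nC = state.fields["cam_N"], state.fields["cam_C"]
                tot = self.spec.cam.total
                fa = nN[:, 2] * nC[:, 2] / tot
                glb["CaM_fully_active"].append(float(M @ fa / vol))
                glb["CaM_N_full"].append(float(M @ nN[:, 2] / vol))
                glb["CaM_C_full"].append(float(M @ nC[:, 2] / vol))
            for i, name in enumerate(self.readout_probes.names):
                probes[name]["Ca"].append(float(
                    self.readout_probes.evaluate(ca)[i]))
                if has_cam:
                    pN2 = float(self.readout_probes.evaluate(nN[:, 2])[i])
                    pC2 = float(self.readout_probes.evaluate(nC[:, 2])[i])
                    probes[name]["CaM_fully_active"].append(pN2 * pC2 / tot)
                    probes[name]["CaM_N_full"].append(pN2)
                    probes[name]["CaM_C_full"].append(pC2)
            tot_ca.append(self._total_ca(state))
            influx_cum_l.append(influx_cum)
            extr_cum_l.append(extr_cum)

        sample()
        gam = self.spec.extrusion.gamma_u
        basal = gam * self.spec.ca_rest if self.spec.basal_influx else 0.0
        for k in range(n_steps):
            t = state.t
            glu = sum(ch.glutamate_pulse(t, on) for kind, on in events
                      if kind == "EPSP")
            bap = sum(ch.bap_waveform(t, on, self.params) for kind, on in events
                      if kind == "bAP")
            stim = ch.StimulusCommand(glutamate=float(glu),
                                      bap_command=float(bap),
                                      sk_blocked=sk_blocked)
            extr_cum += self.dt * float(
                M @ (gam * state.fields["Ca"] - basal))
            state, last_currents, dinflux = self.step(state, stim)
            influx_cum += dinflux
            if snap_left and state.t >= snap_left[0] - 1e-9:
                snap_left.pop(0)
                snap = {"Ca": state.fields["Ca"].copy()}
                if has_cam:
                    nN, nC = state.fields["cam_N"], state.fields["cam_C"]
                    snap["CaM_fully_active"] = nN[:, 2] * nC[:, 2] / self.spec.cam.total
                snapshots[round(state.t, 6)] = snap
            if (k + 1) % sample_every == 0:
                sample()

        return SimOutput(
            t=np.array(ts), V=np.array(Vs), s=np.array(ss),
            currents={k: np.array(v) for k, v in cur.items()},
            global_avg={k: np.array(v) for k, v in glb.items()},
            probes={n: {k: np.array(v) for k, v in d.items()}
                    for n, d in probes.items()},
            total_ca=np.array(tot_ca), influx_cum=np.array(influx_cum_l),
            extrusion_cum=np.array(extr_cum_l), snapshots=snapshots,
            meta={"sk_blocked": sk_blocked, "events": list(events)})

    def _total_ca(self, state: FieldState) -> float:
        """Volume-integrated free + buffer-bound + CaM-bound Ca (µM·µm³)."""
        M = self.ops["M"]
        tot = state.fields["Ca"].copy()
        for b in self.spec.buffers:
            tot = tot + state.fields[b.name]
        if self.spec.cam is not None:
            nN, nC = state.fields["cam_N"], state.fields["cam_C"]
            tot = tot + nN[:, 1] + 2 * nN[:, 2] + nC[:, 1] + 2 * nC[:, 2]
        return float(M @ tot)


def step(state: FieldState, stim: ch.StimulusCommand, sim: Simulation,
         dt: float | None = None) -> FieldState:
    """Functional wrapper over :meth:`Simulation.step`."""
    new_state, _, _ = sim.step(state, stim, dt)
    return new_state


def run_protocol(protocol, condition, config, *,
                 extra_probes: dict[str, np.ndarray] | None = None,
                 mesh: Mesh | None = None) -> SimOutput:
    """Run a named stimulus protocol under a condition (see protocols module).

    ``config`` is a :class:`spinecam.config.ModelConfig`; ``mesh`` may be
    supplied to reuse a previously built mesh for the same condition.
    """
    geom = config.geometry
    clusters = condition.make_clusters(geom)
    if mesh is None:
        mesh = build_spine_mesh(geom, config.mesh_spec, clusters)
    spec = condition.make_chemistry(config.chemistry)
    params = condition.make_channels(config.channels)
    sim = Simulation(mesh, spec, params, config.solver,
                     sk_probe_nm=config.sk_probe_nm, probe_nm=config.probe_nm,
                     extra_probes=extra_probes)
    out = sim.run(protocol.events, sk_blocked=condition.sk_blocked)
    out.meta.update({"protocol": protocol.name,
                     "condition": condition.describe()})
    return out


# ---------------------------------------------------------------------------
# steady state with a point flux (validation against the screened source)
# ---------------------------------------------------------------------------

def solve_steady_state(mesh: Mesh, D_um2_s: float, gamma_s: float,
                       cluster_kind: str, total_rate: float) -> np.ndarray:
    """Steady diffusion + linear sink with a constant patch influx:
    solve (D K + gamma M) c = b.  ``total_rate`` in µM·µm³/ms."""
    K = _p1_stiffness(mesh)
    M = mesh.node_volumes
    D = D_um2_s * 1e-3
    gam = gamma_s * 1e-3
    idx = mesh.cluster_index(cluster_kind)
    b = total_rate * _patch_weight_vector(mesh, idx)
    A = (D * K + sp.diags(gam * M)).tocsc()
    return spsolve(A, b)
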