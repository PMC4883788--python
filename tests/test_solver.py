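"""Discrete operators, conservation, convergence, and output plumbing."""

from dataclasses import replace

import numpy as np
import pytest

from spinecam.chemistry import ChemistrySpec, ExtrusionSpec
from spinecam.config import ModelConfig
from spinecam.geometry import (ClusterPatch, MeshSpec, SpineGeometry,
                               build_spine_mesh, mesh_spec_for_level)
from spinecam.protocols import Condition, Protocol, make_protocol
from spinecam.solver import (Simulation, SolverConfig, assemble, run_protocol,
                             solve_steady_state)
from spinecam.channels import StimulusCommand


class TestAssembly:
    def test_stiffness_annihilates_constants(self, tiny_mesh):
        ops = assemble(tiny_mesh, ChemistrySpec())
        K = ops["K"]
        const = np.ones(tiny_mesh.n_points)
        assert np.abs(K @ const).max() < 1e-10
        # row sums vanish (discrete conservation)
        assert np.abs(np.asarray(K.sum(axis=1))).max() < 1e-10

    def test_patch_weights_normalised(self, tiny_mesh):
        ops = assemble(tiny_mesh, ChemistrySpec())
        for kind, w in ops["patch_weights"].items():
            assert w.sum() == pytest.approx(1.0, rel=1e-12)
            assert (w >= 0).all()
        assert ops["uniform_weights"].sum() == pytest.approx(1.0, rel=1e-12)

    def test_boundary_flux_integrates_to_total_rate(self, tiny_mesh):
        """The load vector delivers exactly the prescribed molar rate."""
        ops = assemble(tiny_mesh, ChemistrySpec())
        rate = 3.7  # µM·µm³/ms
        b = rate * ops["patch_weights"]["NMDAR"]
        assert b.sum() == pytest.approx(rate, rel=1e-9)

    def test_lumped_mass_equals_volume(self, tiny_mesh):
        ops = assemble(tiny_mesh, ChemistrySpec())
        assert ops["M"].sum() == pytest.approx(tiny_mesh.volume, rel=1e-12)


class TestPureDiffusion:
    def test_conservation_and_relaxation_to_uniform(self, tiny_mesh):
        """Zero-flux, zero-reaction diffusion: total moles constant to 1e-6
        relative; the field relaxes toward uniform."""
        spec = ChemistrySpec(buffers=(), extrusion=ExtrusionSpec(0.0),
                             basal_influx=False)
        sim = Simulation(tiny_mesh, spec, ModelConfig().channels,
                         SolverConfig(t_end=1.0))
        state = sim.initial_state()
        z = tiny_mesh.points[:, 2]
        state.fields["Ca"] = 0.5 + 0.4 * np.sign(z)  # step profile
        M = sim.ops["M"]
        total0 = float(M @ state.fields["Ca"])
        var0 = float(np.var(state.fields["Ca"]))
        stim = StimulusCommand()
        for _ in range(300):
            state, _, _ = sim.step(state, stim)
        total1 = float(M @ state.fields["Ca"])
        # graded 2 nm elements make the implicit solve ill-conditioned;
        # conservation holds to the stated 1e-6, not machine precision
        assert total1 == pytest.approx(total0, rel=1e-6)
        assert np.var(state.fields["Ca"]) < 0.3 * var0

    def test_step_beyond_configured_maximum_rejected(self, tiny_mesh):
        spec = ChemistrySpec(buffers=())
        sim = Simulation(tiny_mesh, spec, ModelConfig().channels,
                         SolverConfig(max_step_us=10.0))
        state = sim.initial_state()
        with pytest.raises(ValueError):
            sim.step(state, StimulusCommand(), dt=0.05)


class TestSteadyPointSource:
    def test_patch_size_insensitivity_at_20nm(self):
        """Nanodomain readouts at >= 20 nm depend weakly on the effective
        flux-patch diameter (sub-resolution size is not physical)."""
        geom = SpineGeometry(head_radius=0.5, neck_radius=0.0, neck_length=0.0)
        vals = {}
        for dia in (0.005, 0.010, 0.020):
            spec = MeshSpec(interior_max=0.08, interior_min=0.02,
                            near_max=0.012, near_min=0.0015,
                            refine_radius=0.06, grade_radius=0.3)
            cluster = ClusterPatch("NMDAR", theta=np.pi / 2, diameter=dia)
            mesh = build_spine_mesh(geom, spec, clusters=[cluster])
            c = solve_steady_state(mesh, 220.0, 5000.0, "NMDAR", 1.0)
            center = cluster.center(geom)
            p = center + 0.020 * (-center / np.linalg.norm(center))
            verts, w = mesh.interpolation_weights(p)
            vals[dia] = float(c[verts] @ w)
        spread = max(vals.values()) / min(vals.values()) - 1
        assert spread < 0.20, vals


class TestProtocolRuns:
    def test_no_stimulus_stays_at_rest(self, tiny_config):
        cfg = tiny_config.with_(solver=SolverConfig(t_end=5.0))
        out = run_protocol(Protocol("rest", ()), Condition(), cfg)
        # V parks within the ~0.01 mV window-current offset of rest;
        # Ca2+ stays at the resting value (leak folded into basal balance)
        assert np.abs(out.V - out.V[0]).max() < 0.02
        assert np.abs(out.global_avg["Ca"] - out.global_avg["Ca"][0]).max() < 1e-5
        assert np.all(np.diff(out.t) > 0)  # monotone time axis

    def test_nanodomain_exceeds_global_during_influx(self, epsp_run):
        out = epsp_run
        active = np.abs(out.currents["I_N_Ca"]) > 1e-3
        assert np.all(out.probes["NMDAR"]["Ca"][active]
                      >= out.global_avg["Ca"][active] - 1e-9)

    def test_step_halving_changes_peak_below_half_percent(self, tiny_config):
        peaks = {}
        for us in (10.0, 5.0):
            cfg = tiny_config.with_(solver=SolverConfig(max_step_us=us,
                                                        t_end=8.0))
            out = run_protocol(make_protocol("EPSP"), Condition(), cfg)
            peaks[us] = out.global_avg["Ca"].max()
        assert abs(peaks[10.0] / peaks[5.0] - 1) < 0.005

    def test_mesh_refinement_stability(self, tiny_config):
        """Global peak within 5 %, 20 nm nanodomain within 10 %, between the
        two coarsest mesh levels."""
        peaks = {}
        for level in ("tiny", "coarse"):
            cfg = ModelConfig(mesh_level=level,
                              solver=SolverConfig(t_end=12.0))
            out = run_protocol(make_protocol("EPSP"), Condition(), cfg)
            peaks[level] = (out.global_avg["Ca"].max(),
                            out.probes["NMDAR"]["Ca"].max())
        assert abs(peaks["tiny"][0] / peaks["coarse"][0] - 1) < 0.05
        assert abs(peaks["tiny"][1] / peaks["coarse"][1] - 1) < 0.10

    def test_sk_probe_distance_sensitivity(self, tiny_config):
        """SK activation is robust for gating-probe distances 10-50 nm when
        the cluster sits 50 nm from the NMDAR source."""
        cfg = tiny_config.with_(solver=SolverConfig(t_end=15.0))
        s_peaks = {}
        for d in (10.0, 50.0):
            out = run_protocol(make_protocol("EPSP"), Condition(),
                               cfg.with_(sk_probe_nm=d))
            s_peaks[d] = out.s.max()
        assert min(s_peaks.values()) > 0.5
        assert s_peaks[10.0] >= s_peaks[50.0]


class TestCamLobeKinetics:
    def test_c_lobe_integrates_n_lobe_tracks(self, cam_blockade_runs):
        """After EPSP-2bAPs the fully-occupied C lobe decays more slowly
        than the fully-occupied N lobe (temporal integration vs tracking)."""
        out = cam_blockade_runs[("EPSP-2bAPs", False)]

        def half_decay(trace, t):
            k = int(np.argmax(trace))
            target = trace[0] + 0.5 * (trace[k] - trace[0])
            below = np.nonzero(trace[k:] <= target)[0]
            return (t[k + below[0]] - t[k]) if len(below) else np.inf

        t_c = half_decay(out.global_avg["CaM_C_full"], out.t)
        t_n = half_decay(out.global_avg["CaM_N_full"], out.t)
        assert t_c > t_n

    def test_cam_pointwise_total_conserved(self, cam_blockade_runs):
        out = cam_blockade_runs[("EPSP-2bAPs", False)]
        # the three summaries can never exceed total CaM
        for k in ("CaM_fully_active", "CaM_N_full", "CaM_C_full"):
            assert out.global_avg[k].max() <= 100.0 + 1e-6


class TestOutputs:
    def test_csv_and_hdf5_round_trip(self, epsp_run, tmp_path):
        import h5py
        import pandas as pd
        epsp_run.save_csv(str(tmp_path / "o.csv"))
        epsp_run.save_hdf5(str(tmp_path / "o.h5"))
        df = pd.read_csv(tmp_path / "o.csv")
        assert len(df) == len(epsp_run.t)
        np.testing.assert_allclose(df["V"], epsp_run.V, rtol=1e-9)
        with h5py.File(tmp_path / "o.h5") as f:
            np.testing.assert_allclose(f["global"]["Ca"][:],
                                       epsp_run.global_avg["Ca"])

    def test_units_annotated(self, epsp_run):
        assert epsp_run.units["t"] == "ms"
        assert epsp_run.units["V"] == "mV"
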