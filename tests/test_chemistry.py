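"""Reaction network: binding ratios, equilibria, cooperativity, conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spinecam.chemistry import (CALBINDIN, EFB, BufferSpec, CaMSpec,
                                ChemistrySpec, ExtrusionSpec, ReactionSystem,
                                binding_ratio, cam_from_marginals,
                                cam_summaries, equilibrium_init,
                                lobe_equilibrium, marginals_from_cam,
                                reaction_rhs)

CAM = CaMSpec()
SPEC = ChemistrySpec(cam=CAM)


class TestBindingRatio:
    def test_efb_kappa_20_at_rest(self):
        assert binding_ratio(EFB.total, EFB.K_d, 0.05,
                             EFB.sites) == pytest.approx(20.0, rel=0.01)

    def test_calbindin_kappa_250_at_rest(self):
        assert binding_ratio(CALBINDIN.total, CALBINDIN.K_d, 0.05,
                             CALBINDIN.sites) == pytest.approx(250.0, rel=0.01)

    def test_zero_buffer(self):
        assert binding_ratio(0.0, 1.0, 0.05) == 0.0

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            binding_ratio(10.0, 0.0, 0.05)


class TestEquilibriumInit:
    def test_zero_calcium_all_free(self):
        eq = equilibrium_init(0.0, SPEC)
        for b in SPEC.buffers:
            assert eq[b.name] == 0.0
        assert eq["cam_N"][0] == pytest.approx(CAM.total)
        assert eq["cam_C"][0] == pytest.approx(CAM.total)

    def test_reaction_rhs_vanishes_at_equilibrium(self):
        eq = equilibrium_init(0.05, SPEC)
        cam9 = cam_from_marginals(eq["cam_N"], eq["cam_C"], CAM.total)
        dca, dbuf, dcam = reaction_rhs(
            eq["Ca"], {b.name: eq[b.name] for b in SPEC.buffers}, cam9, SPEC)
        assert abs(float(dca)) < 1e-9
        for v in dbuf.values():
            assert abs(float(v)) < 1e-9
        assert np.abs(dcam).max() < 1e-9

    def test_single_site_bound_fraction(self):
        ca = 0.4
        eq = equilibrium_init(ca, ChemistrySpec(buffers=(EFB,)))
        frac = eq["EFB"] / EFB.site_total
        assert frac == pytest.approx(ca / (ca + EFB.K_d), rel=1e-9)


class TestReactionRhs:
    def test_mass_action_scaling(self):
        """Doubling Ca and free buffer quadruples the forward binding rate."""
        b = BufferSpec("b", total=100.0, k_on=1e8, k_off=0.0,
                       diffusivity=0.0)
        spec = ChemistrySpec(buffers=(b,), extrusion=ExtrusionSpec(0.0),
                             basal_influx=False)
        r1, _, _ = reaction_rhs(np.array(0.1), {"b": np.array(0.0)}, None, spec)
        b2 = BufferSpec("b", total=200.0, k_on=1e8, k_off=0.0, diffusivity=0.0)
        spec2 = ChemistrySpec(buffers=(b2,), extrusion=ExtrusionSpec(0.0),
                              basal_influx=False)
        r2, _, _ = reaction_rhs(np.array(0.2), {"b": np.array(0.0)}, None, spec2)
        assert float(r2) == pytest.approx(4 * float(r1), rel=1e-12)

    def test_cam_network_closed(self):
        rng = np.random.default_rng(1)
        cam9 = np.abs(rng.normal(5, 2, (3, 3)))
        _, _, dcam = reaction_rhs(np.array(0.5), {}, cam9,
                                  ChemistrySpec(buffers=(), cam=CAM))
        assert dcam.sum() == pytest.approx(0.0, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            reaction_rhs(np.array(-0.1), {}, None,
                         ChemistrySpec(buffers=()))


class TestCamSummaries:
    def test_all_fully_active(self):
        cam = np.zeros((3, 3))
        cam[2, 2] = 100.0
        s = cam_summaries(cam)
        assert s["fully_active"] == s["N_full"] == s["C_full"] == 100.0

    def test_c_lobe_only(self):
        cam = np.zeros((3, 3))
        cam[0, 2] = 100.0
        s = cam_summaries(cam)
        assert s["fully_active"] == 0.0
        assert s["N_full"] == 0.0
        assert s["C_full"] == 100.0

    def test_uniform_distribution(self):
        cam = np.full((3, 3), 10.0)  # 90 µM uniformly over 9 states
        s = cam_summaries(cam)
        assert s["N_full"] == s["C_full"] == 30.0
        assert s["fully_active"] == 10.0

    def test_marginal_roundtrip(self):
        nN = np.array([50.0, 30.0, 20.0])
        nC = np.array([10.0, 45.0, 45.0])
        cam = cam_from_marginals(nN, nC, 100.0)
        mN, mC = marginals_from_cam(cam)
        np.testing.assert_allclose(mN, nN)
        np.testing.assert_allclose(mC, nC)
        assert cam.sum() == pytest.approx(100.0)


class TestCooperativity:
    def test_r_state_affinity_constraint(self):
        with pytest.raises(ValueError):
            CaMSpec(kon_RN=1e6, koff_RN=1e6)  # R weaker than T

    def test_lobe_hill_slope_exceeds_one(self):
        """The T->R switch makes full occupancy steeper than independent
        sites: Hill coefficient from the 10-90 % span exceeds 1."""
        rates = CAM.lobe_rates("C")

        def frac_full(ca):
            return lobe_equilibrium(ca, *rates)[2]

        grid = np.geomspace(1e-3, 1e3, 4000)
        occ = np.array([frac_full(c) for c in grid])
        ca10 = grid[np.searchsorted(occ, 0.1)]
        ca90 = grid[np.searchsorted(occ, 0.9)]
        n_hill = np.log(81) / np.log(ca90 / ca10)
        assert n_hill > 1.05


class TestReactionSystem:
    def _spec(self):
        return ChemistrySpec(cam=CAM, extrusion=ExtrusionSpec(0.0),
                             basal_influx=False)

    def test_backward_euler_conserves_linear_invariants(self):
        spec = self._spec()
        rs = ReactionSystem(spec)
        rng = np.random.default_rng(7)
        Y = np.abs(rng.normal(1.0, 0.5, (500, rs.m)))
        Y[:, 0] *= 5

        def total_ca(Y):
            t = Y[:, 0].copy()
            t += Y[:, 1] + Y[:, 2]
            t += Y[:, 3] + 2 * Y[:, 4] + Y[:, 5] + 2 * Y[:, 6]
            return t

        Y1 = Y.copy()
        for _ in range(20):
            Y1 = rs.step_be(Y1, 0.01)
        np.testing.assert_allclose(total_ca(Y1), total_ca(Y), rtol=1e-12)

    def test_agrees_with_reference_integrator(self):
        """The vectorised Newton stepper matches scipy's BDF on the public
        9-state network (also validates the lobe-marginal factorisation)."""
        spec = self._spec()
        rs = ReactionSystem(spec)
        eq = equilibrium_init(0.05, spec)
        Y0 = np.empty((1, rs.m))
        Y0[0, 0] = 2.0  # perturbed free Ca
        Y0[0, 1] = float(eq["EFB"])
        Y0[0, 2] = float(eq["calbindin"])
        Y0[0, 3:5] = eq["cam_N"][1:]
        Y0[0, 5:7] = eq["cam_C"][1:]

        # reference: integrate the full 9-state network independently
        cam9_0 = cam_from_marginals(eq["cam_N"], eq["cam_C"], CAM.total)

        def rhs(t, y):
            ca = y[0]
            bufs = {"EFB": y[1], "calbindin": y[2]}
            cam9 = y[3:].reshape(3, 3)
            dca, dbuf, dcam = reaction_rhs(ca, bufs, cam9, spec)
            return np.concatenate([[float(dca), float(dbuf["EFB"]),
                                    float(dbuf["calbindin"])],
                                   dcam.ravel()])

        y0 = np.concatenate([[2.0, float(eq["EFB"]), float(eq["calbindin"])],
                             cam9_0.ravel()])
        sol = solve_ivp(rhs, (0.0, 1.0), y0, method="BDF", rtol=1e-10,
                        atol=1e-12)
        Y = Y0.copy()
        for _ in range(100):
            Y = rs.step_be(Y, 0.01)
        assert Y[0, 0] == pytest.approx(sol.y[0, -1], rel=2e-3)
        cam9_end = sol.y[3:, -1].reshape(3, 3)
        assert Y[0, 4] == pytest.approx(cam9_end.sum(axis=1)[2], rel=5e-3)


class TestSpecValidation:
    def test_fixed_buffer_zero_diffusivity(self):
        assert EFB.diffusivity == 0.0

    def test_unknown_buffer_set(self):
        with pytest.raises(ValueError):
            ChemistrySpec().with_buffers("EGTA")

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            ExtrusionSpec(-1.0)
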