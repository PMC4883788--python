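"""Ca2+ reaction network: buffers, cooperative calmodulin, extrusion.

Species
-------
* free Ca2+;
* an endogenous fixed buffer (EFB, immobile, resting binding ratio 20);
* a mobile buffer (default 100 µM calbindin, binding ratio ~250; an
  indicator dye for calibration runs is just another mobile buffer);
* calmodulin (CaM): two lobes (N and C), each with two Ca2+ sites binding
  cooperatively — the first site binds in a low-affinity "T" state and the
  remaining site then switches to the high-affinity "R" state.  The full
  molecule therefore has 9 occupancy states (N-lobe 0/1/2 x C-lobe 0/1/2).
* extrusion: a single first-order volumetric sink, -gamma·[Ca2+], balanced
  at rest by a constant basal influx so the resting state is a true steady
  state.

Because the two lobes are kinetically independent and every CaM species
shares one diffusivity, the 9-state joint distribution remains an exact
product of the two 3-state lobe marginals; the time stepper integrates the
marginals and the 9-state vector is reconstructed on demand.

Public rate units follow the field convention (k_on in M^-1 s^-1, k_off in
s^-1, diffusivities in µm^2 s^-1, concentrations in µM); internal
computation uses µM and ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BufferSpec",
    "CaMSpec",
    "ExtrusionSpec",
    "ChemistrySpec",
    "EFB",
    "CALBINDIN",
    "INDICATOR_DYE",
    "binding_ratio",
    "reaction_rhs",
    "equilibrium_init",
    "cam_summaries",
    "cam_from_marginals",
    "marginals_from_cam",
    "lobe_equilibrium",
    "ReactionSystem",
]

KON_TO_INTERNAL = 1e-9   # M^-1 s^-1 -> µM^-1 ms^-1
KOFF_TO_INTERNAL = 1e-3  # s^-1 -> ms^-1


@dataclass(frozen=True)
class BufferSpec:
    """A Ca2+ buffer with ``sites`` independent, identical binding sites."""

    name: str
    total: float          # µM (molecules)
    k_on: float           # M^-1 s^-1 (per site)
    k_off: float          # s^-1
    diffusivity: float    # µm^2 s^-1 (0 => fixed buffer)
    sites: int = 1

    def __post_init__(self) -> None:
        if min(self.total, self.k_on, self.k_off) < 0 or self.sites < 1:
            raise ValueError("buffer rates/concentrations must be >= 0, sites >= 1")
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")

    @property
    def K_d(self) -> float:
        """Dissociation constant, µM."""
        return self.k_off / self.k_on * 1e6

    @property
    def site_total(self) -> float:
        """Total site concentration, µM."""
        return self.sites * self.total

    def bound_at(self, ca: float) -> float:
        """Equilibrium bound-site concentration at free Ca ``ca`` (µM)."""
        return self.site_total * ca / (ca + self.K_d)


#: endogenous fixed buffer: fast, low affinity (K_d = 15 µM), binding
#: ratio 20 at 50 nM resting Ca2+
EFB = BufferSpec("EFB", total=302.0, k_on=5e8, k_off=7500.0, diffusivity=0.0)
#: 100 µM calbindin (4 sites), binding ratio ~250 at rest, D = 20 µm^2/s
CALBINDIN = BufferSpec("calbindin", total=100.0, k_on=7.5e7, k_off=112.4,
                       diffusivity=20.0, sites=4)
#: high-affinity Ca2+ indicator for synthetic imaging runs (K_d = 0.2 µM)
INDICATOR_DYE = BufferSpec("dye", total=100.0, k_on=5e8, k_off=100.0,
                           diffusivity=50.0)


@dataclass(frozen=True)
class CaMSpec:
    """Cooperative two-lobe calmodulin.

    Rates follow the cooperative binding scheme of the Faas et al.
    measurements: the C lobe is high-affinity/slow, the N lobe
    low-affinity/fast.  First binding uses the T-state rates (statistical
    factor 2 on the on-rate), the second site then switches to the R state
    (factor 2 on the final off-rate).
    """

    total: float = 100.0         # µM
    diffusivity: float = 20.0    # µm^2 s^-1, all 9 states
    # N lobe (fast, low affinity)
    kon_TN: float = 7.7e8
    koff_TN: float = 1.6e5
    kon_RN: float = 3.2e10
    koff_RN: float = 2.2e4
    # C lobe (slow, high affinity); the T-state off-rate is set so that
    # 100 µM CaM contributes an incremental binding ratio of ~35 at rest
    kon_TC: float = 8.4e7
    koff_TC: float = 495.0
    kon_RC: float = 2.5e7
    koff_RC: float = 6.5

    def __post_init__(self) -> None:
        rates = (self.kon_TN, self.koff_TN, self.kon_RN, self.koff_RN,
                 self.kon_TC, self.koff_TC, self.kon_RC, self.koff_RC)
        if min(rates) <= 0:
            raise ValueError("all CaM rates must be > 0")
        if self.K_RN > self.K_TN or self.K_RC > self.K_TC:
            raise ValueError("cooperativity requires R-state affinity >= T-state")

    @property
    def K_TN(self) -> float:
        return self.koff_TN / self.kon_TN * 1e6

    @property
    def K_RN(self) -> float:
        return self.koff_RN / self.kon_RN * 1e6

    @property
    def K_TC(self) -> float:
        return self.koff_TC / self.kon_TC * 1e6

    @property
    def K_RC(self) -> float:
        return self.koff_RC / self.kon_RC * 1e6

    def lobe_rates(self, lobe: str) -> tuple[float, float, float, float]:
        """(kon_T, koff_T, kon_R, koff_R) in internal units (µM, ms)."""
        if lobe == "N":
            r = (self.kon_TN, self.koff_TN, self.kon_RN, self.koff_RN)
        elif lobe == "C":
            r = (self.kon_TC, self.koff_TC, self.kon_RC, self.koff_RC)
        else:
            raise ValueError("lobe must be 'N' or 'C'")
        return (r[0] * KON_TO_INTERNAL, r[1] * KOFF_TO_INTERNAL,
                r[2] * KON_TO_INTERNAL, r[3] * KOFF_TO_INTERNAL)


@dataclass(frozen=True)
class ExtrusionSpec:
    """Linear volumetric clearance (pumps/exchangers/uptake lumped)."""

    gamma: float = 5000.0  # s^-1

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    @property
    def gamma_u(self) -> float:
        return self.gamma * 1e-3  # ms^-1


@dataclass(frozen=True)
class ChemistrySpec:
    """The full reaction set for one simulation condition."""

    buffers: tuple[BufferSpec, ...] = (EFB, CALBINDIN)
    cam: CaMSpec | None = None
    extrusion: ExtrusionSpec = field(default_factory=ExtrusionSpec)
    ca_rest: float = 0.05          # µM resting free Ca2+
    ca_diffusivity: float = 220.0  # µm^2 s^-1
    basal_influx: bool = True      # balance extrusion at rest

    def with_buffers(self, names: str) -> "ChemistrySpec":
        """Condition shorthand: 'none', 'EFB' or 'EFB+calbindin'."""
        table = {"none": (), "EFB": (EFB,), "EFB+calbindin": (EFB, CALBINDIN)}
        try:
            return replace(self, buffers=table[names])
        except KeyError:
            raise ValueError(f"unknown buffer set {names!r}; valid: {sorted(table)}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def binding_ratio(B_total: float, K_d: float, ca: float, sites: int = 1) -> float:
    """Incremental Ca2+ binding ratio kappa = sites·B·K_d/(K_d + Ca)^2."""
    if K_d <= 0:
        raise ValueError("K_d must be > 0")
    return sites * B_total * K_d / (K_d + ca) ** 2


def lobe_equilibrium(ca: float, kon_T: float, koff_T: float, kon_R: float,
                     koff_R: float, total: float = 1.0) -> np.ndarray:
    """Equilibrium occupancy [p0, p1, p2]·total of one cooperative lobe."""
    w1 = 2.0 * kon_T * ca / koff_T if koff_T > 0 else 0.0
    w2 = w1 * (kon_R * ca / (2.0 * koff_R)) if koff_R > 0 else 0.0
    z = 1.0 + w1 + w2
    return total * np.array([1.0, w1, w2]) / z


def cam_from_marginals(nN: np.ndarray, nC: np.ndarray, total: float) -> np.ndarray:
    """9-state CaM vector (..., 3, 3) from lobe marginal concentrations.

    Valid because the lobes are kinetically independent and co-diffuse, so
    the joint distribution stays a product for all time.
    """
    nN = np.asarray(nN, float)
    nC = np.asarray(nC, float)
    return nN[..., :, None] * nC[..., None, :] / total


def marginals_from_cam(cam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lobe marginal concentrations (N, C) from a 9-state vector."""
    cam = np.asarray(cam, float)
    return cam.sum(axis=-1), cam.sum(axis=-2)


def cam_summaries(cam: np.ndarray) -> dict[str, np.ndarray]:
    """Readout species of the 9-state vector (..., 3, 3):

    * ``fully_active`` — all four sites occupied, state (2, 2);
    * ``N_full`` — fully occupied N lobe, sum of states (2, ·);
    * ``C_full`` — fully occupied C lobe, sum of states (·, 2).
    """
    cam = np.asarray(cam, float)
    return {
        "fully_active": cam[..., 2, 2],
        "N_full": cam[..., 2, :].sum(axis=-1),
        "C_full": cam[..., :, 2].sum(axis=-1),
    }


def _lobe_rhs(ca, n1, n2, total, rates):
    """(dn1, dn2, ca_uptake) for one lobe; all internal units."""
    kon_T, koff_T, kon_R, koff_R = rates
    n0 = total - n1 - n2
    f01 = 2.0 * kon_T * ca * n0
    f10 = koff_T * n1
    f12 = kon_R * ca * n1
    f21 = 2.0 * koff_R * n2
    dn1 = f01 - f10 - f12 + f21
    dn2 = f12 - f21
    return dn1, dn2, (f01 - f10) + (f12 - f21)


def reaction_rhs(ca, buffers_bound: dict[str, np.ndarray], cam: np.ndarray | None,
                 spec: ChemistrySpec) -> tuple[np.ndarray, dict[str, np.ndarray],
                                               np.ndarray | None]:
    """Mass-action rates (µM/ms) for every species at given concentrations.

    ``buffers_bound`` maps buffer name -> bound-site concentration; ``cam``
    is the 9-state vector (..., 3, 3) or None.  Returns (dCa, dBound, dCaM).
    Raises on negative inputs.  The 9-state CaM rates sum to zero exactly
    (CaM is conserved by the reaction network).
    """
    ca = np.asarray(ca, float)
    if np.any(ca < 0):
        raise ValueError("negative Ca2+ concentration")
    dca = np.zeros_like(ca)
    dbuf: dict[str, np.ndarray] = {}
    for b in spec.buffers:
        bound = np.asarray(buffers_bound[b.name], float)
        if np.any(bound < 0):
            raise ValueError(f"negative bound concentration for {b.name}")
        kon = b.k_on * KON_TO_INTERNAL
        koff = b.k_off * KOFF_TO_INTERNAL
        rate = kon * ca * (b.site_total - bound) - koff * bound
        dbuf[b.name] = rate
        dca = dca - rate
    dcam = None
    if cam is not None:
        if spec.cam is None:
            raise ValueError("cam vector supplied but spec.cam is None")
        cam = np.asarray(cam, float)
        if np.any(cam < -1e-12):
            raise ValueError("negative CaM state concentration")
        rN = spec.cam.lobe_rates("N")
        rC = spec.cam.lobe_rates("C")
        dcam = np.zeros_like(cam)
        # N-lobe transitions act on the first occupancy index, C on the second
        for rates, axis in ((rN, 0), (rC, 1)):
            kon_T, koff_T, kon_R, koff_R = rates
            ax = -2 if axis == 0 else -1
            c0 = np.take(cam, 0, axis=ax)
            c1 = np.take(cam, 1, axis=ax)
            c2 = np.take(cam, 2, axis=ax)
            f01 = 2.0 * kon_T * ca[..., None] * c0
            f10 = koff_T * c1
            f12 = kon_R * ca[..., None] * c1
            f21 = 2.0 * koff_R * c2
            d0 = f10 - f01
            d1 = f01 - f10 - f12 + f21
            d2 = f12 - f21
            if axis == 0:
                dcam[..., 0, :] += d0
                dcam[..., 1, :] += d1
                dcam[..., 2, :] += d2
            else:
                dcam[..., :, 0] += d0
                dcam[..., :, 1] += d1
                dcam[..., :, 2] += d2
            dca = dca - ((f01 - f10) + (f12 - f21)).sum(axis=-1)
    gam = spec.extrusion.gamma_u
    dca = dca - gam * ca
    if spec.basal_influx:
        dca = dca + gam * spec.ca_rest
    return dca, dbuf, dcam


def equilibrium_init(ca_rest: float, spec: ChemistrySpec) -> dict[str, np.ndarray]:
    """Resting steady state of the reaction network at clamped free Ca.

    Closed form: independent-site buffers fill to Ca/(Ca+K_d); each CaM lobe
    follows the two-step cooperative equilibrium.  With the basal influx
    balancing extrusion, ``reaction_rhs`` vanishes at the result.
    """
    if ca_rest < 0:
        raise ValueError("resting Ca2+ must be >= 0")
    out: dict[str, np.ndarray] = {"Ca": np.asarray(float(ca_rest))}
    for b in spec.buffers:
        out[b.name] = np.asarray(b.bound_at(ca_rest))
    if spec.cam is not None:
        nN = lobe_equilibrium(ca_rest, *spec.cam.lobe_rates("N"), total=spec.cam.total)
        nC = lobe_equilibrium(ca_rest, *spec.cam.lobe_rates("C"), total=spec.cam.total)
        out["cam_N"] = nN
        out["cam_C"] = nC
    return out


# ---------------------------------------------------------------------------
# vectorised implicit reaction stepping (used by the PDE solver)
# ---------------------------------------------------------------------------

class ReactionSystem:
    """Backward-Euler integrator for the local reaction network, vectorised
    over mesh nodes.

    State layout per node: ``[Ca, bound_1..bound_nb, n1, n2, c1, c2]`` where
    the CaM entries are the lobe-marginal concentrations (present only when
    the spec includes CaM).  Backward Euler preserves the network's linear
    invariants (total Ca, total buffer, total CaM) to Newton tolerance.
    """

    def __init__(self, spec: ChemistrySpec):
        self.spec = spec
        self.nb = len(spec.buffers)
        self.has_cam = spec.cam is not None
        self.m = 1 + self.nb + (4 if self.has_cam else 0)
        self.kon = np.array([b.k_on * KON_TO_INTERNAL for b in spec.buffers])
        self.koff = np.array([b.k_off * KOFF_TO_INTERNAL for b in spec.buffers])
        self.stot = np.array([b.site_total for b in spec.buffers])
        if self.has_cam:
            self.rN = spec.cam.lobe_rates("N")
            self.rC = spec.cam.lobe_rates("C")
            self.cam_total = spec.cam.total
        self.gamma = spec.extrusion.gamma_u
        self.basal = self.gamma * spec.ca_rest if spec.basal_influx else 0.0

    # -- state helpers ----------------------------------------------------
    def pack(self, fields: dict[str, np.ndarray], n_nodes: int) -> np.ndarray:
        Y = np.empty((n_nodes, self.m))
        Y[:, 0] = fields["Ca"]
        for i, b in enumerate(self.spec.buffers):
            Y[:, 1 + i] = fields[b.name]
        if self.has_cam:
            j = 1 + self.nb
            Y[:, j] = fields["cam_N"][..., 1]
            Y[:, j + 1] = fields["cam_N"][..., 2]
            Y[:, j + 2] = fields["cam_C"][..., 1]
            Y[:, j + 3] = fields["cam_C"][..., 2]
        return Y

    def unpack(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        fields = {"Ca": Y[:, 0]}
        for i, b in enumerate(self.spec.buffers):
            fields[b.name] = Y[:, 1 + i]
        if self.has_cam:
            j = 1 + self.nb
            n = len(Y)
            nN = np.empty((n, 3))
            nC = np.empty((n, 3))
            nN[:, 1], nN[:, 2] = Y[:, j], Y[:, j + 1]
            nN[:, 0] = self.cam_total - nN[:, 1] - nN[:, 2]
            nC[:, 1], nC[:, 2] = Y[:, j + 2], Y[:, j + 3]
            nC[:, 0] = self.cam_total - nC[:, 1] - nC[:, 2]
            fields["cam_N"] = nN
            fields["cam_C"] = nC
        return fields

    # -- rhs / jacobian ---------------------------------------------------
    def rhs(self, Y: np.ndarray) -> np.ndarray:
        ca = Y[:, 0]
        R = np.zeros_like(Y)
        dca = -self.gamma * ca + self.basal
        for i in range(self.nb):
            b = Y[:, 1 + i]
            rate = self.kon[i] * ca * (self.stot[i] - b) - self.koff[i] * b
            R[:, 1 + i] = rate
            dca = dca - rate
        if self.has_cam:
            j = 1 + self.nb
            for k, rates in ((0, self.rN), (2, self.rC)):
                d1, d2, up = _lobe_rhs(ca, Y[:, j + k], Y[:, j + k + 1],
                                       self.cam_total, rates)
                R[:, j + k] = d1
                R[:, j + k + 1] = d2
                dca = dca - up
        R[:, 0] = dca
        return R

    def jac(self, Y: np.ndarray) -> np.ndarray:
        n = len(Y)
        ca = Y[:, 0]
        J = np.zeros((n, self.m, self.m))
        J[:, 0, 0] = -self.gamma
        for i in range(self.nb):
            b = Y[:, 1 + i]
            dr_dca = self.kon[i] * (self.stot[i] - b)
            dr_db = -self.kon[i] * ca - self.koff[i]
            J[:, 1 + i, 0] = dr_dca
            J[:, 1 + i, 1 + i] = dr_db
            J[:, 0, 0] -= dr_dca
            J[:, 0, 1 + i] = -dr_db
        if self.has_cam:
            j = 1 + self.nb
            for k, rates in ((0, self.rN), (2, self.rC)):
                kon_T, koff_T, kon_R, koff_R = rates
                i1, i2 = j + k, j + k + 1
                n1, n2 = Y[:, i1], Y[:, i2]
                n0 = self.cam_total - n1 - n2
                # d(dn1)/d.
                a_ca = 2.0 * kon_T * n0 - kon_R * n1
                a_n1 = -2.0 * kon_T * ca - koff_T - kon_R * ca
                a_n2 = -2.0 * kon_T * ca + 2.0 * koff_R
                # d(dn2)/d.
                b_ca = kon_R * n1
                b_n1 = kon_R * ca
                b_n2 = -2.0 * koff_R
                # d(uptake)/d.
                u_ca = 2.0 * kon_T * n0 + kon_R * n1
                u_n1 = -2.0 * kon_T * ca - koff_T + kon_R * ca
                u_n2 = -2.0 * kon_T * ca - 2.0 * koff_R
                J[:, i1, 0] = a_ca
                J[:, i1, i1] = a_n1
                J[:, i1, i2] = a_n2
                J[:, i2, 0] = b_ca
                J[:, i2, i1] = b_n1
                J[:, i2, i2] = b_n2
                J[:, 0, 0] -= u_ca
                J[:, 0, i1] -= u_n1
                J[:, 0, i2] -= u_n2
        return J

    # -- implicit step ----------------------------------------------------
    def step_be(self, Y0: np.ndarray, dt: float, tol: float = 1e-10,
                max_iter: int = 12, _depth: int = 0) -> np.ndarray:
        """One backward-Euler step with damped Newton; splits the step on
        convergence failure (raises after 8 consecutive halvings)."""
        Y = Y0.copy()
        eye = np.eye(self.m)
        converged = False
        for _ in range(max_iter):
            F = Y - Y0 - dt * self.rhs(Y)
            A = eye[None, :, :] - dt * self.jac(Y)
            delta = np.linalg.solve(A, -F[..., None])[..., 0]
            Y = Y + delta
            err = np.abs(delta) / np.maximum(np.abs(Y), 1e-3)
            if err.max() < tol:
                converged = True
                break
        if not converged or np.any(Y[:, 0] < -1e-6):
            if _depth >= 8:
                raise RuntimeError("reaction Newton failed to converge")
            half = self.step_be(Y0, dt / 2.0, tol, max_iter, _depth + 1)
            return self.step_be(half, dt / 2.0, tol, max_iter, _depth + 1)
        return Y
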