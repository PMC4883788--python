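"""Spine membrane potential and ion-channel gating.

The spine is one isopotential electrical compartment.  Synaptic AMPA and
NMDA receptors are driven by a cleft-glutamate pulse through two-state
binding kinetics; the NMDAR open probability carries a voltage-dependent
Mg2+ unblock.  T-type (LVA) and L-type (HVA) voltage-gated Ca2+ channels use
Boltzmann steady states with first-order relaxation.  The SK channel is a
Ca2+-gated K+ conductance driven by a Hill function of the Ca2+
concentration at a probe just inside its cluster, with a slow (~6 ms)
activation time constant — the source of the "priming" negative feedback.

A back-propagating action potential (bAP) is injected through a neck
coupling conductance that pulls the spine toward a commanded double
exponential waveform; it is not a hard voltage clamp, so the SK current can
repolarise the spine during bAPs.

Units: mV, ms, pA, pS, µM (mM only for glutamate / external ions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelParams",
    "MembraneState",
    "StimulusCommand",
    "glutamate_pulse",
    "bap_waveform",
    "receptor_gating",
    "mg_unblock",
    "vgcc_gates",
    "sk_update",
    "sk_steady_state",
    "channel_currents",
    "update_voltage",
    "current_to_flux",
    "calibrate_bap_gain",
    "FARADAY",
]

FARADAY = 96485.33212  # C/mol
#: pA -> µM·µm³/ms of Ca2+ delivered (divalent): 1e-15 C/ms / (2F) / 1e-21 mol/µM·µm³
PA_TO_UMOL_FLUX = 1e6 / (2.0 * FARADAY)


@dataclass(frozen=True)
class ChannelParams:
    """Channel densities and kinetic constants.

    Cluster conductances are the printed totals.  Kinetic constants not in
    print are reconstructions, kept here (not hard-coded elsewhere) so that
    every assumption is a visible, overridable configuration value.
    """

    # cluster conductances, pS
    g_A: float = 60.0
    g_N: float = 160.0
    g_CaT: float = 0.23
    g_CaL: float = 0.9
    g_SK: float = 25.0

    # SK gating
    K_s: float = 0.33          # µM half-activation
    n_SK: float = 4.0          # Hill coefficient (standard for SK)
    tau_s: float = 6.0         # ms activation/deactivation time constant

    # glutamate binding (two-state, Destexhe-style); alpha in 1/(mM·ms)
    alpha_A: float = 0.35      # sized (with g_neck) for a ~25 mV unitary EPSP
    beta_A: float = 0.19       # /ms -> AMPAR decay ~5 ms
    alpha_N: float = 0.8       # peak NMDAR open fraction ~0.55 after a 1 ms, 1 mM pulse
    beta_N: float = 1.0 / 25.0  # /ms -> NMDAR decay ~25 ms

    # NMDAR Mg2+ unblock (Jahr-Stevens)
    Mg_out: float = 1.0        # mM
    mg_K0: float = 3.57        # mM
    mg_gamma: float = 0.062    # /mV

    # VGCC Boltzmann gates (reconstructions of the unpublished kinetics
    # table; T-type low-voltage activated so EPSP-level depolarisation
    # opens it, L-type high-voltage activated with a steep switch)
    vh_mT: float = -47.0
    k_mT: float = 6.5
    tau_mT: float = 1.5        # ms
    vh_hT: float = -72.0
    k_hT: float = 6.0          # inactivation slope (enters with minus sign)
    tau_hT: float = 25.0       # ms
    vh_mL: float = -10.0
    k_mL: float = 4.5
    tau_mL: float = 0.5        # ms

    # reversal / driving
    E_syn: float = 0.0         # mV, AMPAR/NMDAR
    E_K: float = -79.0
    E_L: float = -70.0
    V_rest: float = -70.0
    E_Ca: float = 130.0        # mV nominal fixed Ca2+ reversal (ohmic driving)
    Ca_out: float = 2.0        # mM (GHK option)
    ca_driving: str = "ohmic"  # {"ohmic", "ghk"}
    f_Ca_N: float = 0.12       # NMDAR fractional Ca2+ current (defined at rest)

    # passive / coupling
    C_m: float = 0.01          # pF/µm² (= 1 µF/cm²)
    membrane_area: float = 3.48  # µm² (default spine); C_total = C_m * area
    g_L: float = 2.3           # pS -> ~15 ms passive time constant
    g_neck: float = 43.0       # pS, sized so a unitary EPSP peaks ~25 mV

    # bAP command waveform
    bap_amp: float = 67.0      # mV above rest (SK-blocked spine peak, calibrated)
    bap_gain: float = 1.0      # command amplitude scale (see calibrate_bap_gain)
    bap_tau1: float = 2.0      # ms fast decay
    bap_tau2: float = 4.0      # ms slow decay
    bap_frac1: float = 0.8     # amplitude fraction on tau1

    temperature: float = 310.0  # K, GHK option

    @property
    def C_total(self) -> float:
        """Total capacitance, pF."""
        return self.C_m * self.membrane_area

    @property
    def rt_over_2f(self) -> float:
        """RT/(zF) for z=2, in mV."""
        return 8.31446 * self.temperature / (2.0 * FARADAY) * 1e3


@dataclass
class MembraneState:
    """Voltage plus all gating variables (all gates in [0, 1])."""

    V: float
    r_A: float = 0.0
    r_N: float = 0.0
    m_T: float = 0.0
    h_T: float = 1.0
    m_L: float = 0.0
    s: float = 0.0

    @classmethod
    def resting(cls, params: ChannelParams, ca_rest: float = 0.05) -> "MembraneState":
        V = params.V_rest
        return cls(
            V=V,
            r_A=0.0,
            r_N=0.0,
            m_T=_boltzmann(V, params.vh_mT, params.k_mT),
            h_T=_boltzmann(V, params.vh_hT, -params.k_hT),
            m_L=_boltzmann(V, params.vh_mL, params.k_mL),
            s=sk_steady_state(ca_rest, params),
        )

    def gates(self) -> np.ndarray:
        return np.array([self.r_A, self.r_N, self.m_T, self.h_T, self.m_L, self.s])


@dataclass(frozen=True)
class StimulusCommand:
    """Stimulus at one instant: cleft glutamate, bAP command, SK blockade."""

    glutamate: float = 0.0       # mM
    bap_command: float = 0.0     # mV above rest
    sk_blocked: bool = False


# ---------------------------------------------------------------------------
# stimulus waveforms
# ---------------------------------------------------------------------------

def glutamate_pulse(t: float | np.ndarray, onset: float,
                    amplitude: float = 1.0, duration: float = 1.0):
    """Cleft glutamate after a presynaptic stimulus: a step pulse
    (default 1 mM for 1 ms starting at ``onset``)."""
    t = np.asarray(t, float)
    out = np.where((t >= onset) & (t < onset + duration), amplitude, 0.0)
    return float(out) if out.ndim == 0 else out


def bap_waveform(t: float | np.ndarray, onset: float, params: ChannelParams):
    """bAP command depolarization above rest: instantaneous rise, double
    exponential decay (amplitude split ``bap_frac1`` on tau1)."""
    if params.bap_tau1 <= 0 or params.bap_tau2 <= 0:
        raise ValueError("bAP decay constants must be > 0")
    t = np.asarray(t, float)
    dt = t - onset
    amp = params.bap_amp * params.bap_gain
    wave = amp * (params.bap_frac1 * np.exp(-np.maximum(dt, 0.0) / params.bap_tau1)
                  + (1.0 - params.bap_frac1) * np.exp(-np.maximum(dt, 0.0) / params.bap_tau2))
    out = np.where(dt >= 0.0, wave, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# gating updates (exact exponential relaxation over one step)
# ---------------------------------------------------------------------------

def _relax(x: float, x_inf: float, tau: float, dt: float) -> float:
    return x_inf + (x - x_inf) * np.exp(-dt / tau)


def _boltzmann(V: float, vh: float, k: float) -> float:
    return 1.0 / (1.0 + np.exp(-(V - vh) / k))


def receptor_gating(r: float, glu: float, alpha: float, beta: float,
                    dt: float) -> float:
    """Advance dr/dt = alpha·glu·(1-r) - beta·r exactly over dt (glu frozen).

    The closed-form update keeps r in [0, 1] for any dt without clipping.
    """
    a = alpha * glu + beta
    r_inf = alpha * glu / a if a > 0 else r
    return _relax(r, r_inf, 1.0 / a, dt) if a > 0 else r


def mg_unblock(V: float | np.ndarray, Mg: float = 1.0,
               K0: float = 3.57, gamma: float = 0.062):
    """Jahr-Stevens voltage-dependent Mg2+ unblock of the NMDAR,
    B(V) = 1 / (1 + (Mg/K0)·exp(-gamma·V))."""
    return 1.0 / (1.0 + (Mg / K0) * np.exp(-gamma * np.asarray(V, float)))


def vgcc_gates(V: float, m_T: float, h_T: float, m_L: float,
               params: ChannelParams, dt: float) -> tuple[float, float, float]:
    """Relax the T-type (activation+inactivation) and L-type (activation)
    gates toward their Boltzmann steady states."""
    m_T = _relax(m_T, _boltzmann(V, params.vh_mT, params.k_mT), params.tau_mT, dt)
    h_T = _relax(h_T, _boltzmann(V, params.vh_hT, -params.k_hT), params.tau_hT, dt)
    m_L = _relax(m_L, _boltzmann(V, params.vh_mL, params.k_mL), params.tau_mL, dt)
    return m_T, h_T, m_L


def sk_steady_state(ca_local: float | np.ndarray, params: ChannelParams):
    """Hill steady state s_inf = Ca^n / (Ca^n + K_s^n)."""
    ca = np.maximum(np.asarray(ca_local, float), 0.0)
    can = ca ** params.n_SK
    return can / (can + params.K_s ** params.n_SK)


def sk_update(s: float, ca_local: float, params: ChannelParams, dt: float) -> float:
    """Advance ds/dt = (s_inf(Ca_local) - s) / tau_s over dt."""
    if ca_local < 0:
        raise ValueError("local Ca2+ must be >= 0")
    return _relax(s, float(sk_steady_state(ca_local, params)), params.tau_s, dt)


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def _ghk_shape(V: np.ndarray, params: ChannelParams) -> np.ndarray:
    """GHK flux factor Phi(V) (µM-scaled); negative = inward for Ca2+."""
    V = np.asarray(V, float)
    u = V / params.rt_over_2f
    ca_out_uM = params.Ca_out * 1e3
    ca_in_uM = 0.05
    small = np.abs(u) < 1e-6
    us = np.where(small, 1e-6, u)
    phi = us * (ca_in_uM - ca_out_uM * np.exp(-us)) / (1.0 - np.exp(-us))
    phi0 = ca_in_uM - ca_out_uM  # u -> 0 limit
    return np.where(small, phi0, phi)


def _ca_driving(V: float, params: ChannelParams, norm_at: float,
                E_nominal: float) -> float:
    """Effective Ca2+ driving term (mV): ohmic (V - E_Ca) by default, or a
    GHK-shaped driving normalised to the ohmic chord at ``norm_at``."""
    if params.ca_driving == "ohmic":
        return V - E_nominal
    if params.ca_driving == "ghk":
        ref = float(_ghk_shape(np.asarray(norm_at), params))
        return float(_ghk_shape(np.asarray(V), params)) / ref * (norm_at - E_nominal)
    raise ValueError(f"unknown ca_driving {params.ca_driving!r}")


def channel_currents(state: MembraneState, params: ChannelParams,
                     sk_blocked: bool = False) -> dict[str, float]:
    """Per-cluster currents (pA; inward negative).

    Returns I_A, I_N (total synaptic), I_N_Ca (the Ca2+ component entering
    the NMDAR patch), I_CaT, I_CaL (VGCC patch Ca2+ currents), I_SK and
    I_L (leak).  ``sk_blocked`` forces I_SK = 0 regardless of s.
    """
    V = state.V
    B = float(mg_unblock(V, params.Mg_out, params.mg_K0, params.mg_gamma))
    i_a = params.g_A * state.r_A * (V - params.E_syn) * 1e-3
    i_n = params.g_N * state.r_N * B * (V - params.E_syn) * 1e-3
    # Ca component of NMDAR current: f_Ca of the total at rest, with the
    # chosen Ca driving shape (ohmic => proportional to V - E_Ca)
    drive_n = _ca_driving(V, params, norm_at=params.V_rest, E_nominal=params.E_Ca)
    rest_drive = params.V_rest - params.E_Ca
    scale_n = params.f_Ca_N * (params.V_rest - params.E_syn) / rest_drive
    i_n_ca = params.g_N * state.r_N * B * scale_n * drive_n * 1e-3
    drive_v = _ca_driving(V, params, norm_at=0.0, E_nominal=params.E_Ca)
    i_ca_t = params.g_CaT * state.m_T * state.h_T * drive_v * 1e-3
    i_ca_l = params.g_CaL * state.m_L * drive_v * 1e-3
    i_sk = 0.0 if sk_blocked else params.g_SK * state.s * (V - params.E_K) * 1e-3
    i_leak = params.g_L * (V - params.E_L) * 1e-3
    return {"I_A": i_a, "I_N": i_n, "I_N_Ca": i_n_ca,
            "I_CaT": i_ca_t, "I_CaL": i_ca_l, "I_SK": i_sk, "I_L": i_leak}


def update_voltage(state: MembraneState, params: ChannelParams,
                   stim: StimulusCommand, dt: float) -> MembraneState:
    """Advance the membrane by one step (exponential Euler on V, exact
    relaxation for every gate).

    All conductance-based terms (leak, AMPAR, NMDAR, SK, neck coupling) are
    treated as frozen conductances over the step; the small VGCC Ca2+
    currents enter as an explicit current source.
    """
    p = params
    # gates first (they see the pre-step voltage)
    r_A = receptor_gating(state.r_A, stim.glutamate, p.alpha_A, p.beta_A, dt)
    r_N = receptor_gating(state.r_N, stim.glutamate, p.alpha_N, p.beta_N, dt)
    m_T, h_T, m_L = vgcc_gates(state.V, state.m_T, state.h_T, state.m_L, p, dt)

    V = state.V
    B = float(mg_unblock(V, p.Mg_out, p.mg_K0, p.mg_gamma))
    g_sk = 0.0 if stim.sk_blocked else p.g_SK * state.s
    # conductance (pS) and conductance-weighted target of each linear term
    g_terms = np.array([p.g_L, p.g_A * state.r_A, p.g_N * state.r_N * B,
                        g_sk, p.g_neck])
    e_terms = np.array([p.E_L, p.E_syn, p.E_syn, p.E_K,
                        p.V_rest + stim.bap_command])
    cur = channel_currents(state, p, sk_blocked=stim.sk_blocked)
    i_extra = cur["I_CaT"] + cur["I_CaL"]  # pA, explicit
    g_tot = g_terms.sum()
    v_inf = (g_terms @ e_terms - i_extra * 1e3) / g_tot
    tau_v = p.C_total / g_tot * 1e3  # ms
    V_new = _relax(V, v_inf, tau_v, dt)

    return MembraneState(V=V_new, r_A=r_A, r_N=r_N, m_T=m_T, h_T=h_T,
                         m_L=m_L, s=state.s)


def current_to_flux(i_ca: float, patch_area: float) -> float:
    """Boundary flux density (µM·µm³ per µm² per ms, i.e. µM·µm/ms) for a
    Ca2+ current ``i_ca`` (pA, inward negative) over ``patch_area`` (µm²).

    Total molar rate is independent of the chosen patch area.
    """
    if patch_area <= 0:
        raise ValueError("patch area must be > 0")
    return -i_ca * PA_TO_UMOL_FLUX / patch_area


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def simulate_voltage_only(params: ChannelParams, protocol_events, t_end: float,
                          dt: float = 0.01, sk_blocked: bool = True,
                          ca_for_sk: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Membrane-only integration (no diffusion feedback), used for waveform
    calibration and passive tests.  SK sees a constant Ca; with SK blocked
    this is exact."""
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    V = np.empty(n + 1)
    state = MembraneState.resting(params, ca_for_sk)
    V[0] = state.V
    for k in range(n):
        tk = t[k]
        glu = sum(glutamate_pulse(tk, on) for kind, on in protocol_events if kind == "EPSP")
        bap = sum(bap_waveform(tk, on, params) for kind, on in protocol_events if kind == "bAP")
        stim = StimulusCommand(glutamate=float(glu), bap_command=float(bap),
                               sk_blocked=sk_blocked)
        state = update_voltage(state, params, stim, dt)
        state.s = sk_update(state.s, ca_for_sk, params, dt)
        V[k + 1] = state.V
    return t, V


def calibrate_bap_gain(params: ChannelParams, tol: float = 1e-3) -> ChannelParams:
    """Scale the bAP command amplitude so that a single, SK-blocked bAP
    drives the spine to exactly ``bap_amp`` (67 mV) above rest.

    The command is conductance-coupled through the neck, so the RC lag makes
    the spine peak fall short of the raw command amplitude; a scalar gain on
    the command restores the printed peak without touching the EPSP path.
    """
    lo, hi = 1.0, 4.0
    for _ in range(40):
        gain = 0.5 * (lo + hi)
        p = replace(params, bap_gain=gain)
        _, V = simulate_voltage_only(p, [("bAP", 1.0)], t_end=8.0, dt=0.01)
        peak = V.max() - p.V_rest
        if abs(peak - params.bap_amp) < tol:
            return p
        if peak < params.bap_amp:
            lo = gain
        else:
            hi = gain
    return replace(params, bap_gain=0.5 * (lo + hi))
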