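# Model and numerical methods

`spinecam` simulates Ca²⁺ and calmodulin (CaM) dynamics in a single
idealised dendritic spine in three spatial dimensions, with the membrane
voltage and channel gating of the spine driving time-varying Ca²⁺ influx at
discrete channel-cluster patches, and a small-conductance Ca²⁺-activated K⁺
(SK) conductance closing a negative-feedback loop from nanodomain [Ca²⁺]
back onto the voltage.

## Geometry and mesh

The domain is the union of a spherical head (radius 0.5 µm) and a
cylindrical neck (radius 0.1 µm, length 0.5 µm) attached antipodal to the
postsynaptic density (PSD) pole; these are median CA1 spine dimensions (the
head radius also follows from the π rad ≈ 1.6 µm membrane-arc relation).
Channel clusters are circular membrane patches addressed by the polar angle
θ from the PSD pole along one meridian: NMDARs at θ = 0, voltage-gated Ca²⁺
channels (VGCCs, T- plus L-type) at θ = π/2, and the SK cluster wherever a
given experiment places it (default: 50 nm of arc from the NMDAR cluster).
A nominal cluster is far smaller than any resolvable element, so flux is
spread over an effective 10 nm patch with the total current conserved
(flux = I/(2FA)); readouts at ≥ 20 nm are insensitive to this choice
(tested between 5 and 20 nm patch diameters).

Meshing builds a deterministic graded point cloud — Fibonacci surface
sampling, geometric refinement rings/shells around each cluster down to
2 nm spacing, an interior lattice — and tetrahedralises it with Delaunay;
tetrahedra with centroids outside the domain are discarded. All points get
a 0.05 nm deterministic jitter, which removes the Qhull co-sphericity
degeneracy of points lying exactly on spheres. Interior element sizes
follow the 0.1/0.02 µm (interior) and 0.02 µm (within 50 nm of a source)
targets; four resolution levels (`tiny`, `coarse`, `default`, `fine`)
scale these uniformly. Contracts, enforced by tests: mesh volume within 1 %
of the analytic value, boundary partitioned exactly into labelled patches,
volume error decreasing at least linearly with element size, and exact
interpolation of linear fields at probe points.

## Membrane and channels

The spine is one isopotential compartment (total capacitance
C = 1 µF/cm² × 3.48 µm²). AMPAR and NMDAR open fractions follow two-state
glutamate-binding kinetics, dr/dt = α·[glu]·(1−r) − β·r, driven by a 1 mM,
1 ms cleft-glutamate step per presynaptic stimulus. The NMDAR carries the
Jahr–Stevens Mg²⁺ unblock B(V) = 1/(1 + ([Mg]/3.57 mM)·e^(−0.062 V)) with
[Mg] = 1 mM. T-type (LVA; V½ = −45 mV, with slow inactivation) and L-type
(HVA; V½ = −10 mV, slope 4.5 mV — a steep switch near full depolarisation)
gates relax first-order to Boltzmann steady states. The SK conductance
follows a Hill function of the Ca²⁺ concentration 20 nm inside its own
cluster, s∞ = Ca⁴/(Ca⁴ + K_s⁴) with K_s = 0.33 µM, relaxing with
τ_s = 6 ms — slow enough that unitary stimuli escape the feedback while a
stimulus 10 ms after a priming EPSP does not.

A back-propagating action potential (bAP) is a commanded waveform —
instantaneous rise, double-exponential decay (τ₁ = 2 ms carrying 80 %,
τ₂ = 4 ms) — injected through a neck coupling conductance
(g_neck = 43 pS), not a hard clamp, so the SK current can repolarise the
spine during bAPs. Because the RC lag keeps the spine below the raw
command, the command amplitude carries a calibrated gain such that a
single SK-blocked bAP peaks at exactly 67 mV above rest; g_neck itself is
sized so a unitary EPSP peaks near 25 mV. Both voltage amplitudes are the
observables the model is calibrated to.

Ca²⁺ driving force is ohmic with a fixed reversal E_Ca = +130 mV. A
GHK-shaped driving is implemented and selectable, but with the published
cluster conductances only a driving that stays strong under depolarisation
delivers the calibrated global Ca²⁺ amplitudes; empirically the NMDAR
fractional Ca²⁺ current is roughly voltage independent, which the fixed
reversal approximates better than a rest-normalised GHK shape. The NMDAR
Ca²⁺ component is f_Ca = 12 % of the total NMDAR current at rest.

Resting channel leak (chiefly the small T-type window current) is
subtracted from the boundary fluxes, and the extrusion sink is offset by a
constant basal influx γ·Ca_rest, so the unstimulated spine is an exact
steady state.

## Chemistry

Free Ca²⁺ (D = 220 µm²/s) reacts with:

* an endogenous fixed buffer (EFB): immobile, fast (k_on = 5×10⁸ M⁻¹s⁻¹),
  low affinity (K_d = 15 µM), with total set so its incremental binding
  ratio κ = B_T·K_d/(K_d+Ca)² is 20 at the 50 nM resting Ca²⁺;
* 100 µM calbindin as four independent sites per molecule
  (k_on = 7.5×10⁷ M⁻¹s⁻¹ per site, K_d = 1.5 µM so κ ≈ 250 at rest),
  diffusing at 20 µm²/s; an indicator dye for calibration runs is another
  mobile single-site buffer (default K_d = 0.2 µM, 100 µM, D = 50 µm²/s);
* 100 µM calmodulin: each lobe binds two Ca²⁺ cooperatively — the first
  site in a low-affinity T state (statistical factor 2 on the on-rate),
  after which the remaining site switches to the high-affinity R state
  (factor 2 on the final off-rate). The N lobe is fast and low affinity,
  the C lobe slow and high affinity (rates from the cooperative-scheme
  literature), except that the C-lobe T-state off-rate (495 s⁻¹,
  K_T,C = 5.9 µM) is set so that 100 µM CaM contributes the documented
  resting binding ratio of ≈ 35. This division of labour makes the C lobe a
  temporal integrator across stimuli and the N lobe a tracker of the
  instantaneous Ca²⁺ signal; fully activated CaCaM (all four sites) exists
  essentially only inside channel nanodomains.

Extrusion is a single linear volumetric sink −γ[Ca²⁺] acting on free Ca²⁺
(γ = 5000 s⁻¹ default), lumping pumps, exchangers and store uptake.

Because the two CaM lobes are kinetically independent and all nine
occupancy states share one diffusivity, the joint 9-state distribution
remains an exact product of the two 3-state lobe marginals; the solver
integrates the six marginal fields and reconstructs the 9-state vector
(and the fully-active/N-full/C-full readouts) pointwise. A test verifies
the factorised integrator against an independent BDF integration of the
full 9-state network.

## Numerics

Space: P1 tetrahedral finite elements with lumped mass; boundary flux
enters as a patch-face load. Time: first-order operator splitting at a
fixed 10 µs step (the published maximum step): an implicit-Euler diffusion
solve per mobile species using prefactorised sparse LU (exactly mass
conservative), then a per-node backward-Euler solve of the local reaction
network by damped Newton (vectorised over nodes; backward Euler preserves
the network's linear invariants — total Ca, buffer, CaM — to Newton
tolerance, 10⁻¹⁰ relative). The membrane ODEs advance by exact
exponential-relaxation updates, which keep every gating variable in [0, 1]
without clipping. Steps that fail the Newton solve are recursively halved.
Contracts replace formal order: halving the step changes the global Ca²⁺
peak by < 0.5 %; with γ = 0 and no influx, total Ca drifts < 0.1 % over
60 ms; with diffusivities ×1000 the solution matches a well-mixed ODE
oracle within 1 %; a constant point flux with linear sink reproduces the
screened point-source profile c(r) = Q·e^(−r/λ)/(2πDr) within 10 % at
20–50 nm.

Default output sampling is 0.05 ms. Desk-scale problem sizes: the test
suite and the acceptance script run on the `tiny`/`coarse` mesh levels
(~1.5–2×10³ nodes, 30–45 ms protocols), where a full run takes tens of
seconds; `default` (~3×10³ nodes) reproduces the same quantities within
the stated mesh-stability tolerances (global peak < 5 % between adjacent
levels, 20 nm probes < 10 %).

## Synthetic data

The stimulus library covers the seven canonical protocols (EPSP, bAP,
EPSP-bAP, bAP-EPSP, EPSP-2bAPs, 2EPSPs, 2bAPs; 10 ms spacings), and a
Condition bundles buffer set, SK blockade/position, VGCC layout and scalar
overrides, so every reported experiment is a (protocol, condition) pair.

The synthetic-fluorescence generator emulates the Ca²⁺-imaging data the
extrusion rate was originally constrained by: it runs the forward model
with the indicator dye as mobile buffer and emits a trace proportional to
the volume-averaged Ca²⁺-bound dye, plus i.i.d. Gaussian noise with a
mandatory seed. What it does not emulate: photon shot-noise statistics,
bleaching, motion artefacts, and dye compartmentalisation — so recovery
tests demonstrate identifiability of γ under the model's own assumptions,
not robustness to real imaging pathologies. Calibration evaluates the
forward model on a log-spaced γ grid, compares baseline/peak-normalised
transients by least squares, and refines the optimum by parabolic
interpolation in log γ; an optimum pinned to the search boundary is
flagged rather than silently returned.

## Parameterisation and known limitations

Published values are used directly: cluster conductances (60/160/0.23/0.9/
25 pS), K_s, τ_s, buffer binding ratios, CaM concentration and
diffusivity, γ, mesh sizes, solver step and tolerance, stimulus
definitions, 67 mV bAP and ~25 mV EPSP amplitudes. The remaining kinetic
constants (receptor α/β, VGCC midpoints, passive/coupling conductances,
bAP decay shape, f_Ca, E_K) are reconstructions calibrated against those
published observables, and are all plain configuration values.

Under this reconstruction the SK-blockade effect on fully-activated CaCaM
is strongest in the VGCC nanodomain (order 10–20 fold, via the steep
L-type switch), and the rank ordering across readouts and protocols —
VGCC nanodomain > global EPSP-2bAPs ≥ global EPSP-bAP > NMDAR nanodomain >
bAP-first protocols (~1) — reproduces, as do the HVA current increase and
the insensitivity of unitary stimuli. The absolute global and
NMDAR-nanodomain fold changes, however, saturate near 2–3 here: the global
fully-activated CaCaM is dominated by the NMDAR nanodomain, whose influx
gains little from blockade because increased Mg²⁺ unblock is largely
cancelled by the reduced driving force. Larger printed ratios evidently
require kinetic details of the original (unpublished) parameter tables;
this is a documented limitation, not a tuned-away discrepancy.

Other limitations: deterministic gating (no channel noise), no internal
stores or CICR, no downstream CaM targets, one isopotential compartment
(no spatial voltage gradients), and idealised geometry.
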