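# spinecam

A 3-D deterministic reaction–diffusion model of Ca²⁺ and calmodulin (CaM)
dynamics in a single dendritic spine, with SK-channel negative feedback on
Ca²⁺ influx.

## The problem

Induction of Hebbian synaptic plasticity is triggered by Ca²⁺ entering the
postsynaptic spine through NMDA receptors and voltage-gated Ca²⁺ channels
(VGCCs), read out by calmodulin — which is only fully activated when all
four of its Ca²⁺ sites (two on a fast, low-affinity N lobe; two on a slow,
high-affinity C lobe) are occupied. Small-conductance Ca²⁺-activated K⁺
(SK) channels sense [Ca²⁺] in a nanodomain near the Ca²⁺ sources and
hyperpolarise the spine, closing a negative-feedback loop that can gate
plasticity. Because these nanodomains are below optical resolution, a
spatial model is the only way to study the loop quantitatively.

`spinecam` is for computational neuroscientists who want a tested,
desk-scale implementation of this system: an idealised spine (sphere head ∪
cylinder neck) with discrete NMDAR, VGCC (T- and L-type) and SK clusters on
the membrane, Hodgkin–Huxley-style voltage/gating dynamics driving
time-varying Ca²⁺ boundary fluxes, buffered Ca²⁺ diffusion (endogenous
fixed buffer, calbindin, indicator dye), a cooperative 9-state two-lobe CaM
model, and a linear extrusion sink (γ = 5000 s⁻¹), integrated with P1
finite elements and implicit time stepping at a 10 µs step.

Key model elements, in the field's notation:

* receptor gating `dr/dt = α[glu](1−r) − βr`; NMDAR Mg²⁺ unblock
  `B(V) = 1/(1 + ([Mg]/3.57 mM)e^(−0.062V))`;
* VGCC gates `m∞(V) = 1/(1+e^(−(V−V½)/k))` with first-order relaxation
  (T-type LVA, L-type HVA);
* SK activation `ds/dt = (s∞ − s)/τ_s`, `s∞ = Ca⁴/(Ca⁴ + K_s⁴)`,
  `K_s = 0.33 µM`, `τ_s = 6 ms`, driven by [Ca²⁺] 20 nm inside the SK
  cluster;
* boundary flux `J = I_Ca/(2FA)` on each cluster patch, zero-flux
  elsewhere; mass-action buffer/CaM kinetics and extrusion `−γ[Ca²⁺]` in
  the volume.

See `docs/methods.md` for the full model description, parameter provenance
and numerical contracts.

## Worked example

Run the canonical LTP-inducing pairing (EPSP followed by a bAP 10 ms
later) with the default buffers and SK coupled 50 nm from the NMDAR
cluster:

```bash
spinecam simulate EPSP-bAP --mesh-level coarse --t-end 35 --out out/
```

prints

```
peak V: 56.75 mV above rest
peak global [Ca2+]: 0.1286 µM
wrote out/EPSP-bAP.csv / .h5
```

The 56.7 mV peak is the bAP depolarisation already curtailed by SK current
(a lone, SK-blocked bAP is calibrated to peak at 67 mV); the
volume-averaged Ca²⁺ transient peaks near 0.13 µM, an order of magnitude
below the nanodomain concentrations stored in the per-probe columns of
`out/EPSP-bAP.csv`. The same library calls are available in Python:

```python
from spinecam import ModelConfig, Condition, make_protocol, run_protocol

out = run_protocol(make_protocol("EPSP-2bAPs"),
                   Condition(include_cam=True, sk_blocked=True),
                   ModelConfig(mesh_level="coarse"))
print(out.global_avg["CaM_fully_active"].max())
```

Other CLI commands: `spinecam sweep` (SK-position θ sweeps),
`spinecam figure fig2|fig4|fig6|...` (reproductions of the in-silico
experiments), `spinecam calibrate` (extrusion-rate recovery from synthetic
indicator fluorescence), `spinecam validate` (quick invariant check).

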