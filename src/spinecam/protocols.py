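"""Stimulus protocols, experimental conditions, and synthetic imaging data.

The seven canonical stimuli combine EPSPs (1 mM, 1 ms glutamate pulses) and
bAPs (67 mV command waveforms) at 10 ms spacing.  A Condition bundles the
buffer set, SK state/position, VGCC distribution and scalar parameter
overrides, so that every in-silico experiment is expressible as a
(protocol, condition) pair.

The synthetic-fluorescence generator stands in for the Ca2+-imaging data the
extrusion rate gamma was originally tuned against: it runs the forward model
with an indicator dye as the mobile buffer and emits a dF/F-like trace
proportional to the Ca2+-bound dye, plus optional Gaussian noise.
``calibrate_extrusion`` then recovers gamma by least squares on the
normalised transient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import chemistry as chem
from .channels import ChannelParams
from .geometry import ClusterPatch, SpineGeometry, default_clusters

__all__ = [
    "Protocol",
    "Condition",
    "SynthFluorescence",
    "CalibrationResult",
    "PROTOCOL_NAMES",
    "make_protocol",
    "make_condition_grid",
    "synth_fluorescence",
    "calibrate_extrusion",
]

EVENT_SPACING = 10.0  # ms between events in compound stimuli

_PROTOCOL_EVENTS = {
    "EPSP": [("EPSP", 0.0)],
    "bAP": [("bAP", 0.0)],
    "EPSP-bAP": [("EPSP", 0.0), ("bAP", 10.0)],
    "bAP-EPSP": [("bAP", 0.0), ("EPSP", 10.0)],
    "EPSP-2bAPs": [("EPSP", 0.0), ("bAP", 10.0), ("bAP", 20.0)],
    "2EPSPs": [("EPSP", 0.0), ("EPSP", 10.0)],
    "2bAPs": [("bAP", 0.0), ("bAP", 10.0)],
}
PROTOCOL_NAMES = tuple(_PROTOCOL_EVENTS)


@dataclass(frozen=True)
class Protocol:
    """Ordered stimulus events [(kind, onset ms)] with a canonical name."""

    name: str
    events: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        onsets = [on for _, on in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be non-decreasing")
        for kind, _ in self.events:
            if kind not in ("EPSP", "bAP"):
                raise ValueError(f"unknown event kind {kind!r}")

    @property
    def duration(self) -> float:
        return max(on for _, on in self.events) if self.events else 0.0


def make_protocol(name: str) -> Protocol:
    """Build one of the canonical stimuli by name."""
    try:
        ev = _PROTOCOL_EVENTS[name]
    except KeyError:
        raise ValueError(
            f"unknown protocol {name!r}; valid: {list(PROTOCOL_NAMES)}")
    return Protocol(name=name, events=tuple((k, float(on)) for k, on in ev))


@dataclass(frozen=True)
class Condition:
    """One experimental condition: buffers, SK state/position, VGCC layout
    and scalar overrides.

    ``sk_theta`` overrides ``sk_coupling_nm`` when given.  ``gamma``,
    ``cam_diffusivity``, ``g_CaL`` and ``mobile_buffer`` override the
    respective defaults; ``extra_buffers`` appends e.g. an indicator dye.
    """

    buffer_set: str = "EFB+calbindin"       # none | EFB | EFB+calbindin
    include_cam: bool = False
    sk_blocked: bool = False
    sk_coupling_nm: float = 50.0            # arc distance to NMDAR cluster
    sk_theta: float | None = None
    vgcc_uniform: bool = False
    gamma: float | None = None              # s^-1
    cam: chem.CaMSpec | None = None
    cam_diffusivity: float | None = None    # µm²/s
    g_CaL: float | None = None              # pS
    mobile_buffer: chem.BufferSpec | None = None  # replaces calbindin
    extra_buffers: tuple[chem.BufferSpec, ...] = ()
    channel_overrides: tuple[tuple[str, float], ...] = ()

    # -- builders ---------------------------------------------------------
    def make_chemistry(self, base: chem.ChemistrySpec) -> chem.ChemistrySpec:
        spec = base.with_buffers(self.buffer_set)
        bufs = list(spec.buffers)
        if self.mobile_buffer is not None:
            bufs = [b for b in bufs if b.diffusivity == 0.0] + [self.mobile_buffer]
        bufs.extend(self.extra_buffers)
        cam = self.cam if self.cam is not None else (
            (base.cam or chem.CaMSpec()) if self.include_cam else None)
        if cam is not None and self.cam_diffusivity is not None:
            cam = replace(cam, diffusivity=self.cam_diffusivity)
        extr = (chem.ExtrusionSpec(self.gamma) if self.gamma is not None
                else base.extrusion)
        return replace(spec, buffers=tuple(bufs), cam=cam, extrusion=extr)

    def make_clusters(self, geom: SpineGeometry) -> list[ClusterPatch]:
        return default_clusters(sk_theta=self.sk_theta, geom=geom,
                                sk_coupling_nm=self.sk_coupling_nm,
                                vgcc_uniform=self.vgcc_uniform)

    def make_channels(self, base: ChannelParams) -> ChannelParams:
        p = base
        if self.g_CaL is not None:
            p = replace(p, g_CaL=self.g_CaL)
        for name, value in self.channel_overrides:
            p = replace(p, **{name: value})
        return p

    def describe(self) -> str:
        bits = [self.buffer_set,
                "SK-blocked" if self.sk_blocked else
                (f"SK@theta={self.sk_theta:.3f}" if self.sk_theta is not None
                 else f"SK@{self.sk_coupling_nm:g}nm")]
        if self.include_cam or self.cam is not None:
            bits.append("CaM")
        if self.vgcc_uniform:
            bits.append("uniform-VGCC")
        if self.gamma is not None:
            bits.append(f"gamma={self.gamma:g}")
        if self.g_CaL is not None:
            bits.append(f"gCaL={self.g_CaL:g}")
        return ", ".join(bits)


def make_condition_grid(**axes: Sequence) -> list[Condition]:
    """Cartesian product of Condition field values, in deterministic order.

    Example: ``make_condition_grid(buffer_set=["none", "EFB"],
    sk_blocked=[False, True])`` -> 4 conditions.
    """
    if not axes:
        return [Condition()]
    names = list(axes)
    for n, vals in axes.items():
        if len(vals) == 0:
            raise ValueError(f"empty axis {n!r}")
    out = []
    for combo in itertools.product(*(axes[n] for n in names)):
        out.append(Condition(**dict(zip(names, combo))))
    return out


# ---------------------------------------------------------------------------
# synthetic fluorescence + extrusion-rate calibration
# ---------------------------------------------------------------------------

@dataclass
class SynthFluorescence:
    """Synthetic indicator trace with known ground-truth extrusion rate."""

    t: np.ndarray            # ms
    trace: np.ndarray        # arbitrary fluorescence units
    sigma: float             # noise std (trace units)
    seed: int | None
    gamma_true: float        # s^-1
    protocol: str
    dye: chem.BufferSpec

    def save_csv(self, path: str) -> None:
        np.savetxt(path, np.column_stack([self.t, self.trace]),
                   delimiter=",", header="t_ms,signal", comments="")


@dataclass
class CalibrationResult:
    gamma_hat: float         # s^-1
    objective: float         # residual sum of squares at the optimum
    at_boundary: bool        # optimum pinned to the search-range edge
    grid: np.ndarray
    objectives: np.ndarray


def _forward_dye_trace(gamma: float, dye: chem.BufferSpec, protocol: Protocol,
                       config, cache: dict | None) -> tuple[np.ndarray, np.ndarray]:
    """Global Ca-bound-dye time course from the forward model (cached)."""
    key = (round(float(gamma), 6), dye, protocol.name,
           config.solver.t_end, config.mesh_level)
    if cache is not None and key in cache:
        return cache[key]
    from .solver import run_protocol  # deferred: avoids an import cycle
    cond = Condition(buffer_set="EFB", mobile_buffer=dye, gamma=float(gamma))
    out = run_protocol(protocol, cond, config)
    bound_dye = out.global_avg[dye.name] if dye.name in out.global_avg else None
    if bound_dye is None:
        # global bound dye is tracked via the output's probe machinery only
        # for Ca; recompute from the saved trace of free Ca is not possible,
        # so the solver records it: fall back to total-bound reconstruction.
        raise RuntimeError("dye trace missing from output")
    res = (out.t, bound_dye)
    if cache is not None:
        cache[key] = res
    return res


def synth_fluorescence(protocol: Protocol | str, gamma_true: float,
                       dye: chem.BufferSpec = chem.INDICATOR_DYE,
                       noise_sigma: float = 0.0, seed: int | None = None,
                       config=None, scale: float = 1.0,
                       cache: dict | None = None) -> SynthFluorescence:
    """Run the forward model with the indicator dye and emit a noisy trace
    ``scale·[Ca-dye](t) + N(0, noise_sigma)``.  Reproducible given ``seed``."""
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if config is None:
        from .config import ModelConfig
        config = ModelConfig()
    if isinstance(protocol, str):
        protocol = make_protocol(protocol)
    t, bound = _forward_dye_trace(gamma_true, dye, protocol, config, cache)
    trace = scale * bound.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sigma, size=trace.shape)
    return SynthFluorescence(t=t, trace=trace, sigma=noise_sigma, seed=seed,
                             gamma_true=gamma_true, protocol=protocol.name,
                             dye=dye)


def _normalise(trace: np.ndarray) -> np.ndarray:
    base = trace[0]
    peak = trace.max() - base
    if peak <= 0:
        raise ValueError("flat trace: no transient to fit")
    return (trace - base) / peak


def _scaled_sse(model: np.ndarray, data: np.ndarray) -> float:
    """Residual sum of squares after fitting scale and offset (robust to
    the unknown fluorescence gain and to noise in the raw peak/baseline)."""
    X = np.column_stack([model, np.ones_like(model)])
    coef, res, *_ = np.linalg.lstsq(X, data, rcond=None)
    if coef[0] <= 0:  # anti-correlated fit: penalise
        return float(((data - data.mean()) ** 2).sum()) * 10.0
    return float(((data - X @ coef) ** 2).sum())


def calibrate_extrusion(trace: SynthFluorescence,
                        dye: chem.BufferSpec | None = None,
                        search_range: tuple[float, float] = (1000.0, 20000.0),
                        config=None, n_grid: int = 9,
                        cache: dict | None = None) -> CalibrationResult:
    """Recover the extrusion rate from a fluorescence transient.

    Runs the forward model on a log-spaced gamma grid, compares each model
    transient to the data by least squares with a free scale and offset
    (the fluorescence gain is unknown), and refines the optimum by
    parabolic interpolation of the objective in log gamma.  Model
    evaluations are shared across calls via ``cache``.  If the optimum pins
    to the edge of the search range, the boundary value is returned with
    ``at_boundary``.
    """
    if config is None:
        from .config import ModelConfig
        config = ModelConfig()
    dye = dye or trace.dye
    protocol = make_protocol(trace.protocol)
    lo, hi = search_range
    if not (0 < lo < hi):
        raise ValueError("invalid search range")
    grid = np.geomspace(lo, hi, n_grid)
    _normalise(trace.trace)  # rejects flat traces
    data = trace.trace
    obj = np.empty(n_grid)
    for i, g in enumerate(grid):
        tm, bound = _forward_dye_trace(g, dye, protocol, config, cache)
        model = np.interp(trace.t, tm, bound)
        obj[i] = _scaled_sse(model, data)
    k = int(np.argmin(obj))
    if k in (0, n_grid - 1):
        return CalibrationResult(float(grid[k]), float(obj[k]), True, grid, obj)
    # parabolic refinement in log-gamma
    x = np.log(grid[k - 1:k + 2])
    y = obj[k - 1:k + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom <= 0:
        ghat = grid[k]
    else:
        ghat = float(np.exp(x[1] - 0.5 * (x[2] - x[0]) / 2 * (y[2] - y[0]) / denom))
    return CalibrationResult(float(ghat), float(obj[k]), False, grid, obj)
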