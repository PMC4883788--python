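"""Aggregate model configuration and YAML round-tripping.

A ModelConfig holds everything a protocol run needs besides the stimulus and
condition: spine geometry, mesh resolution, channel parameters, baseline
chemistry, solver settings, and probe distances.  All fields are plain
dataclasses so a config can be written to / read from a human-readable YAML
file with every assumption visible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import yaml

from .channels import ChannelParams, calibrate_bap_gain
from .chemistry import BufferSpec, CaMSpec, ChemistrySpec, ExtrusionSpec
from .geometry import MeshSpec, SpineGeometry, mesh_spec_for_level
from .solver import SolverConfig

__all__ = ["ModelConfig", "load_config", "save_config"]

_BAP_GAIN_CACHE: dict[tuple, float] = {}


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to run a (protocol, condition) pair."""

    geometry: SpineGeometry = field(default_factory=SpineGeometry)
    mesh_level: str = "default"
    mesh_override: MeshSpec | None = None
    channels: ChannelParams = field(default_factory=ChannelParams)
    chemistry: ChemistrySpec = field(default_factory=ChemistrySpec)
    solver: SolverConfig = field(default_factory=SolverConfig)
    probe_nm: float = 20.0      # nanodomain readout distance
    sk_probe_nm: float = 20.0   # probe feeding the SK Hill gate
    auto_bap_gain: bool = True  # calibrate the bAP command on construction

    def __post_init__(self) -> None:
        if self.auto_bap_gain and self.channels.bap_gain == 1.0:
            key = _channel_key(self.channels)
            if key not in _BAP_GAIN_CACHE:
                _BAP_GAIN_CACHE[key] = calibrate_bap_gain(self.channels).bap_gain
            object.__setattr__(self, "channels",
                               replace(self.channels,
                                       bap_gain=_BAP_GAIN_CACHE[key]))

    @property
    def mesh_spec(self) -> MeshSpec:
        if self.mesh_override is not None:
            return self.mesh_override
        return mesh_spec_for_level(self.mesh_level)

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def _channel_key(p: ChannelParams) -> tuple:
    return tuple(getattr(p, f.name) for f in dataclasses.fields(p)
                 if f.name != "bap_gain")


# ---------------------------------------------------------------------------
# YAML serialisation
# ---------------------------------------------------------------------------

def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_dict(v) for v in obj]
    return obj


def save_config(config: ModelConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_as_dict(config), f, sort_keys=False)


def _build(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data or data[f.name] is None:
            continue
        v = data[f.name]
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str) -> ModelConfig:
    """Read a YAML config written by :func:`save_config` (or hand-edited;
    missing keys fall back to defaults)."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    kwargs = {}
    if "geometry" in data:
        kwargs["geometry"] = _build(SpineGeometry, data["geometry"])
    if "mesh_level" in data:
        kwargs["mesh_level"] = data["mesh_level"]
    if "mesh_override" in data and data["mesh_override"]:
        kwargs["mesh_override"] = _build(MeshSpec, data["mesh_override"])
    if "channels" in data:
        kwargs["channels"] = _build(ChannelParams, data["channels"])
    if "chemistry" in data:
        cd = dict(data["chemistry"])
        if "buffers" in cd:
            cd["buffers"] = tuple(_build(BufferSpec, b) for b in cd["buffers"])
        if cd.get("cam"):
            cd["cam"] = _build(CaMSpec, cd["cam"])
        if "extrusion" in cd and cd["extrusion"] is not None:
            cd["extrusion"] = _build(ExtrusionSpec, cd["extrusion"])
        kwargs["chemistry"] = _build(ChemistrySpec, cd)
    if "solver" in data:
        sd = dict(data["solver"])
        if "snapshot_times" in sd:
            sd["snapshot_times"] = tuple(sd["snapshot_times"])
        kwargs["solver"] = _build(SolverConfig, sd)
    for k in ("probe_nm", "sk_probe_nm", "auto_bap_gain"):
        if k in data:
            kwargs[k] = data[k]
    return ModelConfig(**kwargs)
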