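"""Shared fixtures.

Heavy simulation runs are session-scoped and shared across test modules;
they use the smallest mesh level so the whole suite stays desk-scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from spinecam import (ChemistrySpec, Condition, ModelConfig, SolverConfig,
                      build_spine_mesh, make_protocol, run_protocol)
from spinecam.geometry import mesh_spec_for_level


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig(mesh_level="tiny")


@pytest.fixture(scope="session")
def coarse_mesh():
    cfg = ModelConfig(mesh_level="coarse")
    return build_spine_mesh(cfg.geometry, cfg.mesh_spec)


@pytest.fixture(scope="session")
def tiny_mesh():
    cfg = ModelConfig(mesh_level="tiny")
    return build_spine_mesh(cfg.geometry, cfg.mesh_spec)


def run_tiny(protocol: str, condition: Condition, t_end: float,
             config: ModelConfig | None = None, **kwargs):
    cfg = config or ModelConfig(mesh_level="tiny")
    cfg = cfg.with_(solver=replace(cfg.solver, t_end=t_end))
    return run_protocol(make_protocol(protocol), condition, cfg, **kwargs)


@pytest.fixture(scope="session")
def dye_cache(tiny_config):
    """Shared forward-model cache for synthetic-fluorescence tests (tiny
    mesh, 40 ms single-bAP transients)."""
    cfg = tiny_config.with_(solver=replace(tiny_config.solver, t_end=40.0))
    return {"config": cfg, "cache": {}}


@pytest.fixture(scope="session")
def epsp_run(tiny_config):
    """Single EPSP, full buffers, SK coupled at 50 nm (25 ms)."""
    return run_tiny("EPSP", Condition(), 25.0, tiny_config)


@pytest.fixture(scope="session")
def epsp_bap_runs(tiny_config):
    """EPSP-bAP with SK active and blocked (no CaM), 35 ms."""
    return {blocked: run_tiny("EPSP-bAP", Condition(sk_blocked=blocked),
                              35.0, tiny_config)
            for blocked in (False, True)}


@pytest.fixture(scope="session")
def cam_blockade_runs(tiny_config):
    """The SK-blockade experiment: EPSP-2bAPs, EPSP-bAP and bAP-EPSP with
    CaM, each with SK active and blocked (45 ms)."""
    out = {}
    for proto in ("EPSP-2bAPs", "EPSP-bAP", "bAP-EPSP"):
        for blocked in (False, True):
            out[(proto, blocked)] = run_tiny(
                proto, Condition(include_cam=True, sk_blocked=blocked),
                45.0, tiny_config)
    return out


@pytest.fixture(scope="session")
def unitary_blockade_runs(tiny_config):
    """Unitary EPSP and bAP with SK active/blocked (no CaM), 30 ms."""
    out = {}
    for proto in ("EPSP", "bAP"):
        for blocked in (False, True):
            out[(proto, blocked)] = run_tiny(
                proto, Condition(sk_blocked=blocked), 30.0, tiny_config)
    return out
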