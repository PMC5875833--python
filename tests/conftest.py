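"""Shared fixtures: compact simulation configs and cached pipeline runs.

Simulated measurements reuse a reduced detector grid (160 x 192 pixels at
the 0.784 mm panel pitch, ~125 x 150 mm of panel) so the full 10x10 cm
field and its penumbra fit with margin while keeping the x20 bicubic
upsample affordable inside the suite. Results are cached per SimConfig —
configs are frozen dataclasses, so identical requests across tests share
one run.
"""

from __future__ import annotations

import functools

import pytest
from hypothesis import HealthCheck, settings

from focalspot import (
    LinacGeometry,
    OffsetVector,
    SimConfig,
    measure_focal_spot,
    render_measurement_set,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FAST_GRID = (160, 192)


def fast_config(**overrides) -> SimConfig:
    """Noiseless, reduced-grid simulation config for pipeline tests."""
    kwargs = dict(noise=0.0, grid=FAST_GRID, seed=0)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@functools.lru_cache(maxsize=64)
def run_pipeline(cfg: SimConfig, axis_pairing: str = "x-inplane"):
    """Render a measurement set and measure it; cached across the suite."""
    mset = render_measurement_set(cfg)
    return measure_focal_spot(mset, cfg.geometry, axis_pairing=axis_pairing)


@pytest.fixture(scope="session")
def default_geometry() -> LinacGeometry:
    return LinacGeometry()


@pytest.fixture()
def fast_cfg() -> SimConfig:
    return fast_config()
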