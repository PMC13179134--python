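"""Shared fixtures: small synthetic sections so tests stay fast."""

import numpy as np
import pytest
from hypothesis import settings

from marrowmap import (CellPattern, SimulationConfig, compute_cxcl12_field,
                       generate_section)
from marrowmap.generate import _sample_pixels

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact section: quick to rasterize, same statistical structure."""
    return SimulationConfig(
        section_length_um=800.0, section_width_um=300.0,
        grid_resolution_um=2.0, n_vessels=15, n_stromal=25, n_cells=300,
        seed=42)


@pytest.fixture(scope="session")
def small_section(small_config):
    return generate_section(small_config)


@pytest.fixture(scope="session")
def small_field(small_config, small_section):
    geometry, _, stromal = small_section
    return compute_cxcl12_field(geometry, stromal, small_config)


def uniform_pattern(geometry, n: int, seed: int) -> CellPattern:
    """Cells placed uniformly over the marrow mask (beta = 0 shortcut)."""
    rng = np.random.default_rng(seed)
    pts = _sample_pixels(geometry, n, rng)
    return CellPattern(pts[:, 0], pts[:, 1])


def spawn_seeds(master: int, n: int) -> list[int]:
    """n reproducible integer sub-seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]
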