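"""Shared fixtures: synthetic lattices and cached scenario runs."""

from __future__ import annotations

import numpy as np
import pytest

import callusim as cs
from callusim.geometry import GAP, RegionLattice


def open_box_lattice(shape=(9, 9, 9), spacing_um=60.0) -> RegionLattice:
    """A fully open (all-gap) synthetic lattice for cell-rule unit tests."""
    config = cs.DomainConfig(cell_site_spacing_um=spacing_um)
    region = np.full(shape, GAP, dtype=np.int8)
    return RegionLattice(config=config, region=region)


@pytest.fixture
def box_lattice():
    return open_box_lattice()


@pytest.fixture
def small_domain():
    """A tiny but fully featured defect geometry (seconds to build)."""
    return cs.DomainConfig(
        cortex_outer_radius=1.0,
        cortex_inner_radius=0.5,
        bone_segment_length=2.0,
        gap_width=2.0,
        callus_outer_radius=1.5,
        callus_axial_overhang=0.5,
        cell_site_spacing_um=250.0,
        fe_element_size_callus=0.5,
        fe_element_size_outer=0.5,
        bv_voxel_size=0.1,
    )


@pytest.fixture
def small_lattice(small_domain):
    return cs.build_domain(small_domain)


SCENARIO_SEEDS = (1, 2, 3)
OUTPUT_DAYS = (14.0, 28.0, 42.0)
FIXTURE_SCALE = 0.25


def _run(scenario_kwargs, seed):
    domain, _ = cs.generate_fixture(FIXTURE_SCALE)
    config = cs.ScenarioConfig(
        recruitment="limited", seed=seed, output_days=OUTPUT_DAYS, **scenario_kwargs
    )
    return cs.run_scenario(config, domain)


@pytest.fixture(scope="session")
def scenario_runs():
    """Six-week fixture-scale runs of the key treatment scenarios.

    Cached for the whole session; these back the scenario-level behavior
    tests (bridging, plateau, treatment ordering).
    """
    runs = {}
    for name, kwargs in (
        ("control", dict(scenario="control")),
        ("bmp2_sponge", dict(scenario="bmp2", release="sponge")),
        ("bmp2_fast", dict(scenario="bmp2", release="fast")),
    ):
        for seed in SCENARIO_SEEDS:
            runs[(name, seed)] = _run(kwargs, seed)
    return runs
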