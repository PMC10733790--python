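"""Shared fixtures: small domains, parameter sets and cached replicate runs."""

from __future__ import annotations

import numpy as np
import pytest

from callusim.config import ParameterSet, RunOptions
from callusim.geometry import DomainSpec, build_domain


@pytest.fixture(scope="session")
def default_spec() -> DomainSpec:
    return DomainSpec()


@pytest.fixture(scope="session")
def quarter_spec() -> DomainSpec:
    return DomainSpec(quarter=True)


@pytest.fixture(scope="session")
def small_spec() -> DomainSpec:
    """Reduced geometry for fast simulation tests (scaled problem size)."""
    return DomainSpec(gap_width=500.0, cortex_thickness=100.0, bone_outer_radius=250.0,
                      callus_semi_axes=(500.0, 400.0), extent=1000.0, quarter=True)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.literature()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_masks():
    """A 12x12 all-healing grid for molecular-field oracle tests."""
    from callusim.geometry import DomainMasks

    n = 12
    healing = np.zeros((n, n), dtype=bool)
    healing[1:-1, 1:-1] = True
    empty = np.zeros((n, n), dtype=bool)
    return DomainMasks(
        healing_region=healing, cortex=empty.copy(),
        marrow_interface=empty.copy(), periosteal_boundary=empty.copy(),
        cortex_boundary=empty.copy(), resolution=10.0, origin=(0.0, 0.0),
        spec=None,
    )


@pytest.fixture(scope="session")
def calibrated_replicates(quarter_spec):
    """Five 3-day replicates with the GA-calibrated parameter overrides."""
    from callusim.scheduler import run_replicates

    return run_replicates(quarter_spec, ParameterSet.calibrated(), seeds=range(5),
                          days=3.0, opts=RunOptions(days=3.0))


@pytest.fixture(scope="session")
def validation_replicates():
    """Five 3-day replicates of the 0.7 mm-gap validation geometry."""
    from callusim.scheduler import run_replicates

    spec = DomainSpec(gap_width=700.0, quarter=True)
    return run_replicates(spec, ParameterSet.calibrated(), seeds=range(5),
                          days=3.0, opts=RunOptions(days=3.0))


@pytest.fixture(scope="session")
def literature_replicates(quarter_spec, params):
    """Five 3-day replicates with literature parameters (seeds 0-4).

    Session-scoped: these runs back several acceptance checks (day-1/day-3
    concentrations, fold changes, debris clearance, cytokine wave order).
    """
    from callusim.scheduler import run_replicates

    return run_replicates(quarter_spec, params, seeds=range(5), days=3.0,
                          opts=RunOptions(days=3.0))
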