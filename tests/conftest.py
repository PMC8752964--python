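"""Shared fixtures: synthetic reference maps and the heavier simulated studies.

Expensive studies are session-scoped so the accuracy, property and
acceptance tests reuse one set of simulations instead of regenerating them.
"""

from __future__ import annotations

import numpy as np
import pytest

from lesionmap import (
    BinaryLesionVolume,
    GRFSpec,
    ReferenceSpec,
    SimulationConfig,
    build_design,
    implied_incidence,
    make_reference_maps,
    simulate_mask_array,
)


@pytest.fixture(scope="session")
def ref_spec() -> ReferenceSpec:
    return ReferenceSpec()


@pytest.fixture(scope="session")
def ref_coeffs(ref_spec):
    return make_reference_maps(ref_spec)


@pytest.fixture(scope="session")
def mini_spec() -> ReferenceSpec:
    """Small-grid variant (~350 active voxels) for cheap end-to-end tests."""
    return ReferenceSpec(
        grid_shape=(12, 12, 10),
        centres=((4.0, 4.5, 4.5), (7.5, 7.0, 5.0)),
        radii=((2.6, 2.2, 2.4), (2.3, 2.6, 2.2)),
        edge_distance=1.6,
        # stronger, more spatially variable age effect than the desk default
        # so N=4000 recovery tests have signal well above estimation noise
        age_amplitude=0.06,
        age_tau=0.5,
        bump_sd=0.05,
        seed=777,
    )


@pytest.fixture(scope="session")
def mini_coeffs(mini_spec):
    return make_reference_maps(mini_spec)


def make_config(spec: ReferenceSpec, n_subjects: int, seed: int, scale: float = 1.5,
                n_reps: int = 1, **kwargs) -> SimulationConfig:
    return SimulationConfig(
        n_subjects=n_subjects,
        age_range=spec.age_range,
        age_center=spec.age_center,
        grf=GRFSpec(shape=spec.grid_shape, variance=1.0, scale=scale),
        base_seed=seed,
        n_reps=n_reps,
        **kwargs,
    )


def to_volumes(arr: np.ndarray, grid) -> list[BinaryLesionVolume]:
    return [BinaryLesionVolume(grid=grid, data=arr[i]) for i in range(arr.shape[0])]


@pytest.fixture(scope="session")
def big_sim(ref_spec, ref_coeffs):
    """10^4-subject study on the reference maps: per-voxel lesion counts
    alongside the exact model-implied incidence."""
    config = make_config(ref_spec, n_subjects=10_000, seed=41)
    design = build_design(config)
    arr = simulate_mask_array(ref_coeffs, design, config)
    counts = arr.sum(axis=0).astype(float)
    del arr
    expected = implied_incidence(ref_coeffs, design)
    return {
        "counts": counts,
        "n": config.n_subjects,
        "expected": expected,
        "design": design,
        "config": config,
    }
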