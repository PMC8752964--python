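"""Synthetic reference coefficient maps and summary tables.

Real studies learn the "truth" maps from a large reference cohort; this
module generates a stand-in with the same qualitative anatomy so the full
pipeline is exercisable without any data download: a pair of ellipsoidal
"periventricular" cores where lesion incidence is high, decaying towards a
low-incidence periphery (incidence spanning roughly 0.005-0.4 at mean age),
and a non-negative age-effect map peaked near the cores (higher age, higher
lesion probability, strongest periventricularly).  The geometry is
deliberately cartoonish; it makes no claim of clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .grf import GaussianRandomField, GRFSpec
from .simulator import CoefficientMaps, SimulationConfig, build_design, simulate_mask_array
from .summaries import AgeBinnedMedians, binned_medians
from .volume_io import VoxelGrid

__all__ = ["ReferenceSpec", "make_reference_maps", "make_reference_summaries"]


@dataclass(frozen=True)
class ReferenceSpec:
    """Geometry and effect sizes of the synthetic reference.

    Parameters
    ----------
    grid_shape : tuple
        Desk default 24 x 24 x 18 (~2,500 active voxels), small enough that
        hundred-replicate studies run in minutes.
    centres, radii : tuples
        Ellipsoid centres (voxel coordinates) and semi-axes of the two
        high-incidence cores.
    p_core, p_edge : float
        Lesion incidence at mean age at the core centre and at unit
        ellipsoidal distance beyond the shell; the intercept map
        interpolates ``ndtri(p_core) -> ndtri(p_edge)`` linearly in
        ellipsoidal distance, giving the target incidence span.
    age_amplitude : float
        Peak age effect on the probit scale per year of age (>= 0 keeps the
        aging effect monotone).
    age_tau : float
        Ellipsoidal-distance e-folding width of the age-effect peak.
    mask_floor : float
        Analysis mask keeps voxels whose implied incidence at the maximum
        age exceeds this floor.
    bump_sd, bump_scale : float
        Optional smooth seeded perturbation of the intercept (sd on the
        probit scale; GRF correlation length in voxels) so the maps are not
        perfectly symmetric.  Set ``bump_sd=0`` for a fully analytic map.
    age_range : tuple
        Reference age range in years (uncentered); centering offset is the
        midpoint.
    """

    grid_shape: tuple[int, ...] = (24, 24, 18)
    centres: tuple = ((9.0, 9.5, 8.5), (15.0, 14.5, 9.5))
    radii: tuple = ((4.5, 3.5, 4.0), (4.0, 4.5, 3.5))
    p_core: float = 0.4
    p_edge: float = 0.002
    edge_distance: float = 1.9
    age_amplitude: float = 0.02
    age_tau: float = 0.9
    mask_floor: float = 0.002
    bump_sd: float = 0.08
    bump_scale: float = 3.0
    age_range: tuple[float, float] = (45.0, 80.0)
    seed: int = 12345

    def __post_init__(self) -> None:
        if not (0 < self.p_edge < self.p_core < 1):
            raise ValueError("need 0 < p_edge < p_core < 1")
        if self.age_amplitude < 0:
            raise ValueError("age_amplitude must be >= 0 (monotone aging)")
        if not 0 < self.mask_floor < 1:
            raise ValueError("mask_floor must be in (0, 1)")

    @property
    def age_center(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


def _core_distance(spec: ReferenceSpec) -> np.ndarray:
    """Minimum ellipsoidal distance to any core (0 at a centre, 1 on the
    shell)."""
    coords = np.indices(spec.grid_shape).astype(float)
    dist = np.full(spec.grid_shape, np.inf)
    for centre, radii in zip(spec.centres, spec.radii):
        d2 = sum(
            ((coords[a] - centre[a]) / radii[a]) ** 2 for a in range(3)
        )
        dist = np.minimum(dist, np.sqrt(d2))
    return dist


def make_reference_maps(spec: ReferenceSpec) -> CoefficientMaps:
    """Smooth intercept and age-effect maps plus the analysis mask.

    Deterministic under ``spec.seed``.
    """
    grid = VoxelGrid(shape=spec.grid_shape)
    d = _core_distance(spec)
    b_hi = ndtri(spec.p_core)
    b_lo = ndtri(spec.p_edge)
    slope = (b_hi - b_lo) / spec.edge_distance
    intercept = b_hi - slope * d  # linear decay, keeps dropping beyond the edge
    if spec.bump_sd > 0:
        bump = GaussianRandomField(
            GRFSpec(shape=spec.grid_shape, variance=1.0, scale=spec.bump_scale,
                    seed=spec.seed)
        ).sample(1)[0]
        intercept = intercept + spec.bump_sd * bump
    age = spec.age_amplitude * np.exp(-(d**2) / (2.0 * spec.age_tau**2))
    eta_max_age = intercept + (spec.age_range[1] - spec.age_center) * age
    mask = ndtr(eta_max_age) > spec.mask_floor
    maps = np.stack([intercept, age])
    return CoefficientMaps(
        grid=grid,
        maps=maps,
        term_names=("intercept", "age"),
        analysis_mask=mask,
        covariate_center=np.array([0.0, spec.age_center]),
    )


def make_reference_summaries(
    spec: ReferenceSpec,
    n_subjects: int = 1000,
    scale: float = 1.5,
    seed: int | None = None,
) -> tuple[AgeBinnedMedians, pd.DataFrame]:
    """Simulate one large stack at a designated "true" scale and summarise it.

    Returns the age-binned medians (the tuning target that a real reference
    cohort would provide) and the per-subject covariate table.
    """
    coeffs = make_reference_maps(spec)
    seed = spec.seed + 1 if seed is None else seed
    config = SimulationConfig(
        n_subjects=n_subjects,
        age_range=spec.age_range,
        age_center=spec.age_center,
        grf=GRFSpec(shape=spec.grid_shape, variance=1.0, scale=scale),
        base_seed=seed,
    )
    design = build_design(config, rep=0)
    ages = design.values[:, 1] + design.centering[1]
    arr = simulate_mask_array(coeffs, design, config, rep=0)
    edges = np.quantile(ages, np.linspace(0, 1, 11))
    medians = binned_medians(arr, ages, edges)
    table = pd.DataFrame({"subject_id": [f"ref-{i:05d}" for i in range(n_subjects)],
                          "age": ages})
    return medians, table
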