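"""Lesion summaries, age-binned medians, and GRF scale tuning.

Three per-subject summaries describe a binary mask: total lesion volume
(number of lesion voxels), lesion count (number of 6-connected components,
i.e. face connectivity), and average lesion size (volume / count, undefined
for lesion-free subjects).  Tuning compares the medians of these summaries
across ten age-decile bins between a reference data set and stacks simulated
over a grid of GRF scale values, and picks the scale with the smallest
relative discrepancy; the per-scale curves are returned so the choice can
also be confirmed visually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grf import GaussianRandomField, GRFSpec
from .simulator import CoefficientMaps, SimulationConfig, build_design, simulate_mask_array
from .volume_io import BinaryLesionVolume

logger = logging.getLogger(__name__)

__all__ = [
    "LesionSummary",
    "AgeBinnedMedians",
    "summarize_mask",
    "summarize_stack",
    "binned_medians",
    "discrepancy",
    "tune_scale",
]

# 6-connectivity: voxels are neighbours only if they share a face
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

_SUMMARY_NAMES = ("total_volume", "lesion_count", "avg_size")


@dataclass(frozen=True)
class LesionSummary:
    """Per-subject lesion summaries; ``avg_size`` is NaN when count is 0."""

    total_volume: int
    lesion_count: int

    @property
    def avg_size(self) -> float:
        if self.lesion_count == 0:
            return float("nan")
        return self.total_volume / self.lesion_count


@dataclass
class AgeBinnedMedians:
    """Medians of the three summaries over ten age-decile bins.

    ``bin_edges`` holds the 11 decile edges of the reference age
    distribution; bins are half-open ``[q_k, q_{k+1})`` with the last bin
    closed.  ``medians`` is a (10, 3) array ordered (total_volume,
    lesion_count, avg_size); empty bins carry NaN and are flagged.
    Subjects with zero lesions enter the volume and count medians (as 0) but
    are excluded from avg_size medians, where the ratio is undefined.
    """

    bin_edges: np.ndarray
    medians: np.ndarray
    counts: np.ndarray
    empty_bins: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.medians,
            columns=list(_SUMMARY_NAMES),
            index=pd.IntervalIndex.from_breaks(np.round(self.bin_edges, 6), closed="left"),
        ).assign(n_subjects=self.counts)


def summarize_mask(volume) -> LesionSummary:
    """Total volume, 6-connected component count for one binary mask."""
    data = volume.data if isinstance(volume, BinaryLesionVolume) else np.asarray(volume)
    if not np.isin(data, (0, 1)).all():
        raise ValueError("mask must be binary")
    total = int(data.sum())
    if total == 0:
        return LesionSummary(total_volume=0, lesion_count=0)
    _, count = ndimage.label(data, structure=_STRUCT6)
    return LesionSummary(total_volume=total, lesion_count=int(count))


def summarize_stack(stack) -> pd.DataFrame:
    """Summaries for each subject; rows align with the stack order."""
    if isinstance(stack, np.ndarray):
        items = stack
    else:
        items = [vol.data for vol in stack]
    rows = []
    for data in items:
        s = summarize_mask(data)
        rows.append((s.total_volume, s.lesion_count, s.avg_size))
    return pd.DataFrame(rows, columns=list(_SUMMARY_NAMES))


def _bin_assign(ages: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign ages to the 10 decile bins ``[q_k, q_{k+1})``, last bin closed;
    values beyond the outer edges fall into the first/last bin."""
    idx = np.searchsorted(edges, ages, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def binned_medians(
    stack, ages: np.ndarray, reference_age_quantiles: np.ndarray
) -> AgeBinnedMedians:
    """Per-bin medians of the three summaries over subjects in each bin."""
    ages = np.asarray(ages, dtype=float)
    n = stack.shape[0] if isinstance(stack, np.ndarray) else len(stack)
    if ages.shape[0] != n:
        raise ValueError("ages must align with the stack")
    edges = np.asarray(reference_age_quantiles, dtype=float)
    if edges.ndim != 1 or edges.size != 11 or not np.all(np.diff(edges) > 0):
        raise ValueError("need 11 strictly increasing decile edges")
    table = summarize_stack(stack)
    bins = _bin_assign(ages, edges)
    medians = np.full((10, 3), np.nan)
    counts = np.zeros(10, dtype=int)
    for b in range(10):
        sel = bins == b
        counts[b] = int(sel.sum())
        if counts[b] == 0:
            continue
        sub = table[sel]
        medians[b, 0] = sub["total_volume"].median()
        medians[b, 1] = sub["lesion_count"].median()
        with_lesions = sub["avg_size"].dropna()
        medians[b, 2] = with_lesions.median() if len(with_lesions) else np.nan
    empty = counts == 0
    if empty.any():
        logger.warning("%d empty age bins; their medians are undefined", int(empty.sum()))
    return AgeBinnedMedians(bin_edges=edges, medians=medians, counts=counts, empty_bins=empty)


def discrepancy(
    sim: AgeBinnedMedians, ref: AgeBinnedMedians, eps: float = 1e-6
) -> float:
    """Mean relative distance between simulated and reference bin medians.

    ``mean over bins and summaries of |med_sim - med_ref| / (med_ref + eps)``;
    bins undefined on either side are skipped; all-undefined comparisons (or
    an all-empty simulated stack) score infinite.
    """
    diff = np.abs(sim.medians - ref.medians) / (np.abs(ref.medians) + eps)
    valid = np.isfinite(diff)
    if not valid.any():
        return float("inf")
    return float(diff[valid].mean())


def tune_scale(
    coeffs: CoefficientMaps,
    config: SimulationConfig,
    reference_medians: AgeBinnedMedians,
    scale_grid: Sequence[float],
) -> tuple[float, pd.DataFrame]:
    """Grid-search the GRF scale against reference age-binned medians.

    For each candidate scale one stack is simulated (single replicate) and
    scored with :func:`discrepancy`.  The search is conditional on the noise
    component: every scale reuses the same underlying white-noise seed, so
    only the field smoothness varies along the grid.  Returns the argmin
    scale and a per-scale table (discrepancy plus each summary's bin medians)
    for Fig.-style curve plots.
    """
    scale_grid = list(scale_grid)
    if not scale_grid:
        raise ValueError("scale grid is empty")
    design = build_design(config, rep=0)
    ages_raw = design.values[:, 1] + design.centering[1]
    base = config.grf if config.grf is not None else GRFSpec(shape=coeffs.grid.shape)
    rows = []
    best = (np.inf, None)
    for ell in scale_grid:
        spec = dc_replace(base, shape=coeffs.grid.shape, scale=float(ell))
        grf = GaussianRandomField(spec)  # same seed across ells: shared noise
        arr = simulate_mask_array(coeffs, design, config, rep=0, _grf=grf)
        if not arr.any():
            logger.warning("scale %g produced an all-empty stack", ell)
            rows.append({"scale": ell, "discrepancy": np.inf})
            continue
        med = binned_medians(arr, ages_raw, reference_medians.bin_edges)
        score = discrepancy(med, reference_medians)
        row = {"scale": ell, "discrepancy": score}
        for k, name in enumerate(_SUMMARY_NAMES):
            row[f"median_{name}"] = np.nanmedian(med.medians[:, k])
            for b in range(10):
                row[f"{name}_bin{b}"] = med.medians[b, k]
        rows.append(row)
        if score < best[0]:
            best = (score, float(ell))
    table = pd.DataFrame(rows)
    if best[1] is None:
        raise RuntimeError("every candidate scale produced an empty stack")
    return best[1], table
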