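"""Estimator-accuracy metrics across simulation replicates.

Voxel-wise Monte-Carlo summaries against the generating ("truth") maps:

* bias        ``B(s) = mean_r est_r(s) - truth(s)``
* MSE         ``mean_r (est_r(s) - truth(s))^2``
* PU          ``mean_r 1{est_r(s) < truth(s)}`` (probability of
  underestimation; 0.5 = median-unbiased)

plus per-replicate Pearson correlation with the truth, incidence-binned
reporting with right-closed edges ``(0.005, 0.01], (0.01, 0.05], (0.05, 0.1],
(0.1, 1]``, top-|z| Dice overlap, and false-positive counting on null
studies.  Replicate-voxel pairs with non-finite estimates (infinite MLEs
under separation) are excluded from the averages and counted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "bias_mse_pu",
    "bin_by_incidence",
    "correlation_per_rep",
    "dice_table",
    "dice_top_m",
    "false_positive_eval",
    "qq_data",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (0.005, 0.01, 0.05, 0.1, 1.0)


def bias_mse_pu(estimates: np.ndarray, truth: np.ndarray) -> dict[str, np.ndarray]:
    """Monte-Carlo bias, MSE and PU per voxel over replicates.

    Parameters
    ----------
    estimates : ndarray, (R, M)
        One estimate per replicate per voxel; non-finite entries are treated
        as excluded replicate-voxel pairs.
    truth : ndarray, (M,)
        Generating coefficients (constant across replicates).

    Returns
    -------
    dict with ``bias``, ``mse``, ``pu`` (each (M,); NaN where every
    replicate was excluded), ``n_used`` (replicates entering each voxel) and
    ``n_excluded``.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.ndim != 2 or truth.shape != (estimates.shape[1],):
        raise ValueError("estimates must be (R, M) with truth (M,)")
    finite = np.isfinite(estimates)
    n_used = finite.sum(axis=0)
    err = np.where(finite, estimates - truth[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = err.sum(axis=0) / n_used
        mse = (err**2).sum(axis=0) / n_used
        pu = np.where(finite, estimates < truth[None, :], 0).sum(axis=0) / n_used
    dead = n_used == 0
    for arr in (bias, mse, pu):
        arr[dead] = np.nan
    return {
        "bias": bias,
        "mse": mse,
        "pu": pu,
        "n_used": n_used,
        "n_excluded": estimates.shape[0] - n_used,
    }


def _bin_labels(edges) -> list[str]:
    return [f"({edges[k]:g},{edges[k + 1]:g}]" for k in range(len(edges) - 1)]


def assign_incidence_bins(p: np.ndarray, edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """Right-closed bin index per voxel; -1 for p at or below the floor."""
    p = np.asarray(p, dtype=float)
    edges = np.asarray(edges, dtype=float)
    # (e_k, e_{k+1}]: searchsorted with side='left' puts p == e_k in bin k-1
    idx = np.searchsorted(edges, p, side="left") - 1
    idx[p <= edges[0]] = -1
    idx[p > edges[-1]] = -1
    return idx


def bin_by_incidence(
    metrics: dict[str, np.ndarray],
    incidence: np.ndarray,
    edges=DEFAULT_BIN_EDGES,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Mean (sd) of each metric over voxels within incidence bins.

    Rows: one per bin (plus an overall ``(floor, 1]`` row), with voxel counts
    as in the accuracy-table headers; a bin with no voxels yields count 0 and
    NaN summaries.
    """
    incidence = np.asarray(incidence, dtype=float)
    idx = assign_incidence_bins(incidence, edges)
    labels = _bin_labels(edges)
    rows = []
    selections = []
    if include_overall:
        selections.append((f"({edges[0]:g},1]", idx >= 0))
    selections += [(lab, idx == k) for k, lab in enumerate(labels)]
    for label, sel in selections:
        row: dict = {"bin": label, "n_voxels": int(sel.sum())}
        for name, values in metrics.items():
            values = np.asarray(values, dtype=float)
            vals = values[sel]
            vals = vals[np.isfinite(vals)]
            row[f"{name}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{name}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


def correlation_per_rep(estimates: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between one replicate's estimates and the truth,
    over voxels with finite estimates."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    finite = np.isfinite(estimates) & np.isfinite(truth)
    if finite.sum() < 2:
        raise ValueError("need at least two voxels with finite estimates")
    e, t = estimates[finite], truth[finite]
    if e.std() == 0 or t.std() == 0:
        return float("nan")
    return float(np.corrcoef(e, t)[0, 1])


def _top_m(z: np.ndarray, m_star: int) -> np.ndarray:
    """Indices of the m_star largest |z|; ties broken by raster order."""
    absz = np.abs(np.asarray(z, dtype=float))
    absz = np.where(np.isfinite(absz), absz, -np.inf)
    order = np.lexsort((np.arange(absz.size), -absz))
    return order[:m_star]


def dice_top_m(z_ref: np.ndarray, z_est: np.ndarray, m_star: int) -> float:
    """Dice overlap of the top-``m_star`` |z| voxel sets of two maps.

    Both sets have exactly ``m_star`` voxels, so
    ``DSC = |intersection| / m_star``.
    """
    z_ref = np.asarray(z_ref).ravel()
    z_est = np.asarray(z_est).ravel()
    if z_ref.shape != z_est.shape:
        raise ValueError("z maps must share a voxel set")
    if not 0 < m_star <= z_ref.size:
        raise ValueError(f"m_star must be in [1, {z_ref.size}]")
    a = set(_top_m(z_ref, m_star).tolist())
    b = set(_top_m(z_est, m_star).tolist())
    return len(a & b) / m_star


def dice_table(z_ref: np.ndarray, z_reps: dict, m_stars) -> pd.DataFrame:
    """Mean top-|z| Dice overlap per method and per set size.

    ``z_reps`` maps a method name to a sequence of per-replicate z maps (each
    aligned with ``z_ref``); the table reports the across-replicate mean DSC
    for every ``m_star``.
    """
    rows = []
    for method, maps in z_reps.items():
        row: dict = {"method": method}
        for m_star in m_stars:
            row[f"dsc_m{m_star}"] = float(
                np.mean([dice_top_m(z_ref, z, m_star) for z in maps])
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")


def false_positive_eval(
    z: np.ndarray,
    incidence: np.ndarray,
    threshold: float = 1.96,
    edges=DEFAULT_BIN_EDGES,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-incidence-bin count and rate of |z| above ``threshold`` under a
    null-generated study; non-finite z (separated fits) are excluded.

    A Benjamini-Hochberg flag count at ``fdr_level`` is reported alongside as
    a secondary summary (computed over all binned voxels jointly).
    """
    z = np.asarray(z, dtype=float)
    incidence = np.asarray(incidence, dtype=float)
    idx = assign_incidence_bins(incidence, edges)
    finite = np.isfinite(z)
    in_scope = (idx >= 0) & finite
    pvals = 2.0 * ndtr(-np.abs(z[in_scope]))
    n_bh = _bh_count(pvals, fdr_level)
    labels = _bin_labels(edges)
    rows = []
    selections = [(f"({edges[0]:g},1]", in_scope)]
    selections += [(lab, in_scope & (idx == k)) for k, lab in enumerate(labels)]
    for label, sel in selections:
        n = int(sel.sum())
        hits = int((np.abs(z[sel]) > threshold).sum())
        rows.append(
            {
                "bin": label,
                "n_voxels": n,
                "n_significant": hits,
                "rate_pct": 100.0 * hits / n if n else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("bin")
    out.attrs["n_bh_significant"] = n_bh
    out.attrs["n_excluded_nonfinite"] = int(((idx >= 0) & ~finite).sum())
    return out


def _bh_count(pvals: np.ndarray, level: float) -> int:
    """Number of Benjamini-Hochberg discoveries at ``level``."""
    p = np.sort(np.asarray(pvals, dtype=float))
    n = p.size
    if n == 0:
        return 0
    thresh = level * np.arange(1, n + 1) / n
    below = np.nonzero(p <= thresh)[0]
    return 0 if below.size == 0 else int(below[-1] + 1)


def qq_data(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal QQ pairs (theoretical, empirical) for a z sample."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 10:
        raise ValueError("need at least 10 finite z values")
    emp = np.sort(z)
    pp = (np.arange(1, z.size + 1) - 0.5) / z.size
    return ndtri(pp), emp
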