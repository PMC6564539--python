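"""Per-group structural covariance network construction.

The pipeline: regress each ROI's morphometric value (cortical thickness or
local gyrification index) on age, sex, age*sex and the subject's global
measure; correlate the residuals across subjects (ROI x ROI Pearson r);
mark edges *eligible* when the correlation is positive and significant at
``alpha``; then threshold by density, keeping the strongest eligible edges,
so that every group's graph has the same edge count at each density.

Edge sets are nested across densities by construction, and the minimum
density is searched as the smallest grid value at which every group's
graph is a single connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import n_components

__all__ = [
    "residualize",
    "residualize_rois",
    "correlation_matrix",
    "edge_eligibility",
    "edge_ranking",
    "threshold_by_density",
    "find_min_density",
    "density_grid",
    "build_group_stack",
    "GroupNetworkStack",
]


def residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``y`` on the ``design`` matrix.

    Uses a least-squares (pseudoinverse) fit, so rank-deficient designs with
    redundant columns still give well-defined residuals.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(design, dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def residualize_rois(
    morphometry: pd.DataFrame,
    covariates: pd.DataFrame,
    roi_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Residualize each ROI on intercept + age + sex + age*sex + global measure.

    ``morphometry`` holds one row per subject and one column per ROI;
    ``covariates`` (aligned on index) must carry ``age`` and ``sex`` columns.
    The global measure is the subject's mean across ROI columns (mean
    cortical thickness, or total gyrification up to the 1/148 factor, which
    is absorbed by the regression coefficient).
    """
    if roi_columns is None:
        roi_columns = list(morphometry.columns)
    y = morphometry[roi_columns].to_numpy(dtype=float)
    if y.shape[0] < 5:
        raise ValueError("ROI residualization needs >= 5 subjects")
    cov = covariates.loc[morphometry.index]
    age = cov["age"].to_numpy(dtype=float)
    sex = cov["sex"].to_numpy(dtype=float)
    if np.isnan(age).any() or np.isnan(sex).any():
        raise ValueError("covariates must be complete (no missing age/sex)")
    glob = y.mean(axis=1)
    constant = [name for name, col in (("age", age), ("global measure", glob))
                if np.ptp(col) == 0]
    if constant:
        raise ValueError(f"collinear design: constant column(s) {constant}")
    design = np.column_stack([np.ones_like(age), age, sex, age * sex, glob])
    res = residualize(y, design)
    return pd.DataFrame(res, index=morphometry.index, columns=roi_columns)


def correlation_matrix(residuals: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, int]:
    """Pairwise Pearson correlation of ROI residuals.

    Returns ``(r_matrix, n_subjects)``.  Constant columns are flagged with a
    warning and their correlations set to 0 (undefined-as-zero), so they can
    never form eligible edges.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("correlation needs >= 4 subjects")
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant ROI column(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r)
    r[np.isnan(r)] = 0.0
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return r, n


def edge_eligibility(corr: np.ndarray, n_subjects: int, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of edges that are positive and significant at ``alpha``.

    Significance by the t statistic r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom, two-sided.  The diagonal is never eligible.
    """
    if n_subjects < 4:
        raise ValueError("eligibility needs >= 4 subjects")
    r = np.asarray(corr, dtype=float)
    df = n_subjects - 2
    rr = np.clip(r, -0.9999999999, 0.9999999999)
    t = rr * np.sqrt(df / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    mask = (r > 0) & (p < alpha)
    np.fill_diagonal(mask, False)
    return mask


def edge_ranking(corr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Eligible upper-triangle edges ordered by descending r, ties by (i, j).

    Returns an array of shape (n_eligible, 2) of node-index pairs.  The
    lexicographic tie rule makes density thresholding deterministic.
    """
    r = np.asarray(corr, dtype=float)
    iu, ju = np.triu_indices(r.shape[0], k=1)
    keep = mask[iu, ju]
    iu, ju, rv = iu[keep], ju[keep], r[iu, ju][keep]
    order = np.lexsort((ju, iu, -rv))
    return np.column_stack([iu[order], ju[order]])


def n_edges_at_density(n_rois: int, density: float) -> int:
    """round-half-away-from-zero of density * R(R-1)/2."""
    possible = n_rois * (n_rois - 1) / 2
    return int(np.floor(density * possible + 0.5))


def threshold_by_density(
    corr: np.ndarray,
    mask: np.ndarray,
    density: float,
    ranking: np.ndarray | None = None,
) -> np.ndarray:
    """Binary adjacency with the strongest eligible edges at the given density.

    If fewer eligible edges exist than the density asks for, all are kept
    and a warning reports the achieved density.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if density > 0.5:
        raise ValueError("densities above 0.5 are not considered meaningful")
    r = np.asarray(corr, dtype=float)
    n = r.shape[0]
    if ranking is None:
        ranking = edge_ranking(r, mask)
    m = n_edges_at_density(n, density)
    if len(ranking) < m:
        warnings.warn(
            f"only {len(ranking)} eligible edges for requested {m} "
            f"(achieved density {len(ranking) / (n * (n - 1) / 2):.4f})"
        )
        m = len(ranking)
    adj = np.zeros((n, n))
    sel = ranking[:m]
    adj[sel[:, 0], sel[:, 1]] = 1.0
    adj[sel[:, 1], sel[:, 0]] = 1.0
    return adj


def find_min_density(
    corrs: list[np.ndarray],
    masks: list[np.ndarray],
    floor: float = 0.01,
    increment: float = 0.01,
    max_density: float = 0.5,
) -> float:
    """Smallest grid density at which every group's graph is connected.

    Scans ``floor, floor+increment, ...`` up to ``max_density``; raises with
    per-group component counts if no density connects all groups.
    """
    if not corrs:
        raise ValueError("need at least one group")
    rankings = [edge_ranking(c, m) for c, m in zip(corrs, masks)]
    last_counts = None
    for step_i in range(int(np.floor((max_density - floor) / increment + 1e-9)) + 1):
        d = round(floor + step_i * increment, 10)
        counts = []
        for c, mk, rk in zip(corrs, masks, rankings):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                adj = threshold_by_density(c, mk, d, ranking=rk)
            counts.append(n_components(adj))
        if all(k == 1 for k in counts):
            return d
        last_counts = counts
    raise ValueError(
        f"no density <= {max_density} renders all groups connected "
        f"(component counts at {max_density}: {last_counts})"
    )


def density_grid(d_min: float, d_max: float, step: float = 0.01) -> np.ndarray:
    """Ordered densities d_min, d_min+step, ..., <= d_max (all in (0, 0.5])."""
    if not 0 < d_min <= d_max <= 0.5:
        raise ValueError("require 0 < d_min <= d_max <= 0.5")
    n = int(np.floor((d_max - d_min) / step + 1e-9)) + 1
    return np.round(d_min + step * np.arange(n), 10)


@dataclass
class GroupNetworkStack:
    """One group's correlation matrix and its binary graphs over a density grid."""

    label: object
    corr: np.ndarray = field(repr=False)
    n_subjects: int = 0
    mask: np.ndarray = field(default=None, repr=False)
    densities: np.ndarray = field(default=None, repr=False)
    adjacency: list[np.ndarray] = field(default=None, repr=False)


def build_group_stack(
    residuals: pd.DataFrame | np.ndarray,
    densities: np.ndarray,
    label: object = None,
    alpha: float = 0.05,
) -> GroupNetworkStack:
    """Correlate residuals and threshold at each grid density for one group."""
    corr, n = correlation_matrix(residuals)
    mask = edge_eligibility(corr, n, alpha=alpha)
    ranking = edge_ranking(corr, mask)
    adj = [threshold_by_density(corr, mask, d, ranking=ranking) for d in densities]
    return GroupNetworkStack(
        label=label, corr=corr, n_subjects=n, mask=mask,
        densities=np.asarray(densities, dtype=float), adjacency=adj,
    )
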