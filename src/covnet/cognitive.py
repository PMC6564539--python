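"""Cognitive subtyping: score transformation, residualization, k-means profiles.

Subjects are grouped by common profiles of cognitive functioning across a
six-test battery (premorbid FSIQ, HVLT-R immediate recall, RVIP A',
Stroop color-word, IDED total adjusted errors, IGT net score).  The IDED
error count is log-transformed and sign-flipped so that, like the other
tests, higher means better.  Scores are then regressed on age and education
and the residuals — z-scored per test, since the tests live on
incommensurate scales — are partitioned by Euclidean k-means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .network import residualize

__all__ = [
    "TEST_COLUMNS",
    "transform_ided",
    "impute_single_missing",
    "residualize_scores",
    "kmeans_profiles",
    "ClusterAssignment",
    "cluster_cognitive",
]

TEST_COLUMNS = ["fsiq", "hvlt_immediate", "rvip_a", "stroop_cw", "ided_errors", "igt_net"]


def transform_ided(errors: np.ndarray, offset: float = 1.0) -> np.ndarray:
    """-log10(errors + offset): right-skew corrected, higher = better.

    Error counts must be non-negative; the offset keeps zero-error subjects
    finite.
    """
    e = np.asarray(errors, dtype=float)
    if np.nanmin(e) < 0:
        raise ValueError("IDED error counts must be non-negative")
    return -np.log10(e + offset)


def impute_single_missing(table: pd.DataFrame, test_columns: list[str]) -> pd.DataFrame:
    """Fill at most one missing test per subject with its age/education OLS prediction.

    Subjects missing more than one test violate the inclusion rule and are
    rejected.  Imputing with the covariate-model prediction means the
    subject's residual for that test is exactly 0 (the residual-space
    column mean), a neutral value for clustering.
    """
    miss = table[test_columns].isna().sum(axis=1)
    if (miss > 1).any():
        bad = list(table.index[miss > 1])
        raise ValueError(f"subjects missing more than one test: {bad}")
    out = table.copy()
    design_full = np.column_stack(
        [np.ones(len(table)), table["age"].to_numpy(float), table["education"].to_numpy(float)]
    )
    for col in test_columns:
        y = out[col].to_numpy(dtype=float)
        nan = np.isnan(y)
        if not nan.any():
            continue
        x_obs = design_full[~nan]
        beta, *_ = np.linalg.lstsq(x_obs, y[~nan], rcond=None)
        y[nan] = design_full[nan] @ beta
        out[col] = y
    return out


def residualize_scores(
    table: pd.DataFrame, test_columns: list[str] | None = None
) -> pd.DataFrame:
    """Per-test OLS residuals on intercept + age + education.

    Missing age or education is rejected; a design in which neither
    covariate varies is rejected as rank-deficient.
    """
    if test_columns is None:
        test_columns = [c for c in TEST_COLUMNS if c in table.columns]
    age = table["age"].to_numpy(dtype=float)
    edu = table["education"].to_numpy(dtype=float)
    if np.isnan(age).any() or np.isnan(edu).any():
        raise ValueError("age and education must be complete")
    if (age <= 0).any() or (edu <= 0).any():
        raise ValueError("age and education must be positive")
    design = np.column_stack([np.ones_like(age), age, edu])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("rank-deficient design: age and education are both constant")
    y = table[test_columns].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing test scores; impute before residualizing")
    res = residualize(y, design)
    return pd.DataFrame(res, index=table.index, columns=test_columns)


class ClusterAssignment:
    """k-means result: labels (1..k), centroids, z-profiles, WCSS."""

    def __init__(self, labels, centroids, z_profiles, wcss, index):
        self.labels = pd.Series(labels, index=index, name="cluster")
        self.centroids = centroids          # k x n_tests, residual space
        self.z_profiles = z_profiles        # k x n_tests, sample-referenced z
        self.wcss = wcss

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def kmeans_profiles(
    residuals: pd.DataFrame, k: int = 3, seed: int = 0, n_init: int = 50,
    standardize: bool = True,
) -> ClusterAssignment:
    """Euclidean k-means on (z-scored) residual profiles.

    Clusters are relabelled 1..k by *descending* mean z-profile, so cluster 1
    is always the highest-functioning profile and the labelling is stable
    across runs and seeds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = residuals.to_numpy(dtype=float)
    if len(x) < k:
        raise ValueError("need at least k subjects")
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd if standardize else x.copy()
    if k == 1:
        labels0 = np.zeros(len(x), dtype=int)
        centers = z.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels0 = km.fit_predict(z)
        centers = km.cluster_centers_
    # deterministic relabelling: descending mean profile height
    order = np.argsort(-centers.mean(axis=1), kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    labels = rank[labels0] + 1
    wcss = float(((z - centers[labels0]) ** 2).sum())
    centroids = np.vstack([
        residuals.to_numpy(float)[labels == c].mean(axis=0) for c in range(1, k + 1)
    ])
    zs = (x - x.mean(axis=0)) / np.where(x.std(axis=0, ddof=1) == 0, 1, x.std(axis=0, ddof=1))
    z_profiles = np.vstack([zs[labels == c].mean(axis=0) for c in range(1, k + 1)])
    return ClusterAssignment(labels, centroids, z_profiles, wcss, residuals.index)


def cluster_cognitive(
    table: pd.DataFrame, k: int = 3, seed: int = 0, ided_offset: float = 1.0,
    n_init: int = 50,
) -> ClusterAssignment:
    """Full cognitive stage: impute, transform IDED, residualize, k-means."""
    test_cols = [c for c in TEST_COLUMNS if c in table.columns]
    work = impute_single_missing(table, test_cols)
    if "ided_errors" in work.columns:
        work = work.assign(ided_errors=transform_ided(work["ided_errors"], ided_offset))
    res = residualize_scores(work, test_cols)
    return kmeans_profiles(res, k=k, seed=seed, n_init=n_init)
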