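"""Synthetic multi-group cohorts with planted covariance topology.

Real structural covariance studies rest on clinical MRI cohorts that are
rarely deposited.  This module generates cohorts whose statistical structure
is known by construction, so every downstream stage — residualization,
correlation networks, density thresholding, graph metrics, FDA permutation
comparison — can be validated end to end:

* ROI morphometry is multivariate normal per group with a *blocked
  compound-symmetric* correlation matrix (correlation ``within_block_r``
  inside each planted block, ``between_block_r`` across blocks), plus linear
  age / sex / age*sex effects.  Under this law the Pearson covariance
  network has known modular topology.
* Cognitive test scores follow planted cluster centroids (z units) mapped
  to test-native scales, with linear age / education effects and Gaussian
  within-cluster noise; true labels are returned for recovery testing.
* ``plant_topology_contrast`` raises one group's within-block correlation,
  producing the segregation/integration contrast (higher clustering and
  transitivity, longer path length, lower global efficiency) that the
  group-comparison stage must detect.

All randomness flows through numpy's PCG64 via ``SeedSequence(seed)``, with
per-group child seeds spawned deterministically; equal seeds give
bit-identical tables across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "CognitiveSpec",
    "Cohort",
    "generate_morphometry",
    "generate_cognitive",
    "plant_topology_contrast",
    "block_correlation",
    "COGNITIVE_TESTS",
    "write_cohort",
    "read_cohort",
]

#: test name -> (native-scale mean, native-scale SD per planted z unit).
#: IDED is handled separately as a positively skewed error count.
COGNITIVE_TESTS = {
    "fsiq": (98.0, 9.0),
    "hvlt_immediate": (25.0, 5.0),
    "rvip_a": (0.90, 0.04),
    "stroop_cw": (45.0, 10.0),
    "ided_errors": None,
    "igt_net": (2.0, 20.0),
}


def _per_group(value, n_groups: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_groups, float(arr))
    if arr.shape != (n_groups,):
        raise ValueError(f"expected scalar or length-{n_groups} sequence, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one multi-group morphometry cohort.

    ``within_block_r`` / ``between_block_r`` may be scalars (shared across
    groups) or one value per group.  ``block_partition`` assigns each ROI to
    a block; by default ROIs are split into ``n_blocks`` contiguous
    near-equal blocks.
    """

    group_sizes: tuple[int, ...] = (60, 60, 60)
    n_rois: int = 148
    n_blocks: int = 4
    block_partition: tuple[int, ...] | None = None
    within_block_r: float | tuple[float, ...] = 0.45
    between_block_r: float | tuple[float, ...] = 0.1
    global_loading_spread: float = 0.8
    bridges_per_block_pair: int | None = None   # None -> scaled to block size
    bridge_r: float = 0.5
    bridge_block_discount: float = 0.8
    homotopic_r: float = 0.7
    n_secondary: int = 3
    secondary_var: float = 0.1
    baseline: float = 2.5          # mm, a typical mean cortical thickness
    age_coef: float = -0.005       # mm per year, mild age-related thinning
    sex_coef: float = 0.05         # mm offset for sex = 1
    age_sex_coef: float = 0.0
    noise_sd: float = 0.15         # mm residual SD per ROI
    age_range: tuple[float, float] = (25.0, 60.0)
    sex_p: float = 0.8             # Bernoulli probability of sex = 1
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def partition(self) -> np.ndarray:
        if self.block_partition is not None:
            part = np.asarray(self.block_partition, dtype=int)
            if part.shape != (self.n_rois,):
                raise ValueError("block_partition must assign every ROI to one block")
            return part
        chunks = np.array_split(np.arange(self.n_rois), self.n_blocks)
        return np.concatenate([np.full(len(c), b) for b, c in enumerate(chunks)])

    def validate(self) -> None:
        if any(n < 4 for n in self.group_sizes):
            raise ValueError("every group needs >= 4 subjects for correlation p-values")
        w = _per_group(self.within_block_r, self.n_groups)
        b = _per_group(self.between_block_r, self.n_groups)
        if np.any(b < 0) or np.any(w < b):
            raise ValueError("require within_block_r >= between_block_r >= 0")
        if np.any(w >= 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        part = self.partition()
        h = self.global_loadings()
        bridges = self.bridge_pairs()
        for g in range(self.n_groups):
            target = block_correlation(part, w[g], b[g], loadings=h,
                                       bridges=bridges, bridge_r=self.bridge_r,
                                       bridge_block_discount=self.bridge_block_discount,
                                       homotopic_r=self.homotopic_r,
                                       secondary=self.secondary_loadings())
            lam_min = np.linalg.eigvalsh(target)[0]
            if lam_min <= 1e-10:
                raise ValueError(
                    f"group {g}: blocked correlation with within_r={w[g]}, "
                    f"between_r={b[g]} is not positive definite (min eig {lam_min:.3g})"
                )

    def global_loadings(self) -> np.ndarray:
        """Per-ROI deviation of the global-factor loading, mean-centered.

        Drawn deterministically from the cohort seed and shared by all
        groups.  Heterogeneous loadings are what keep covariance networks
        connectable after the pipeline regresses out the global measure:
        a constant between-block correlation is exactly a global factor and
        would vanish entirely under that regression.
        """
        if self.global_loading_spread == 0:
            return np.zeros(self.n_rois)
        child = np.random.SeedSequence(self.seed).spawn(1)[0]
        rng = np.random.default_rng(child)
        h = rng.uniform(-self.global_loading_spread, self.global_loading_spread,
                        size=self.n_rois)
        return h - h.mean()

    def secondary_loadings(self) -> np.ndarray:
        """Signed loadings of the secondary covariance modes, shared by groups.

        Each of ``n_secondary`` modes assigns every ROI a loading of
        +/- sqrt(secondary_var) with equal probability.  Sign-balanced modes
        add broad positive *and* negative correlation tails across blocks
        while staying orthogonal (in expectation) to the global mean, so the
        positive tails survive the global-measure regression — the feature
        that makes real covariance networks dense far beyond their modular
        skeleton.
        """
        if self.n_secondary == 0 or self.secondary_var == 0:
            return np.zeros((0, self.n_rois))
        child = np.random.SeedSequence(self.seed).spawn(3)[2]
        rng = np.random.default_rng(child)
        signs = rng.choice([-1.0, 1.0], size=(self.n_secondary, self.n_rois))
        return np.sqrt(self.secondary_var) * signs

    def bridge_pairs(self) -> np.ndarray:
        """Planted strong between-block ROI pairs, shared by all groups.

        Regressing out the global measure cancels any *uniform* between-block
        correlation (it is exactly a global factor), so connectivity across
        blocks — which real cortical networks always show — must come from
        specific strong inter-block correlations.  A few ``bridge_r`` pairs
        per block pair emulate such inter-lobe couplings.  Anchors are each
        block's nodes with the *lowest* global-factor loading: those carry
        the most free variance and the smallest global-mean footprint, so
        their bridges survive the global-measure regression (mirroring
        connector regions that sit outside the dominant covariance mode).
        No bridges are planted when ``between_block_r`` is 0.
        """
        b = _per_group(self.between_block_r, self.n_groups)
        part = self.partition()
        n_bridges = self.bridges_per_block_pair
        if n_bridges is None:
            # roughly one bridge per five block members, so small blocks are
            # not drained by too many variance-hungry anchors
            min_block = int(np.bincount(part).min())
            n_bridges = max(1, min(3, min_block // 5))
        if n_bridges == 0 or np.all(b == 0):
            return np.zeros((0, 2), dtype=int)
        h = self.global_loadings()
        blocks = np.unique(part)
        by_block = {
            k: list(np.flatnonzero(part == k)[np.argsort(h[part == k], kind="stable")])
            for k in blocks
        }
        counters = {k: 0 for k in blocks}

        def next_anchor(k):
            nodes = by_block[k]
            node = nodes[counters[k] % len(nodes)]
            counters[k] += 1
            return node

        pairs = []
        for t in range(n_bridges):
            for a_i, k in enumerate(blocks):
                for l in blocks[a_i + 1:]:
                    pairs.append((next_anchor(k), next_anchor(l)))
        return np.array(sorted(set(map(tuple, pairs))), dtype=int)


def block_correlation(
    partition: np.ndarray,
    within_r: float,
    between_r: float,
    loadings: np.ndarray | None = None,
    bridges: np.ndarray | None = None,
    bridge_r: float = 0.5,
    bridge_block_discount: float = 0.8,
    homotopic_r: float = 0.0,
    secondary: np.ndarray | None = None,
) -> np.ndarray:
    """Target correlation matrix for one group, built as an explicit factor model.

    Components, in order of their claim on each node's unit variance budget:

    1. *block factors* — loading sqrt(within_r - between_r) per node (bridge
       anchors discounted), giving the planted modular skeleton;
    2. *homotopic pairs* — consecutive same-block ROIs coupled toward
       ``homotopic_r``, emulating the dominant bilateral couplings of real
       morphometry and guaranteeing every node one strong edge;
    3. *bridge factors* — a few strong inter-block pairs per block pair
       (connector regions) that keep the graph connectable after the
       pipeline regresses out the global measure;
    4. a *global factor* with heterogeneous per-node loadings
       sqrt(between_r) * (1 + h_i), capped by the remaining budget — this
       carries the nominal between-block correlation;
    5. *secondary signed modes* soaking up leftover budget, adding the broad
       positive/negative correlation tails real covariance matrices show.

    Because every component is a factor loading and idiosyncratic variance
    stays positive, the matrix is positive definite by construction.
    """
    n = len(partition)
    same = partition[:, None] == partition[None, :]
    u = np.ones(n) if loadings is None else 1.0 + np.asarray(loadings, dtype=float)
    cap = 0.95

    a = np.full(n, np.sqrt(max(within_r - between_r, 0.0)))
    if bridges is not None and len(bridges):
        a[np.unique(bridges)] *= bridge_block_discount
    target = np.where(same, np.outer(a, a), 0.0)
    used = a**2

    def add_pair_factor(i, j, r_target):
        want = max(r_target - target[i, j], 0.0)
        c2 = min(want, max(cap - used[i], 0.0), max(cap - used[j], 0.0))
        target[i, j] += c2
        target[j, i] = target[i, j]
        used[i] += c2
        used[j] += c2

    if bridges is not None and len(bridges):
        for i, j in bridges:
            add_pair_factor(i, j, bridge_r)
    if homotopic_r > 0:
        for i in range(0, n - 1, 2):
            if partition[i] == partition[i + 1]:
                add_pair_factor(i, i + 1, homotopic_r)
    if between_r > 0:
        g = np.sqrt(between_r) * u
        g = np.minimum(g, np.sqrt(np.maximum(cap - used, 0.0)))
        target += np.outer(g, g)
        used += g**2
    if secondary is not None and len(secondary):
        sec_var = (secondary**2).sum(axis=0)
        rem = np.maximum(cap - used, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.sqrt(np.minimum(1.0, np.where(sec_var > 0, rem / sec_var, 1.0)))
        loads = secondary * scale[None, :]
        target += loads.T @ loads
    np.fill_diagonal(target, 1.0)
    return _repair_correlation(target)


def _repair_correlation(target: np.ndarray, max_violation: float = 0.1) -> np.ndarray:
    """Project a near-correlation matrix to the PD cone by eigenvalue clipping.

    Sparse bridge entries layered on the blocked structure can nudge the
    smallest eigenvalue slightly negative; clipping at a small positive
    floor and renormalizing the diagonal restores a valid correlation
    matrix while leaving the planted pattern essentially unchanged.  A
    violation beyond ``max_violation`` indicates inconsistent parameters
    and is raised instead of silently repaired.
    """
    lam, vec = np.linalg.eigh(target)
    if lam[0] >= 1e-8:
        return target
    if lam[0] < -max_violation:
        raise ValueError(
            f"target correlation is far from positive definite (min eig {lam[0]:.3g}); "
            "within/between/bridge parameters are mutually inconsistent"
        )
    fixed = (vec * np.clip(lam, 1e-6, None)) @ vec.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class Cohort:
    """Generated morphometry cohort: tables plus the planted ground truth."""

    morphometry: pd.DataFrame       # subjects x ROIs, mm
    covariates: pd.DataFrame        # age, sex, group per subject
    target_corr: list[np.ndarray] = field(repr=False)   # per group
    block_partition: np.ndarray = field(repr=False)
    spec: CohortSpec = None

    @property
    def roi_names(self) -> list[str]:
        return list(self.morphometry.columns)

    @property
    def group_labels(self) -> np.ndarray:
        return self.covariates["group"].to_numpy()


def generate_morphometry(spec: CohortSpec) -> Cohort:
    """Draw one cohort: per-group multivariate-normal ROI values + covariates.

    Deterministic given ``spec.seed``: per-group generators are spawned from
    a single ``SeedSequence``.
    """
    spec.validate()
    part = spec.partition()
    w = _per_group(spec.within_block_r, spec.n_groups)
    b = _per_group(spec.between_block_r, spec.n_groups)
    h = spec.global_loadings()
    bridges = spec.bridge_pairs()
    roi_names = [f"roi_{i:03d}" for i in range(spec.n_rois)]
    frames, cov_frames, targets = [], [], []
    # children 0 and 1 are reserved for the loadings and bridge draws
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_groups + 2)[2:]
    offset = 0
    for g, (n, child) in enumerate(zip(spec.group_sizes, children)):
        rng = np.random.default_rng(child)
        target = block_correlation(part, w[g], b[g], loadings=h,
                                   bridges=bridges, bridge_r=spec.bridge_r,
                                   bridge_block_discount=spec.bridge_block_discount,
                                   homotopic_r=spec.homotopic_r,
                                   secondary=spec.secondary_loadings())
        targets.append(target)
        chol = np.linalg.cholesky(target)
        z = rng.standard_normal((n, spec.n_rois)) @ chol.T
        age = rng.uniform(*spec.age_range, size=n)
        sex = (rng.uniform(size=n) < spec.sex_p).astype(float)
        age_c = age - np.mean(spec.age_range)
        effects = (
            spec.age_coef * age_c[:, None]
            + spec.sex_coef * sex[:, None]
            + spec.age_sex_coef * (age_c * sex)[:, None]
        )
        values = spec.baseline + effects + spec.noise_sd * z
        idx = [f"sub_{offset + i:04d}" for i in range(n)]
        offset += n
        frames.append(pd.DataFrame(values, index=idx, columns=roi_names))
        cov_frames.append(pd.DataFrame({"age": age, "sex": sex, "group": g}, index=idx))
    morph = pd.concat(frames)
    cov = pd.concat(cov_frames)
    morph.index.name = cov.index.name = "subject_id"
    return Cohort(morphometry=morph, covariates=cov, target_corr=targets,
                  block_partition=part, spec=spec)


def plant_topology_contrast(
    base: CohortSpec, delta_within_r: float, target_group: int
) -> CohortSpec:
    """Spec identical to ``base`` with one group's within-block r raised.

    This plants higher network segregation (and, with between-block
    connections relatively weaker, poorer integration) in the target group.
    A zero delta returns the base spec unchanged.
    """
    if delta_within_r == 0:
        return base
    w = _per_group(base.within_block_r, base.n_groups).copy()
    w[target_group] = w[target_group] + delta_within_r
    if w[target_group] >= 1:
        raise ValueError(
            f"contrast pushes within_block_r to {w[target_group]:.3f} >= 1"
        )
    new = dataclasses.replace(base, within_block_r=tuple(w))
    new.validate()
    return new


@dataclass(frozen=True)
class CognitiveSpec:
    """Planted cluster structure for the six-test cognitive battery.

    ``cluster_centroids`` is K x 6 in z units (test order as in
    ``COGNITIVE_TESTS``); scores are mapped onto test-native scales, so the
    IDED column comes out as a positively skewed non-negative error count.
    """

    cluster_centroids: tuple[tuple[float, ...], ...] = (
        (0.8, 0.8, 0.8, 0.8, 0.8, 0.8),
        (0.0, 0.0, 0.0, 0.0, -0.8, 0.0),
        (-0.8, -0.8, -0.8, -0.8, -0.8, 0.3),
    )
    within_cluster_sd: float = 0.5
    age_effect: float = -0.02      # z units per year of age
    education_effect: float = 0.05  # z units per year of education
    age_range: tuple[float, float] = (25.0, 60.0)
    education_mean: float = 10.5
    education_sd: float = 2.3
    seed: int = 0

    def validate(self) -> None:
        cent = np.asarray(self.cluster_centroids, dtype=float)
        if cent.ndim != 2 or cent.shape[1] != len(COGNITIVE_TESTS):
            raise ValueError(f"centroids must be K x {len(COGNITIVE_TESTS)}")
        for i in range(len(cent)):
            for j in range(i + 1, len(cent)):
                if np.allclose(cent[i], cent[j]):
                    raise ValueError(f"centroids {i} and {j} are not distinct")
        if self.within_cluster_sd < 0:
            raise ValueError("within_cluster_sd must be >= 0")


def generate_cognitive(
    spec: CognitiveSpec, group_sizes: tuple[int, ...]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cognitive table (six tests + age + education) and true cluster labels."""
    spec.validate()
    cent = np.asarray(spec.cluster_centroids, dtype=float)
    if len(group_sizes) != len(cent):
        raise ValueError("one group size per centroid row required")
    if any(n <= 0 for n in group_sizes):
        raise ValueError("group sizes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows, labels = [], []
    total = sum(group_sizes)
    age = rng.uniform(*spec.age_range, size=total)
    edu = np.clip(rng.normal(spec.education_mean, spec.education_sd, size=total), 5, None)
    pos = 0
    for k, n in enumerate(group_sizes):
        for _ in range(n):
            a, e = age[pos], edu[pos]
            z = (
                cent[k]
                + spec.age_effect * (a - np.mean(spec.age_range))
                + spec.education_effect * (e - spec.education_mean)
                + rng.normal(0.0, spec.within_cluster_sd, size=cent.shape[1])
            )
            row = {"age": a, "education": e}
            for j, (test, scale) in enumerate(COGNITIVE_TESTS.items()):
                if test == "ided_errors":
                    # right-skewed non-negative count; more errors = worse
                    row[test] = float(np.floor(np.exp(2.0 - 0.8 * z[j])))
                else:
                    mu, sd = scale
                    row[test] = mu + sd * z[j]
            rows.append(row)
            labels.append(k)
            pos += 1
    table = pd.DataFrame(rows, index=[f"sub_{i:04d}" for i in range(total)])
    table.index.name = "subject_id"
    cols = ["age", "education"] + list(COGNITIVE_TESTS)
    return table[cols], np.asarray(labels)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as the delimited tables the pipeline reads.

    Ground-truth sidecars (group labels, block partition, per-group target
    correlation matrices) go alongside for test assertions.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.morphometry.to_csv(out / "morphometry.tsv", sep="\t", float_format="%.10g")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", float_format="%.10g")
    np.savetxt(out / "truth_block_partition.txt", cohort.block_partition, fmt="%d")
    for g, target in enumerate(cohort.target_corr):
        np.savetxt(out / f"truth_target_corr_group{g}.tsv", target,
                   delimiter="\t", fmt="%.10g")


def read_cohort(indir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back (morphometry, covariates) written by :func:`write_cohort`."""
    from pathlib import Path

    ind = Path(indir)
    morph = pd.read_csv(ind / "morphometry.tsv", sep="\t", index_col="subject_id")
    cov = pd.read_csv(ind / "covariates.tsv", sep="\t", index_col="subject_id")
    return morph, cov
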