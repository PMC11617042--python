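"""Community-level summaries: alpha diversity, Bray-Curtis, PCoA, PERMANOVA.

Shannon uses the natural log; Simpson is the Gini-Simpson complement
1 - sum(p^2).  Diversity is computed on raw counts without rarefaction.
PCoA is classical metric scaling (Gower double-centering); negative
eigenvalues are dropped and percent variance is reported over the
positive spectrum only.  PERMANOVA is the one-way pseudo-F permutation
test on a distance matrix with the add-one p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tabio import AbundanceTable, StudyMetadata

__all__ = [
    "shannon",
    "simpson",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "OrdinationResult",
    "PermanovaResult",
]


def shannon(sample_counts) -> float:
    """Shannon index H = -sum p_i ln p_i (nats) over features with p_i > 0."""
    x = np.asarray(sample_counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(sample_counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (0 for a single-species sample)."""
    x = np.asarray(sample_counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = x / total
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon and Simpson indices."""
    return pd.DataFrame(
        {
            "shannon": [shannon(table.counts[:, j]) for j in range(table.n_samples)],
            "simpson": [simpson(table.counts[:, j]) for j in range(table.n_samples)],
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v) between samples."""
    x = table.counts.T  # samples x features
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("Bray-Curtis undefined for an all-zero sample")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class OrdinationResult:
    distances: pd.DataFrame
    coordinates: pd.DataFrame  # samples x retained axes
    percent_explained: np.ndarray  # per retained axis, sums to <= 100


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix diagonal must be zero")
    return d


def pcoa(distances, eig_tolerance: float = 1e-10) -> OrdinationResult:
    """Classical PCoA: eigendecompose the Gower-centered -d^2/2 matrix.

    Axes with eigenvalue <= tolerance (including all negative ones) are
    dropped; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    """
    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        d = _check_distance_matrix(distances.to_numpy())
    else:
        d = _check_distance_matrix(distances)
        ids = [f"s{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eig_tolerance
    pos_sum = eigvals[eigvals > 0].sum()
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    percent = 100.0 * eigvals[keep] / pos_sum if pos_sum > 0 else np.zeros(keep.sum())
    dist_df = distances if isinstance(distances, pd.DataFrame) else pd.DataFrame(d, index=ids, columns=ids)
    coord_df = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(dist_df, coord_df, percent)


def _permanova_f(d2: np.ndarray, masks: list[np.ndarray], sst: float, n: int) -> float:
    ssw = 0.0
    for mask in masks:
        ng = int(mask.sum())
        ssw += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)  # full matrix double-counts i<j
    g = len(masks)
    denom = ssw / (n - g)
    if denom == 0:
        return np.inf if sst - ssw > 0 else 0.0
    return ((sst - ssw) / (g - 1)) / denom


def permanova(distances, groups, n_perm: int = 999, seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SST = (1/n) sum_{i<j} d_ij^2, SSW = sum_g (1/n_g) sum_{i<j in g} d_ij^2,
    pseudo-F = ((SST-SSW)/(g-1)) / (SSW/(n-g)); the p-value counts label
    permutations with F* >= F_obs under the add-one estimator.
    """
    if isinstance(distances, pd.DataFrame):
        if isinstance(groups, (pd.Series, StudyMetadata)):
            g = groups.group if isinstance(groups, StudyMetadata) else groups
            groups = g.loc[list(distances.index)].to_numpy()
        d = _check_distance_matrix(distances.to_numpy())
    else:
        d = _check_distance_matrix(distances)
        groups = np.asarray(groups)
    labels = np.asarray([str(x) for x in np.asarray(groups)])
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels do not match distance matrix size")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = d**2
    sst = d2.sum() / (2.0 * n)
    masks = [labels == lv for lv in levels]
    f_obs = _permanova_f(d2, masks, sst, n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        perm_masks = [perm_labels == lv for lv in levels]
        if _permanova_f(d2, perm_masks, sst, n) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), n_perm)
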