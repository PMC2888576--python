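"""Profile standardization, K-means clustering and template matching.

Genes are clustered on their row-standardized 15-cell mean profiles so that
shape, not magnitude, drives assignment.  The cluster tracking adipose
expansion is then nominated as the one whose centroid best correlates with a
phenotype-derived template (fat-accumulation rate blended with marker-gene
profiles).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .matrix import ExpressionMatrix
from .tables import profile_vector

log = logging.getLogger(__name__)

__all__ = [
    "ProfileTemplate",
    "ClusterResult",
    "StandardizedProfiles",
    "standardize_profiles",
    "kmeans_profiles",
    "select_cluster_by_template",
    "default_template",
]


@dataclass(frozen=True)
class ProfileTemplate:
    """A 15-cell target profile (canonical cell order) with provenance."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("template must be finite")
        if np.ptp(v) == 0:
            raise ValueError("template must not be constant")
        object.__setattr__(self, "values", v)


def default_template(
    config=None, rate_weight: float = 0.5
) -> ProfileTemplate:
    """Blend of the fat-accumulation-rate profile and the marker archetype.

    The rate component is the per-day change in mean fat mass leading into
    each sampling age (z-scored per arm block); the marker component is the
    planted adiposity archetype profile.  ``rate_weight`` balances the two.
    """
    from .design import AGES, ARMS
    from .synth import GeneratorConfig

    config = config or GeneratorConfig()
    rate = []
    for arm in ARMS:
        prev_age, prev_fm = 0, 0.05  # essentially fat-free at birth
        for age in AGES:
            fm = config.param(arm, age, "fm")[0]
            rate.append((fm - prev_fm) / (age - prev_age))
            prev_age, prev_fm = age, fm
    rate = np.asarray(rate)
    rate = (rate - rate.mean()) / rate.std()
    marker = profile_vector(config.profiles["ATE"])
    marker = (marker - marker.mean()) / marker.std()
    values = rate_weight * rate + (1 - rate_weight) * marker
    return ProfileTemplate(values, source="fat accumulation rate + marker archetype")


@dataclass
class StandardizedProfiles:
    """Row z-scored cell-mean profiles plus the moments to invert them."""

    profiles: pd.DataFrame      # genes x cells, mean 0 / sd 1 rows
    row_means: pd.Series
    row_sds: pd.Series
    dropped: list[str]          # constant-profile genes

    def unstandardize(self) -> pd.DataFrame:
        return self.profiles.mul(self.row_sds, axis=0).add(self.row_means, axis=0)


def standardize_profiles(matrix: ExpressionMatrix) -> StandardizedProfiles:
    """Cell-mean profiles, z-scored per gene (ddof=1).

    Genes whose cell means are constant carry no shape information and are
    dropped with a warning.
    """
    means = matrix.cell_means()
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    constant = sd == 0
    dropped = list(means.index[constant])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant-profile gene(s)",
            UserWarning, stacklevel=2,
        )
        log.info("constant profiles dropped: %s", dropped)
    keep = ~constant
    z = means.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return StandardizedProfiles(
        profiles=z, row_means=mu[keep], row_sds=sd[keep], dropped=dropped
    )


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series       # gene_id -> cluster index
    centroids: np.ndarray        # k x n_cells
    sizes: np.ndarray
    inertia: float
    seed: int
    n_restarts: int
    objective_history: list[float] = field(default_factory=list, repr=False)

    def genes_in(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = cdist(X, centers[:1], "sqeuclidean").ravel()
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[i] = X[rng.integers(n)]
        else:
            centers[i] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, cdist(X, centers[i:i + 1], "sqeuclidean").ravel())
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = centers.shape[0]
    labels = np.full(X.shape[0], -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = d2.argmin(axis=1)
        # re-seed empty clusters from the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = d2[np.arange(len(new_labels)), new_labels].argmax()
                centers[c] = X[far]
                d2[:, c] = cdist(X, centers[c:c + 1], "sqeuclidean").ravel()
                new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(new_labels)), new_labels].sum())
        history.append(inertia)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = X[labels == c].mean(axis=0)
    d2 = cdist(X, centers, "sqeuclidean")
    inertia = float(d2[np.arange(len(labels)), labels].sum())
    return labels, centers, inertia, history


def kmeans_profiles(
    profiles: StandardizedProfiles | pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """Euclidean K-means (k-means++ seeding, best of ``n_restarts``)."""
    if k <= 0:
        raise ValueError("k must be positive")
    P = profiles.profiles if isinstance(profiles, StandardizedProfiles) else profiles
    X = P.to_numpy(dtype=float)
    if k >= X.shape[0]:
        raise ValueError(f"k={k} must be smaller than the number of genes ({X.shape[0]})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        centers = _kmeans_pp_init(X, k, rng)
        labels, centers, inertia, history = _lloyd(X, centers)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, history)
    labels, centers, inertia, history = best
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels, index=P.index, name="cluster"),
        centroids=centers,
        sizes=np.bincount(labels, minlength=k),
        inertia=inertia,
        seed=seed,
        n_restarts=n_restarts,
        objective_history=history,
    )


def select_cluster_by_template(
    result: ClusterResult,
    template: ProfileTemplate,
    corr_floor: float = 0.5,
) -> tuple[int, float]:
    """Cluster whose centroid best (Pearson-)matches the template.

    Ties are broken toward the larger cluster, then the lower index;
    constant centroids are excluded.  A best correlation below
    ``corr_floor`` is flagged with a warning but still returned.
    """
    t = template.values
    if len(t) != result.centroids.shape[1]:
        raise ValueError("template length does not match centroid length")
    best: tuple[float, int, int] | None = None  # (corr, size, -index)
    best_idx, best_r = -1, -np.inf
    for i, c in enumerate(result.centroids):
        if np.ptp(c) == 0:
            log.info("cluster %d has a constant centroid; excluded", i)
            continue
        r = float(np.corrcoef(c, t)[0, 1])
        key = (r, int(result.sizes[i]), -i)
        if best is None or key > best:
            best = key
            best_idx, best_r = i, r
    if best is None:
        raise ValueError("no cluster with a non-constant centroid")
    if best_r < corr_floor:
        warnings.warn(
            f"best template correlation {best_r:.3f} below floor {corr_floor}",
            UserWarning, stacklevel=2,
        )
    return best_idx, best_r
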