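"""K-means site classification with gap-statistic model selection.

Sites are clustered on their mean physiochemical property vectors with
many-restart K-means (the kept solution is the restart minimising the
pooled within-cluster sum of squares W_k).  The number of classes is
chosen with the gap statistic: W_k is compared against its expectation
under a shape-aware uniform null --- points drawn uniformly inside the
bounding box of the data expressed in its right-singular-vector basis
--- and the smallest k with Gap(k) >= Gap(k+1) - s_{k+1} is selected
(the one-standard-error rule, with s_k inflated by sqrt(1 + 1/B) for the
Monte-Carlo error of the B reference draws).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .properties import SiteProfileMatrix, profile_matrix

__all__ = [
    "ClusterAssignment",
    "GapStatistics",
    "within_dispersion",
    "kmeans_partition",
    "reference_draw",
    "gap_curve",
    "select_k",
    "cluster_sites",
    "SiteClusterModel",
    "SiteClusterResults",
]


@dataclass
class ClusterAssignment:
    """Site -> group map with the group centroids and the achieved W_k.

    Labels are 1-based and numbered by decreasing group size (1 = largest),
    matching the partition-map file convention.
    """

    labels: np.ndarray
    centroids: np.ndarray
    within_ss: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.labels.min() < 1 or self.labels.max() > self.centroids.shape[0]:
            raise ValueError("labels must lie in 1..k")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_sites(self) -> int:
        return self.labels.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def group_sites(self, g: int) -> np.ndarray:
        """0-based site indices of group ``g`` (1-based label)."""
        return np.nonzero(self.labels == g)[0]


@dataclass
class GapStatistics:
    """Gap(k) curve with its standard-error terms."""

    k_values: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    B: int
    log_W_observed: np.ndarray
    mean_log_W_reference: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "gap": self.gap,
                "s_k": self.s_k,
                "log_W_observed": self.log_W_observed,
                "mean_log_W_reference": self.mean_log_W_reference,
            }
        )


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SiteProfileMatrix):
        X = X.profiles
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("data matrix must be 2-D")
    return X


def within_dispersion(X, labels) -> float:
    """Pooled within-cluster sum of squares around the cluster means."""
    X = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    total = 0.0
    for g in np.unique(labels):
        members = X[labels == g]
        if members.shape[0] == 0:
            raise ValueError(f"empty cluster {g}")
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    # guard against clusters declared but absent
    declared = labels.max() - labels.min() + 1
    if len(np.unique(labels)) != declared:
        raise ValueError("empty cluster in label range")
    return total


def _relabel_by_size(raw_labels: np.ndarray, centers: np.ndarray):
    sizes = np.bincount(raw_labels, minlength=centers.shape[0])
    order = np.argsort(-sizes, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return rank[raw_labels] + 1, centers[order]


def kmeans_partition(X, k: int, n_restarts: int = 1000, seed=None) -> ClusterAssignment:
    """Best-of-``n_restarts`` K-means solution (Lloyd, random initials).

    The restart achieving the minimum pooled within-cluster sum of
    squares is kept; deterministic given ``seed``.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=None if seed is None else int(seed) % (2**32),
    ).fit(X)
    labels, centers = _relabel_by_size(km.labels_, km.cluster_centers_)
    return ClusterAssignment(labels, centers, float(km.inertia_))


class _ReferenceBox:
    """Uniform null over the SVD-aligned bounding box of the data."""

    def __init__(self, X: np.ndarray):
        X = _as_matrix(X)
        if X.shape[0] < 2:
            raise ValueError("need at least two rows for a reference box")
        self.mean = X.mean(axis=0)
        centred = X - self.mean
        _, s, Vt = np.linalg.svd(centred, full_matrices=False)
        if not np.any(s > 1e-12):
            raise ValueError("degenerate data: all rows identical")
        self.Vt = Vt
        rotated = centred @ Vt.T
        self.lo = rotated.min(axis=0)
        self.hi = rotated.max(axis=0)
        self.shape = X.shape

    def draw(self, rng) -> np.ndarray:
        z = rng.uniform(self.lo, self.hi, size=self.shape)
        return z @ self.Vt + self.mean


def reference_draw(X, seed=None) -> np.ndarray:
    """One draw from the gap statistic's shape-aware uniform reference."""
    return _ReferenceBox(X).draw(np.random.default_rng(seed))


def gap_curve(
    X,
    k_max: int,
    B: int = 100,
    n_restarts: int = 1000,
    ref_restarts: int = 25,
    seed=None,
) -> GapStatistics:
    """Gap(k) and s_k for k = 1..k_max.

    ``B`` reference datasets are drawn once and re-clustered at every k.
    Reference fits use ``ref_restarts`` K-means restarts (fewer than the
    observed-data fits, which dominate neither cost nor noise).
    """
    X = _as_matrix(X)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    box = _ReferenceBox(X)
    refs = [box.draw(rng) for _ in range(B)]

    ks = np.arange(1, k_max + 1)
    log_W_obs = np.empty(k_max)
    log_W_ref = np.empty((B, k_max))
    for i, k in enumerate(ks):
        obs_seed = int(rng.integers(2**31))
        log_W_obs[i] = np.log(
            kmeans_partition(X, k, n_restarts=n_restarts, seed=obs_seed).within_ss
        )
        for b, ref in enumerate(refs):
            ref_seed = int(rng.integers(2**31))
            log_W_ref[b, i] = np.log(
                kmeans_partition(ref, k, n_restarts=ref_restarts, seed=ref_seed).within_ss
            )
    mean_ref = log_W_ref.mean(axis=0)
    gap = mean_ref - log_W_obs
    sd = log_W_ref.std(axis=0, ddof=0)
    s_k = sd * np.sqrt(1.0 + 1.0 / B)
    return GapStatistics(
        k_values=ks,
        gap=gap,
        s_k=s_k,
        B=B,
        log_W_observed=log_W_obs,
        mean_log_W_reference=mean_ref,
    )


def select_k(stats: GapStatistics):
    """One-standard-error rule: smallest k with Gap(k) >= Gap(k+1) - s_{k+1}.

    Returns ``(k, no_structure_warning)``; when no k below k_max satisfies
    the rule, k_max is returned with the warning flag set.
    """
    ks = np.asarray(stats.k_values)
    if np.any(np.diff(ks) != 1):
        raise ValueError("gap statistics must cover consecutive k")
    for i in range(len(ks) - 1):
        if stats.gap[i] >= stats.gap[i + 1] - stats.s_k[i + 1]:
            return int(ks[i]), False
    return int(ks[-1]), True


class SiteClusterModel:
    """Physiochemical site classification for one alignment.

    ``SiteClusterModel(msa).fit()`` computes the site-profile matrix, the
    gap curve, the selected number of classes and the final assignment.
    A profile matrix (or plain array) may be supplied directly.
    """

    def __init__(self, msa=None, profiles=None, table=None):
        if (msa is None) == (profiles is None):
            raise ValueError("supply exactly one of msa or profiles")
        if profiles is None:
            profiles = profile_matrix(msa, table=table)
        if not isinstance(profiles, SiteProfileMatrix):
            profiles = SiteProfileMatrix(
                profiles=np.asarray(profiles, dtype=float),
                site_ids=np.arange(1, np.asarray(profiles).shape[0] + 1),
                n_sequences_used=np.full(np.asarray(profiles).shape[0], -1),
            )
        self.profiles = profiles

    def fit(
        self,
        k_max: int = 6,
        B: int = 100,
        n_restarts: int = 1000,
        ref_restarts: int = 25,
        seed=None,
    ) -> "SiteClusterResults":
        stats = gap_curve(
            self.profiles,
            k_max=k_max,
            B=B,
            n_restarts=n_restarts,
            ref_restarts=ref_restarts,
            seed=seed,
        )
        k, no_structure = select_k(stats)
        if no_structure:
            warnings.warn(
                f"gap statistic satisfied by no k < {k_max}; returning k={k}",
                RuntimeWarning,
            )
        assignment = kmeans_partition(
            self.profiles, k, n_restarts=n_restarts, seed=seed
        )
        return SiteClusterResults(self, stats, assignment, no_structure)


class SiteClusterResults:
    """Selected site classes with the gap curve behind the choice."""

    def __init__(self, model, gap_statistics, assignment, no_structure):
        self.model = model
        self.gap_statistics = gap_statistics
        self.assignment = assignment
        self.no_structure = bool(no_structure)

    @property
    def k(self) -> int:
        return self.assignment.k

    @property
    def labels(self) -> np.ndarray:
        return self.assignment.labels

    def summary(self) -> str:
        sizes = ", ".join(str(s) for s in self.assignment.sizes)
        lines = [
            "Site classification by physiochemical profile",
            "=" * 60,
            f"sites: {self.assignment.n_sites}   selected k: {self.k}"
            + ("   (no-structure warning)" if self.no_structure else ""),
            f"group sizes: {sizes}",
            "",
            self.gap_statistics.as_frame().round(4).to_string(index=False),
        ]
        return "\n".join(lines)


def cluster_sites(
    msa,
    k_max: int = 6,
    B: int = 100,
    n_restarts: int = 1000,
    ref_restarts: int = 25,
    seed=None,
    table=None,
) -> SiteClusterResults:
    """End-to-end: profile matrix -> gap curve -> select k -> assignment."""
    return SiteClusterModel(msa, table=table).fit(
        k_max=k_max, B=B, n_restarts=n_restarts, ref_restarts=ref_restarts, seed=seed
    )
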