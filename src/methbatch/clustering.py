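"""Detection of multi-modal CpG probes by exact univariate k-means.

Beta values at a CpG site can be multi-modal across a cohort — genotype at
the probed cytosine (allele-specific methylation), X inactivation, cell
composition or residual technical structure all produce clusters. Clusters
are found per probe with a dynamic-programming univariate k-means that is
globally optimal (minimum within-cluster sum of squares over contiguous
partitions of the sorted data), the number of clusters is chosen by BIC
under acceptance constraints (every cluster >= 5 samples, adjacent centroids
separated by >= 0.1 beta), and a two-stage protocol first determines k with
the worst-affected slides set aside, then re-clusters all samples at that k.

Clustering operates on the beta scale: the centroid-separation rule is
stated in beta units (10% methylation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .containers import BetaMatrix

__all__ = [
    "ClusterModel",
    "ckmeans_1d",
    "clustering_bic",
    "select_optimal_k",
    "cluster_probes_two_stage",
]

KMAX_RECODE = 4  # any selected k above this is recoded down to 4

_BIC_VAR_FLOOR = 1e-6  # variance floor for degenerate, dispersion-free clusters


@dataclass
class ClusterModel:
    """Fitted per-probe clustering: k, assignments, ascending centroids."""

    probe_id: str
    k: int
    assignments: np.ndarray  # per-sample cluster index, 0..k-1, centroid-ordered
    centroids: np.ndarray  # strictly increasing mean beta per cluster
    cluster_sizes: np.ndarray
    within_ss: float
    bic_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.cluster_sizes.sum()) != self.assignments.size:
            raise ValueError("cluster sizes must sum to the number of samples")


@njit(cache=True)
def _ckmeans_dp(x_sorted: np.ndarray, kmax: int):
    """DP over contiguous partitions of sorted data.

    Returns (cost, split) where cost[k, i] is the minimal within-SS of
    partitioning the first i points into k clusters and split[k, i] is the
    start index (1-based point count) of the last cluster in that optimum.
    """
    n = x_sorted.size
    s1 = np.zeros(n + 1)
    s2 = np.zeros(n + 1)
    for i in range(n):
        s1[i + 1] = s1[i] + x_sorted[i]
        s2[i + 1] = s2[i] + x_sorted[i] * x_sorted[i]

    cost = np.full((kmax + 1, n + 1), np.inf)
    split = np.zeros((kmax + 1, n + 1), dtype=np.int64)
    cost[0, 0] = 0.0
    for k in range(1, kmax + 1):
        for i in range(k, n + 1):
            best = np.inf
            arg = k
            for j in range(k, i + 1):
                # last cluster covers points j-1 .. i-1 (0-based)
                m = i - j + 1
                seg_sum = s1[i] - s1[j - 1]
                seg_ss = s2[i] - s2[j - 1] - seg_sum * seg_sum / m
                if seg_ss < 0.0:
                    seg_ss = 0.0
                v = cost[k - 1, j - 1] + seg_ss
                if v < best:
                    best = v
                    arg = j
            cost[k, i] = best
            split[k, i] = arg
    return cost, split


def _backtrack(split: np.ndarray, k: int, n: int) -> list[tuple[int, int]]:
    """Recover [start, stop) index pairs of each cluster in sorted order."""
    bounds = []
    i = n
    for kk in range(k, 0, -1):
        j = split[kk, i]
        bounds.append((j - 1, i))
        i = j - 1
    bounds.reverse()
    return bounds


def ckmeans_1d(x, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal univariate k-means.

    Returns (assignments, centroids, within_ss). Assignments follow the
    original order of ``x``; cluster indices are sorted by ascending
    centroid. Deterministic, and exact: the partition minimises the total
    within-cluster sum of squares over all contiguous partitions of the
    sorted data (which contains the global optimum in one dimension).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("x must be finite")
    n = x.size
    if k < 1 or k > n:
        raise ValueError(f"k must satisfy 1 <= k <= n={n}, got {k}")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    center = xs.mean()
    cost, split = _ckmeans_dp(xs - center, k)
    bounds = _backtrack(split, k, n)

    assignments = np.empty(n, dtype=np.intp)
    centroids = np.empty(k)
    for c, (a, b) in enumerate(bounds):
        assignments[order[a:b]] = c
        centroids[c] = xs[a:b].mean()
    return assignments, centroids, float(cost[k, n])


def clustering_bic(x, assignments, centroids=None) -> float:
    """BIC of a hard-assignment univariate Gaussian-mixture fit.

    Each cluster contributes a Gaussian with its own mean and (MLE) variance
    and mixing proportion n_c/n; the parameter count is 3k - 1. Orientation:
    BIC = 2 log L - (3k - 1) log n, so LARGER is better. A variance floor of
    1e-6 guards dispersion-free clusters.
    """
    x = np.asarray(x, dtype=float)
    assignments = np.asarray(assignments)
    n = x.size
    labels = np.unique(assignments)
    k = labels.size
    loglik = 0.0
    for lab in labels:
        xi = x[assignments == lab]
        nc = xi.size
        var = max(float(xi.var()), _BIC_VAR_FLOOR)
        loglik += nc * (
            np.log(nc / n) - 0.5 * np.log(2.0 * np.pi * var)
        ) - 0.5 * ((xi - xi.mean()) ** 2).sum() / var
    return float(2.0 * loglik - (3 * k - 1) * np.log(n))


def _qualifies(sizes: np.ndarray, centroids: np.ndarray, min_size: int, min_sep: float) -> bool:
    if sizes.min() < min_size:
        return False
    if centroids.size > 1 and np.diff(centroids).min() < min_sep:
        return False
    return True


def select_optimal_k(
    x,
    kmax: int = 4,
    min_cluster_size: int = 5,
    min_centroid_sep: float = 0.1,
    probe_id: str = "",
) -> ClusterModel:
    """Choose the number of modes for one probe.

    Procedure: fit k = 1..kmax, rank by BIC and take the two best; a
    candidate k qualifies iff every cluster has at least ``min_cluster_size``
    members and adjacent centroids differ by at least ``min_centroid_sep``
    (k = 1 always qualifies); the largest qualifying candidate wins, and any
    selection above 4 is recoded to 4. BIC ties break toward smaller k.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= min_cluster_size:
        raise ValueError(f"need more than {min_cluster_size} samples, got {n}")
    kmax_eff = min(kmax, n)

    fits: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    bic_by_k: dict[int, float] = {}
    for k in range(1, kmax_eff + 1):
        assignments, centroids, wss = ckmeans_1d(x, k)
        fits[k] = (assignments, centroids, wss)
        bic_by_k[k] = clustering_bic(x, assignments, centroids)

    # two best by BIC; ties toward smaller k
    ranked = sorted(bic_by_k, key=lambda k: (-bic_by_k[k], k))
    candidates = set(ranked[:2]) | {1}

    chosen = 1
    for k in sorted(candidates, reverse=True):
        assignments, centroids, _ = fits[k]
        sizes = np.bincount(assignments, minlength=k)
        if k == 1 or _qualifies(sizes, centroids, min_cluster_size, min_centroid_sep):
            chosen = k
            break
    if chosen > KMAX_RECODE:
        chosen = KMAX_RECODE

    assignments, centroids, wss = fits[chosen]
    return ClusterModel(
        probe_id=probe_id,
        k=chosen,
        assignments=assignments,
        centroids=centroids,
        cluster_sizes=np.bincount(assignments, minlength=chosen),
        within_ss=wss,
        bic_by_k=bic_by_k,
    )


def cluster_probes_two_stage(
    beta: BetaMatrix,
    sheet: pd.DataFrame | None = None,
    excluded_slides: list | None = None,
    kmax: int = 4,
    min_cluster_size: int = 5,
    min_centroid_sep: float = 0.1,
) -> dict[str, ClusterModel]:
    """Two-stage modal clustering over all probes of a beta matrix.

    Stage 1 determines k per probe on the samples whose slide is NOT in
    ``excluded_slides`` (slides with the strongest batch-effects, typically
    chosen from PCA review, would otherwise inflate k). Stage 2 re-clusters
    ALL samples at the stage-1 k, so every sample is assigned.
    """
    excluded_slides = list(excluded_slides or [])
    vals = beta.values
    if excluded_slides:
        if sheet is None:
            raise ValueError("a sample sheet is required when excluding slides")
        slides = sheet.set_index("sample_id").loc[beta.sample_ids, "slide"]
        keep = ~slides.astype(str).isin([str(s) for s in excluded_slides]).to_numpy()
        if not keep.any():
            raise ValueError("excluded slides remove every sample")
        if keep.sum() < 2 * min_cluster_size:
            raise ValueError(
                f"only {int(keep.sum())} samples retained after slide exclusion; "
                f"need at least {2 * min_cluster_size}"
            )
    else:
        keep = np.ones(vals.shape[1], dtype=bool)

    models: dict[str, ClusterModel] = {}
    for i, probe in enumerate(beta.probe_ids):
        stage1 = select_optimal_k(
            vals[i, keep],
            kmax=kmax,
            min_cluster_size=min_cluster_size,
            min_centroid_sep=min_centroid_sep,
            probe_id=str(probe),
        )
        if keep.all():
            models[str(probe)] = stage1
            continue
        assignments, centroids, wss = ckmeans_1d(vals[i], stage1.k)
        models[str(probe)] = ClusterModel(
            probe_id=str(probe),
            k=stage1.k,
            assignments=assignments,
            centroids=centroids,
            cluster_sizes=np.bincount(assignments, minlength=stage1.k),
            within_ss=wss,
            bic_by_k=stage1.bic_by_k,
        )
    return models
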