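"""Hierarchical clustering of t-invariants with cluster-number selection.

t-invariants are clustered on their integer multiplicity vectors (or binary
support indicators) under eight distance measures and seven agglomerative
linkage algorithms, the partition being scored at each cut ``k`` by the
Calinski-Harabasz index (larger is better) and the Mean Split Silhouette
(smaller is better).  The distance and linkage names follow the R
``dist`` / ``hclust`` vocabulary so results line up with what the usual
clustering tools report.

The agglomeration is implemented directly via the Lance-Williams update so
that tie-breaking is fully deterministic: among pairs at the minimal
distance, the pair whose clusters contain the smallest original indices is
merged first.  Centroid, median and Ward linkage operate on squared
distances, as in their classical (Euclidean) definitions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DISTANCES",
    "LINKAGES",
    "pairwise_distances",
    "linkage_tree",
    "hierarchical_cluster",
    "calinski_harabasz",
    "mean_split_silhouette",
    "model_selection",
    "ch_curve",
    "interior_ch_maxima",
    "cluster_with_local_ch",
    "ClusteringResult",
]

DISTANCES = (
    "binary",
    "canberra",
    "euclidean",
    "manhattan",
    "maximum",
    "minkowski",
    "pearson_uncentered",
    "pearson_centered",
)

LINKAGES = ("centroid", "complete", "mcquitty", "median", "single", "upgma", "ward")

#: centroid/median are defined on squared Euclidean geometry; under other
#: measures they still run but are not eligible as the "best" configuration.
EUCLIDEAN_ONLY_LINKAGES = ("centroid", "median")


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def pairwise_distances(vectors, name: str, minkowski_p: float = 3.0) -> np.ndarray:
    """Symmetric pairwise distance matrix under the named measure.

    ``binary`` is the proportion of mismatching positions among positions
    where at least one vector is non-zero (the R ``dist`` convention).
    ``pearson_centered`` is ``1 - r`` (range 0..2); a zero-variance vector is
    assigned distance 0 to identical vectors and 1 otherwise, and similarly
    for the all-zero vector under ``pearson_uncentered``.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two vectors")
    n = X.shape[0]
    if name == "binary":
        B = (X != 0).astype(float)
        both = B @ B.T
        nz = B.sum(axis=1)
        union = nz[:, None] + nz[None, :] - both
        with np.errstate(invalid="ignore", divide="ignore"):
            D = (union - both) / union
        D = np.where(union == 0, 0.0, D)
    elif name == "canberra":
        D = np.zeros((n, n))
        for i in range(n):
            num = np.abs(X[i] - X)
            den = np.abs(X[i]) + np.abs(X)
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = np.where(den > 0, num / den, 0.0)
            D[i] = terms.sum(axis=1)
    elif name == "euclidean":
        D = _lp(X, 2.0)
    elif name == "manhattan":
        D = _lp(X, 1.0)
    elif name == "maximum":
        D = np.max(np.abs(X[:, None, :] - X[None, :, :]), axis=2)
    elif name == "minkowski":
        D = _lp(X, float(minkowski_p))
    elif name == "pearson_uncentered":
        norms = np.linalg.norm(X, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (X @ X.T) / np.outer(norms, norms)
        D = 1.0 - C
        D = _degenerate_rows(D, X, norms == 0)
    elif name == "pearson_centered":
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (Xc @ Xc.T) / np.outer(norms, norms)
        D = 1.0 - C
        D = _degenerate_rows(D, X, norms == 0)
    else:
        raise ValueError(f"unknown distance {name!r}; expected one of {DISTANCES}")
    D = np.asarray(D, dtype=float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _lp(X: np.ndarray, p: float) -> np.ndarray:
    diff = np.abs(X[:, None, :] - X[None, :, :])
    return (diff**p).sum(axis=2) ** (1.0 / p)


def _degenerate_rows(D, X, degenerate) -> np.ndarray:
    """Constant/zero vectors: correlation undefined -> 1, except identical -> 0."""
    if not degenerate.any():
        return D
    idx = np.flatnonzero(degenerate)
    for i in idx:
        same = np.all(X == X[i], axis=1)
        D[i, :] = np.where(same, 0.0, 1.0)
        D[:, i] = D[i, :]
    return D


# --------------------------------------------------------------------------
# agglomerative linkage (Lance-Williams)
# --------------------------------------------------------------------------

_SQUARED = {"centroid", "median", "ward"}


@dataclass
class LinkageTree:
    """Merge history: ``merges[s] = (a, b)`` joins clusters labelled a and b.

    Labels 0..N-1 are singletons; merge ``s`` creates label ``N + s``.
    Heights are monotone for the graph methods; centroid/median may invert.
    """

    n: int
    merges: list[tuple[int, int]]
    heights: list[float]

    def cut(self, k: int) -> np.ndarray:
        """Labels 0..k-1 (renumbered by smallest member) for a cut into k."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k={k} outside 1..{self.n}")
        members: dict[int, list[int]] = {i: [i] for i in range(self.n)}
        for s in range(self.n - k):
            a, b = self.merges[s]
            members[self.n + s] = members.pop(a) + members.pop(b)
        labels = np.empty(self.n, dtype=np.int64)
        for new_id, group in enumerate(sorted(members.values(), key=min)):
            labels[group] = new_id
        return labels


def linkage_tree(D: np.ndarray, linkage: str) -> LinkageTree:
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    work = D.copy() ** 2 if linkage in _SQUARED else D.copy()
    np.fill_diagonal(work, np.inf)
    size = np.ones(n)
    rows = list(range(n))  # row index -> current label
    smallest = list(range(n))  # row -> smallest original member
    alive = np.ones(n, dtype=bool)
    merges: list[tuple[int, int]] = []
    heights: list[float] = []

    for step in range(n - 1):
        sub = np.where(alive[:, None] & alive[None, :], work, np.inf)
        # ties resolved by row-major position: rows keep the position of the
        # cluster holding the smallest original index, so the first minimal
        # entry is the lexicographically smallest pair
        flat = int(np.argmin(sub))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dmin = sub[i, j]
        la, lb = rows[i], rows[j]
        merges.append((min(la, lb), max(la, lb)))
        heights.append(math.sqrt(dmin) if linkage in _SQUARED else float(dmin))

        ni, nj = size[i], size[j]
        dik, djk = work[i], work[j]
        dij = work[i, j]
        if linkage == "single":
            new = np.minimum(dik, djk)
        elif linkage == "complete":
            new = np.maximum(dik, djk)
        elif linkage == "upgma":
            new = (ni * dik + nj * djk) / (ni + nj)
        elif linkage == "mcquitty":
            new = (dik + djk) / 2.0
        elif linkage == "centroid":
            new = (ni * dik + nj * djk) / (ni + nj) - (ni * nj * dij) / (ni + nj) ** 2
        elif linkage == "median":
            new = dik / 2.0 + djk / 2.0 - dij / 4.0
        else:  # ward (on squared distances, ward.D2 convention)
            nk = size
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        work[i] = new
        work[:, i] = new
        work[i, i] = np.inf
        alive[j] = False
        size[i] = ni + nj
        rows[i] = n + step
        smallest[i] = min(smallest[i], smallest[j])

    return LinkageTree(n, merges, heights)


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray
    distance: str
    linkage: str
    mss: float | None = None
    ch: float | None = None

    @property
    def sizes(self) -> list[int]:
        return np.bincount(self.labels, minlength=self.k).tolist()

    @property
    def n_singletons(self) -> int:
        return int(sum(1 for s in self.sizes if s == 1))


def hierarchical_cluster(D: np.ndarray, linkage: str, k: int,
                         distance: str = "custom") -> ClusteringResult:
    """Cut the agglomerative merge tree of ``D`` into ``k`` clusters."""
    n = D.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in 2..{n}, got {k}")
    tree = linkage_tree(D, linkage)
    return ClusteringResult(k=k, labels=tree.cut(k), distance=distance, linkage=linkage)


# --------------------------------------------------------------------------
# validity indices
# --------------------------------------------------------------------------

def calinski_harabasz(points, labels) -> float:
    """Between/within variance ratio criterion ``(B/(k-1)) / (W/(N-k))``.

    Computed in Euclidean geometry of the feature vectors regardless of the
    distance used for clustering.  Perfectly tight clusters (W = 0) give
    ``inf``.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    k, n = len(ids), X.shape[0]
    if k < 2 or n <= k:
        raise ValueError("need 2 <= k < N")
    overall = X.mean(axis=0)
    B = W = 0.0
    for c in ids:
        sub = X[labels == c]
        cen = sub.mean(axis=0)
        B += len(sub) * float(((cen - overall) ** 2).sum())
        W += float(((sub - cen) ** 2).sum())
    if W == 0.0:
        return math.inf
    return (B / (k - 1)) / (W / (n - k))


def _silhouette_widths(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = len(labels)
    ids = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own)
        if same.sum() <= 1:
            s[i] = 0.0
            continue
        a = D[i][same & (np.arange(n) != i)].mean()
        b = min(D[i][labels == c].mean() for c in ids if c != own)
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def mean_split_silhouette(D: np.ndarray, labels, linkage: str,
                          _cache: dict | None = None) -> float:
    """Mean Split Silhouette: average splittability of the clusters.

    Each cluster of size >= 3 is forcibly re-clustered into two sub-clusters
    with the same linkage, and the mean silhouette width of its members under
    that split is recorded; MSS is the mean over clusters.  A cluster that
    splits cleanly (silhouette near 1) was hiding structure, so *lower* MSS
    indicates a better-resolved clustering.  Clusters too small to split
    (size < 3) contribute the neutral value 1.
    """
    labels = np.asarray(labels)
    D = np.asarray(D, dtype=float)
    ids = np.unique(labels)
    per_cluster = []
    any_split = False
    for c in ids:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 3:
            per_cluster.append(1.0)
            continue
        any_split = True
        key = (linkage, idx.tobytes())
        if _cache is not None and key in _cache:
            per_cluster.append(_cache[key])
            continue
        sub = D[np.ix_(idx, idx)]
        split = linkage_tree(sub, linkage).cut(2)
        value = float(_silhouette_widths(sub, split).mean())
        if _cache is not None:
            _cache[key] = value
        per_cluster.append(value)
    if not any_split:
        warnings.warn("all clusters have size < 3; MSS defaults to 1", stacklevel=2)
    return float(np.mean(per_cluster))


def ch_curve(vectors, tree: LinkageTree, k_range=range(2, 31)) -> dict[int, float]:
    """Calinski-Harabasz score of each cut of ``tree`` over ``k_range``."""
    X = np.asarray(vectors, dtype=float)
    return {k: calinski_harabasz(X, tree.cut(k)) for k in k_range if k < len(X)}


def interior_ch_maxima(curve: dict[int, float]) -> list[int]:
    """Interior local maxima of a CH-versus-k curve, sorted by k.

    On data dominated by one coarse split the CH index decays from k = 2
    and the informative cluster number shows up as an interior local
    maximum rather than the global one; this extracts those candidates.
    """
    ks = sorted(curve)
    return [
        k for k in ks[1:-1]
        if curve[k] > curve[k - 1] and curve[k] > curve[k + 1]
    ]


def cluster_with_local_ch(
    vectors,
    distance: str = "pearson_centered",
    linkage: str = "upgma",
    binary: bool = True,
    k_range=range(2, 31),
    minkowski_p: float = 3.0,
) -> ClusteringResult:
    """Cluster at the dominant interior CH local maximum of one configuration.

    Runs a single (distance, linkage) agglomeration, scores every cut with
    Calinski-Harabasz, and cuts at the interior local maximum with the
    highest score (falling back to the global maximum if the curve is
    monotone).  This is the protocol that identifies the t-cluster count on
    invariant sets whose CH curve decays from a dominant two-block split.
    """
    X = np.asarray(vectors, dtype=float)
    if binary:
        X = (X != 0).astype(float)
    D = pairwise_distances(X, distance, minkowski_p=minkowski_p)
    tree = linkage_tree(D, linkage)
    curve = ch_curve(X, tree, k_range)
    candidates = interior_ch_maxima(curve) or list(curve)
    k = max(candidates, key=lambda kk: (curve[kk], -kk))
    labels = tree.cut(k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mss = mean_split_silhouette(D, labels, linkage)
    return ClusteringResult(k=k, labels=labels, distance=distance, linkage=linkage,
                            mss=mss, ch=curve[k])


# --------------------------------------------------------------------------
# model selection
# --------------------------------------------------------------------------

def model_selection(
    vectors,
    k_range=range(2, 31),
    distances=DISTANCES,
    linkages=LINKAGES,
    binary: bool = False,
    minkowski_p: float = 3.0,
    compute_mss: bool = True,
    allow_geometric_anywhere: bool = False,
):
    """Exhaustive (distance, linkage, k) grid scored by CH and MSS.

    Returns ``(best, table)``: the winning :class:`ClusteringResult` and a
    DataFrame of all scores.  The best configuration maximises CH, with
    smaller MSS then smaller ``k`` breaking ties; centroid and median
    linkage only compete under the Euclidean measure unless
    ``allow_geometric_anywhere`` is set.
    """
    import pandas as pd

    X = np.asarray(vectors, dtype=float)
    if binary:
        X = (X != 0).astype(float)
    rows = []
    best = None
    best_key = None
    for dist in distances:
        D = pairwise_distances(X, dist, minkowski_p=minkowski_p)
        mss_cache: dict = {}
        for link in linkages:
            tree = linkage_tree(D, link)
            for k in k_range:
                if k >= len(X):
                    continue
                labels = tree.cut(k)
                ch = calinski_harabasz(X, labels)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mss = (
                        mean_split_silhouette(D, labels, link, _cache=mss_cache)
                        if compute_mss
                        else float("nan")
                    )
                rows.append(
                    {"distance": dist, "linkage": link, "k": k, "ch": ch, "mss": mss}
                )
                eligible = (
                    allow_geometric_anywhere
                    or link not in EUCLIDEAN_ONLY_LINKAGES
                    or dist == "euclidean"
                )
                if not eligible:
                    continue
                key = (-ch, mss if compute_mss else 0.0, k)
                if best_key is None or key < best_key:
                    best_key = key
                    best = ClusteringResult(
                        k=k, labels=labels, distance=dist, linkage=link, mss=mss, ch=ch
                    )
    return best, pd.DataFrame(rows)
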