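"""Clustering tendency and unsupervised structure of exposure profiles.

Samples are points on the signature-contribution simplex; the questions
asked here are (i) is there any cluster structure at all (Hopkins
statistic), (ii) what is it (divisive hierarchical clustering, DIANA),
and (iii) how strong is it (silhouette widths), with PCA for inspection.

The Hopkins convention used is H = sum(w) / (sum(u) + sum(w)) with w the
nearest-neighbour distances among real points and u the distances from
uniform probes to real points: H near 0.5 means spatial randomness and H
well below 0.5 means clustered data.  Pass ``clustered_high=True`` for
the complementary convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform


def clr_transform(X: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """Centered log-ratio transform of compositional rows.

    Exposure profiles are compositions; Euclidean distance after CLR is
    the Aitchison distance, offered as an alternative to raw Euclidean
    on the simplex.  Zeros are handled by a small pseudocount followed by
    re-closure.
    """
    X = np.asarray(X, dtype=float)
    X = X / X.sum(axis=1, keepdims=True)     # close first: scale-free
    X = X + pseudocount
    X = X / X.sum(axis=1, keepdims=True)
    logX = np.log(X)
    return logX - logX.mean(axis=1, keepdims=True)


def hopkins_statistic(X: np.ndarray, sample_fraction: float = 0.1,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      clustered_high: bool = False) -> float:
    """Clustering-tendency statistic on an S x d point matrix."""
    X = np.asarray(X, dtype=float)
    S = X.shape[0]
    if S < 10:
        raise ValueError("Hopkins statistic needs at least 10 points")
    lo, hi = X.min(axis=0), X.max(axis=0)
    keep = hi > lo
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-width dimension(s) "
                      "from the Hopkins bounding box")
        X, lo, hi = X[:, keep], lo[keep], hi[keep]
    if X.shape[1] == 0:
        raise ValueError("all dimensions are degenerate")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = max(5, int(round(sample_fraction * S)))
    m = min(m, S - 1)
    idx = rng.choice(S, size=m, replace=False)
    uniform = rng.uniform(lo, hi, size=(m, X.shape[1]))
    # w: sampled real point -> nearest other real point
    dw = cdist(X[idx], X)
    dw[np.arange(m), idx] = np.inf
    w = dw.min(axis=1)
    # u: uniform probe -> nearest real point
    u = cdist(uniform, X).min(axis=1)
    h = float(w.sum() / (u.sum() + w.sum()))
    return 1.0 - h if clustered_high else h


# ---------------------------------------------------------------------------
# DIANA


@dataclass
class DianaSplit:
    height: float                # diameter of the cluster being split
    cluster: tuple[int, ...]
    splinter: tuple[int, ...]
    remainder: tuple[int, ...]


@dataclass
class DianaResult:
    """Divisive clustering tree: splits in execution order (by decreasing
    diameter), with ``cut(k)`` replaying the first k-1 splits."""

    n: int
    splits: list[DianaSplit]

    @property
    def heights(self) -> list[float]:
        return [s.height for s in self.splits]

    def cut(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n:
            raise ValueError(f"k must be in [1, {self.n}]")
        clusters = [tuple(range(self.n))]
        for split in self.splits[: k - 1]:
            clusters.remove(split.cluster)
            clusters.extend([split.splinter, split.remainder])
        labels = np.empty(self.n, dtype=int)
        for lab, members in enumerate(clusters, start=1):
            labels[list(members)] = lab
        return labels

    def newick(self, names: list[str] | None = None) -> str:
        if names is None:
            names = [str(i) for i in range(self.n)]
        children = {tuple(range(self.n)): None}
        tree = {}
        for split in self.splits:
            tree[split.cluster] = (split.splinter, split.remainder, split.height)

        def render(cluster: tuple[int, ...]) -> str:
            if len(cluster) == 1:
                return names[cluster[0]]
            a, b, h = tree[cluster]
            return f"({render(a)},{render(b)}):{h:.6g}"

        return render(tuple(range(self.n))) + ";"


def _avg_dissim(D: np.ndarray, i: int, others: list[int]) -> float:
    if not others:
        return 0.0
    return float(D[i, others].mean())


def diana_clustering(X: np.ndarray, metric: str = "euclidean",
                     precomputed: bool = False) -> DianaResult:
    """Divisive hierarchical clustering (Kaufman & Rousseeuw).

    At each step the cluster with the largest diameter is split: the
    member with maximal average dissimilarity to the rest seeds a
    splinter group, then members closer on average to the splinter than
    to the remainder defect one at a time (largest positive margin
    first) until no one moves.
    """
    if precomputed:
        D = np.asarray(X, dtype=float)
    else:
        D = squareform(pdist(np.asarray(X, dtype=float), metric=metric))
    if not np.isfinite(D).all():
        i, j = np.argwhere(~np.isfinite(D))[0]
        raise ValueError(f"non-finite distance between points {i} and {j}")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    active = [tuple(range(n))]
    splits: list[DianaSplit] = []
    while any(len(c) > 1 for c in active):
        diams = [D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in active]
        ci = int(np.argmax(diams))
        cluster = active.pop(ci)
        diameter = diams[ci]
        members = list(cluster)
        avg = [(_avg_dissim(D, i, [j for j in members if j != i]), i)
               for i in members]
        seed_point = max(avg)[1]
        splinter = [seed_point]
        remainder = [i for i in members if i != seed_point]
        moved = True
        while moved and len(remainder) > 1:
            moved = False
            margins = []
            for i in remainder:
                d_rem = _avg_dissim(D, i, [j for j in remainder if j != i])
                d_spl = _avg_dissim(D, i, splinter)
                margins.append((d_rem - d_spl, i))
            best_margin, best_i = max(margins)
            if best_margin > 0:
                remainder.remove(best_i)
                splinter.append(best_i)
                moved = True
        splits.append(DianaSplit(float(diameter), cluster,
                                 tuple(sorted(splinter)),
                                 tuple(sorted(remainder))))
        active.extend([tuple(sorted(splinter)), tuple(sorted(remainder))])
    return DianaResult(n, splits)


# ---------------------------------------------------------------------------
# Silhouette


def silhouette_widths(X: np.ndarray, labels: np.ndarray,
                      metric: str = "euclidean",
                      precomputed: bool = False
                      ) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s(i) = (b - a) / max(a, b).

    ``a`` is the mean distance to the other members of i's cluster and
    ``b`` the smallest mean distance to any other cluster.  Members of
    singleton clusters get s = 0.  Raises for k = 1, where the silhouette
    is undefined.
    """
    labels = np.asarray(labels)
    if precomputed:
        D = np.asarray(X, dtype=float)
    else:
        D = squareform(pdist(np.asarray(X, dtype=float), metric=metric))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    n = D.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        widths[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return widths, float(widths.mean())


# ---------------------------------------------------------------------------
# PCA


def pca_projection(X: np.ndarray, n_components: int = 2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores and explained-variance fractions."""
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if np.allclose(X, X[0:1, :]):
        raise ValueError("constant matrix has no principal components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
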