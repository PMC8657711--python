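"""De novo signature extraction, catalog matching and exposure fitting.

The three-step procedure mirrors the standard mutational-signature
workflow:

1. *Extraction* — non-negative matrix factorization of the 96 x S count
   matrix under a Poisson (generalized Kullback-Leibler) objective with
   multiplicative updates, repeated over multinomial bootstrap resamples
   of each sample's counts.  For each candidate rank the replicate
   signatures are pooled and clustered by cosine distance; the mean
   silhouette of that clustering measures how reproducibly the rank's
   signatures re-emerge, and the selected rank is the largest stable one.
2. *Similarity* — each extracted signature is expressed as a conic
   combination of a reference catalog by non-negative least squares; the
   cosine similarity between the signature and its NNLS composite decides
   whether it matches known processes or is flagged novel.
3. *Fitting* — per-sample relative exposures to a fixed signature basis
   are estimated by iterative per-signature golden-section refinement of
   a non-negative weight vector (the deconstructSigs scheme), with small
   contributions zeroed by a cutoff and the rest renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform

_EPS = 1e-12


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Inner-product cosine between two non-negative 96-vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# KL-NMF with multiplicative updates


def _kl_divergence(V: np.ndarray, R: np.ndarray) -> float:
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / R[mask])) - V.sum() + R.sum())


def kl_nmf(V: np.ndarray, rank: int, rng: np.random.Generator,
           max_iter: int = 1000, tol: float = 1e-8,
           track_objective: bool = False):
    """Poisson/KL NMF by Lee-Seung multiplicative updates.

    Returns (W, H, final KL divergence[, objective trace]).  The KL
    objective is non-increasing across iterations; a violation beyond
    numerical noise indicates a bug and raises.
    """
    V = np.asarray(V, dtype=float)
    m, n = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.5, 1.5, size=(m, rank)) * scale
    H = rng.uniform(0.5, 1.5, size=(rank, n)) * scale
    trace = []
    prev = _kl_divergence(V, W @ H + _EPS)
    if track_objective:
        trace.append(prev)
    for _ in range(max_iter):
        R = W @ H + _EPS
        W *= (V / R) @ H.T / (H.sum(axis=1)[None, :] + _EPS)
        R = W @ H + _EPS
        H *= W.T @ (V / R) / (W.sum(axis=0)[:, None] + _EPS)
        obj = _kl_divergence(V, W @ H + _EPS)
        if track_objective:
            trace.append(obj)
        if obj > prev + 1e-9 * max(1.0, abs(prev)):
            raise AssertionError("KL objective increased during NMF update")
        if prev - obj < tol * max(1.0, abs(prev)):
            prev = obj
            break
        prev = obj
    if track_objective:
        return W, H, prev, trace
    return W, H, prev


def _bootstrap_columns(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial resample of each sample's counts, totals preserved."""
    out = np.zeros_like(V)
    for j in range(V.shape[1]):
        total = int(V[:, j].sum())
        if total == 0:
            continue
        p = V[:, j] / V[:, j].sum()
        out[:, j] = rng.multinomial(total, p)
    return out


# ---------------------------------------------------------------------------
# Rank selection and extraction


@dataclass
class RankSelectionReport:
    """Per-rank bootstrap stability and reconstruction error."""

    table: pd.DataFrame          # columns: rank, stability, median_error
    selected_rank: int
    stability_threshold: float
    n_bootstrap: int
    n_restarts: int
    seed: int


@dataclass
class ExtractionResult:
    signatures: pd.DataFrame     # 96 x k, column-stochastic
    exposures: pd.DataFrame      # k x S, column-stochastic (or zero, flagged)
    report: RankSelectionReport
    unfit_samples: list = field(default_factory=list)


def _cluster_replicates(pooled: list[np.ndarray], rank: int
                        ) -> tuple[np.ndarray, float]:
    """Consensus-cluster replicate signatures into ``rank`` groups.

    Each bootstrap replicate contributes exactly one signature per
    cluster: replicate solutions are matched to the current centroids by
    Hungarian assignment on cosine similarity, and centroids are
    re-estimated until the partition stabilizes.  The matching constraint
    makes an overfit rank visible -- its surplus cluster collects a
    different noise direction from every replicate and scores a low
    silhouette.  Stability is the unweighted mean over clusters of the
    within-cluster mean silhouette (cosine distance).
    """
    from scipy.optimize import linear_sum_assignment

    n_rep = len(pooled)
    sigs = np.concatenate(pooled, axis=1)
    if rank == 1:
        return np.ones(sigs.shape[1], dtype=int), 1.0
    norms = [W / (np.linalg.norm(W, axis=0, keepdims=True) + _EPS)
             for W in pooled]
    centroids = norms[0].copy()
    assign = np.zeros((n_rep, rank), dtype=int)
    for _ in range(50):
        changed = False
        for r, Wn in enumerate(norms):
            sim = centroids.T @ Wn          # clusters x signatures
            rows, cols = linear_sum_assignment(-sim)
            new = np.empty(rank, dtype=int)
            new[cols] = rows                # signature j -> cluster new[j]
            if not np.array_equal(new, assign[r]):
                changed = True
                assign[r] = new
        for c in range(rank):
            members = np.concatenate(
                [norms[r][:, [j]] for r in range(n_rep)
                 for j in range(rank) if assign[r, j] == c], axis=1)
            centroid = members.mean(axis=1)
            centroids[:, c] = centroid / (np.linalg.norm(centroid) + _EPS)
        if not changed:
            break
    labels = np.concatenate([assign[r] + 1 for r in range(n_rep)])
    D = squareform(np.clip(pdist(sigs.T, metric="cosine"), 0.0, None))
    from .clustering import silhouette_widths
    widths, _ = silhouette_widths(D, labels, precomputed=True)
    per_cluster = [widths[labels == c].mean() for c in range(1, rank + 1)]
    return labels, float(np.mean(per_cluster))


def _medoids(sigs: np.ndarray, labels: np.ndarray, rank: int) -> np.ndarray:
    D = squareform(np.clip(pdist(sigs.T, metric="cosine"), 0.0, None))
    cols = []
    for lab in range(1, rank + 1):
        members = np.flatnonzero(labels == lab)
        if len(members) == 0:
            continue
        sub = D[np.ix_(members, members)]
        medoid = members[np.argmin(sub.sum(axis=1))]
        cols.append(sigs[:, medoid])
    M = np.column_stack(cols)
    return M / M.sum(axis=0)


def extract_denovo(matrix: pd.DataFrame, rank_range=range(1, 7),
                   n_bootstrap: int = 50, n_restarts: int = 3,
                   seed: int = 0, stability_threshold: float = 0.8,
                   max_iter: int = 1000, tol: float = 1e-8
                   ) -> ExtractionResult:
    """Bootstrap-stability de novo extraction from a 96 x S count matrix.

    For each rank, every bootstrap resample is factorized from
    ``n_restarts`` random initializations (best KL kept); the pooled
    signatures are clustered by cosine distance into ``rank`` groups and
    the mean silhouette of that clustering is the rank's stability.  The
    selected rank is the largest with stability >= the threshold whose
    median reconstruction error improves on the smallest rank's; the
    final signatures are the cluster medoids at that rank, and exposures
    are re-fitted on the original matrix by NNLS.
    """
    V = matrix.to_numpy(dtype=float)
    if V.sum() == 0:
        raise ValueError("all-zero context matrix")
    S = V.shape[1]
    if S < 2:
        raise ValueError("need at least 2 samples for de novo extraction")
    rng = np.random.default_rng(seed)
    rank_rng = {r: np.random.default_rng(rng.integers(2**31))
                for r in rank_range}

    rows = []
    per_rank = {}
    for rank in rank_range:
        if rank > min(96, S):
            continue
        r_rng = rank_rng[rank]
        pooled = []
        errors = []
        for _ in range(n_bootstrap):
            Vb = _bootstrap_columns(V, r_rng)
            best = None
            for _ in range(n_restarts):
                W, H, err = kl_nmf(Vb, rank, r_rng, max_iter=max_iter, tol=tol)
                if best is None or err < best[2]:
                    best = (W, H, err)
            W = best[0] / (best[0].sum(axis=0) + _EPS)
            pooled.append(W)
            errors.append(best[2])
        labels, stability = _cluster_replicates(pooled, rank)
        per_rank[rank] = (np.concatenate(pooled, axis=1), labels)
        rows.append({"rank": rank, "stability": stability,
                     "median_error": float(np.median(errors))})

    table = pd.DataFrame(rows)
    base_rank = int(table["rank"].min())
    base_err = float(table.loc[table["rank"] == base_rank, "median_error"].iloc[0])
    candidates = [
        int(r.rank) for r in table.itertuples()
        if r.stability >= stability_threshold
        and (r.rank == base_rank or r.median_error < base_err)
    ]
    if candidates:
        selected = max(candidates)
    else:
        selected = int(table.loc[table["stability"].idxmax(), "rank"])
    report = RankSelectionReport(table, selected, stability_threshold,
                                 n_bootstrap, n_restarts, seed)

    sigs, labels = per_rank[selected]
    W = _medoids(sigs, labels, selected)
    names = [f"DN{i + 1}" for i in range(W.shape[1])]
    signatures = pd.DataFrame(W, index=matrix.index, columns=names)

    expo = np.zeros((W.shape[1], S))
    unfit = []
    for j in range(S):
        col = V[:, j]
        if col.sum() == 0:
            unfit.append(matrix.columns[j])
            continue
        w, _ = nnls(W, col / col.sum())
        if w.sum() > 0:
            expo[:, j] = w / w.sum()
        else:
            unfit.append(matrix.columns[j])
    exposures = pd.DataFrame(expo, index=names, columns=matrix.columns)
    return ExtractionResult(signatures, exposures, report, unfit)


# ---------------------------------------------------------------------------
# NNLS similarity to a reference catalog


@dataclass
class SimilarityEntry:
    """NNLS decomposition of one signature over a reference catalog."""

    weights: pd.Series           # normalized to sum 1
    retained: pd.Series          # weights >= retention threshold
    composite: np.ndarray        # normalized catalog @ weights
    cosine: float
    matched: bool
    residual: float


def nnls_decompose(signature: np.ndarray, catalog: pd.DataFrame,
                   retention: float = 0.1,
                   match_threshold: float = 0.85,
                   pairwise: bool = False) -> SimilarityEntry:
    """Express a signature as a conic combination of catalog signatures.

    A signature whose NNLS composite reaches cosine >= ``match_threshold``
    is considered explained by known processes; below that it is flagged
    novel.  With ``pairwise=True`` the search is restricted to the best
    single catalog signature or pair of signatures (exhaustive NNLS over
    all pairs) instead of the full catalog.
    """
    if catalog.shape[1] == 0:
        raise ValueError("empty reference catalog")
    s = np.asarray(signature, dtype=float).ravel()
    A = catalog.to_numpy(dtype=float)
    if pairwise:
        k = A.shape[1]
        best = None
        from itertools import combinations
        pools = [(j,) for j in range(k)] + list(combinations(range(k), 2))
        for pool in pools:
            wp, rp = nnls(A[:, list(pool)], s)
            if best is None or rp < best[2]:
                best = (pool, wp, rp)
        w = np.zeros(k)
        w[list(best[0])] = best[1]
        rnorm = best[2]
    else:
        w, rnorm = nnls(A, s)
    total = w.sum()
    wn = w / total if total > 0 else w
    weights = pd.Series(wn, index=catalog.columns)
    retained = weights[weights >= retention]
    composite = A @ w
    if composite.sum() > 0:
        composite = composite / composite.sum()
    cos = cosine_similarity(s, composite) if composite.sum() > 0 else 0.0
    return SimilarityEntry(weights, retained, composite, cos,
                           cos >= match_threshold, float(rnorm))


def match_catalog(signatures: pd.DataFrame, catalog: pd.DataFrame,
                  retention: float = 0.1, match_threshold: float = 0.85
                  ) -> pd.DataFrame:
    """Similarity report for every column of ``signatures``."""
    rows = []
    for name in signatures.columns:
        entry = nnls_decompose(signatures[name].to_numpy(), catalog,
                               retention, match_threshold)
        rows.append({
            "signature": name,
            "cosine": entry.cosine,
            "matched": entry.matched,
            "components": "+".join(entry.retained.sort_values(
                ascending=False).index),
            "weights": ";".join(
                f"{k}={v:.3f}" for k, v in entry.retained.sort_values(
                    ascending=False).items()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-sample exposure fitting (deconstructSigs scheme)


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_min(f, a: float, b: float, tol: float = 1e-9) -> float:
    """Golden-section minimizer of a unimodal function on [a, b]."""
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2


def _fit_weights(p: np.ndarray, B: np.ndarray, tol: float,
                 max_sweeps: int = 200) -> np.ndarray:
    """Coordinate-wise golden-section descent on the normalized SSE."""
    k = B.shape[1]

    def sse(wv: np.ndarray) -> float:
        t = wv.sum()
        if t <= 0:
            return float(np.dot(p, p))
        r = p - B @ (wv / t)
        return float(np.dot(r, r))

    # seed with the single best-fitting signature, then refine
    w = np.zeros(k)
    singles = [float(np.dot(p - B[:, j], p - B[:, j])) for j in range(k)]
    w[int(np.argmin(singles))] = 1.0
    current = sse(w)
    for _ in range(max_sweeps):
        before = current
        for j in range(k):
            def fj(x, j=j):
                wj = w.copy()
                wj[j] = x
                return sse(wj)
            x = _golden_min(fj, 0.0, 1.0)
            fx = fj(x)
            if fx < current:
                w[j] = x
                current = fx
        if before - current < tol:
            break
    return w


def fit_exposures(matrix: pd.DataFrame, basis: pd.DataFrame,
                  cutoff: float = 0.06, tol: float = 1e-6
                  ) -> tuple[pd.DataFrame, pd.Series, list]:
    """Fit per-sample relative signature exposures to a fixed basis.

    Each sample's 96-count column is normalized to fractions and a
    non-negative weight vector is refined signature-by-signature with
    golden-section line searches until the squared-error improvement per
    sweep falls below ``tol``.  Weights below ``cutoff`` (default 6%) are
    zeroed and the rest renormalized to sum 1.  Returns (k x S exposure
    matrix, per-sample reconstruction SSE, list of unfittable samples).
    """
    if not 0 <= cutoff <= 0.5:
        raise ValueError("cutoff must be in [0, 0.5]")
    B = basis.to_numpy(dtype=float)
    B = B / B.sum(axis=0)
    V = matrix.to_numpy(dtype=float)
    k, S = B.shape[1], V.shape[1]
    expo = np.zeros((k, S))
    errors = np.full(S, np.nan)
    unfit = []
    for j in range(S):
        total = V[:, j].sum()
        if total == 0:
            unfit.append(matrix.columns[j])
            continue
        p = V[:, j] / total
        w = _fit_weights(p, B, tol)
        if w.sum() <= 0:
            unfit.append(matrix.columns[j])
            continue
        wn = w / w.sum()
        wn[wn < cutoff] = 0.0
        if wn.sum() == 0:
            unfit.append(matrix.columns[j])
            continue
        wn = wn / wn.sum()
        expo[:, j] = wn
        r = p - B @ wn
        errors[j] = float(np.dot(r, r))
    exposures = pd.DataFrame(expo, index=list(basis.columns),
                             columns=list(matrix.columns))
    return exposures, pd.Series(errors, index=list(matrix.columns)), unfit


def reconstruct_spectrum(basis: pd.DataFrame, exposure: np.ndarray,
                         total: float) -> np.ndarray:
    """Expected 96-count vector for a sample: total * basis @ exposure."""
    B = basis.to_numpy(dtype=float)
    e = np.asarray(exposure, dtype=float).ravel()
    if B.shape[1] != e.shape[0]:
        raise ValueError("basis and exposure shapes do not conform")
    return total * (B @ e)
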