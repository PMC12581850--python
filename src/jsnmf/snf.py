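"""Similarity-network fusion and extraction of the n x K prior matrix R.

The pipeline is: per-modality Euclidean distances -> scaled-exponential
similarity kernel with local bandwidth -> row-stochastic k-nearest-neighbor
affinity -> convex fusion across modalities -> (diagnostic) spectral
clustering against the recurrence label -> PCA of the fused affinity,
min-max rescaled per component into [0, 1], giving the nonnegative prior R
that anchors the basis matrix W during factorization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score

from .io import MultiOmicsDataset, RunConfig, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AffinityGraph:
    """An n x n sample graph at one stage of the fusion pipeline."""

    matrix: np.ndarray
    kind: str  # distance | similarity | knn_affinity | fused
    k_neighbors: int | None = None
    epsilon: float | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PriorMatrix:
    """Nonnegative n x K prior distilled from the fused affinity network."""

    matrix: np.ndarray
    source_rank: int
    column_scaling: list[tuple[float, float]] = field(default_factory=list)


def pairwise_distance(X: np.ndarray) -> AffinityGraph:
    """Euclidean distances between sample rows of one modality block."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 samples to define neighborhoods")
    if not np.all(np.isfinite(X)):
        raise ValidationError("distance input must be finite")
    D = squareform(pdist(X, metric="euclidean"))
    return AffinityGraph(matrix=D, kind="distance")


def similarity_kernel(D: AffinityGraph, k: int, mu: float = 0.5) -> AffinityGraph:
    """Scaled-exponential kernel with local bandwidth.

    S_ij = exp(-D_ij^2 / (mu * sigma_ij)) with
    sigma_ij = (mean k-NN distance of i + mean k-NN distance of j + D_ij) / 3,
    the mean taken over each sample's k nearest other samples.
    """
    if D.kind != "distance":
        raise ValidationError("similarity_kernel expects a distance graph")
    M = D.matrix
    n = M.shape[0]
    if not 1 <= k < n:
        raise ValidationError("k must satisfy 1 <= k < n")
    if not M.any():
        raise ValidationError("degenerate input: all samples are identical")
    off = M + np.diag(np.full(n, np.inf))  # exclude self from neighborhoods
    knn_mean = np.sort(off, axis=1)[:, :k].mean(axis=1)
    sigma = (knn_mean[:, None] + knn_mean[None, :] + M) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.exp(-(M**2) / (mu * sigma))
    S[M == 0] = 1.0  # kernel at zero distance (also fixes 0/0 at sigma == 0)
    return AffinityGraph(matrix=S, kind="similarity", k_neighbors=k)


def _neighbor_mask(S: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of each row's k most similar other samples.

    Ties at the k-th neighbor are broken toward the smaller sample index.
    """
    n = S.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, -S[i]))  # descending similarity, then index
        order = order[order != i]
        mask[i, order[:k]] = True
    return mask


def knn_affinity(S: AffinityGraph, k: int, epsilon: float) -> AffinityGraph:
    """Row-stochastic k-NN affinity: mass 1-epsilon inside each neighborhood.

    A_ij = (1-eps) S_ij / sum_{j in N_k(i)} S_ij for neighbors,
    eps S_ij / sum_{j not in N_k(i)} S_ij otherwise; self is excluded from
    both sets (A_ii = 0).  Rows whose out-of-neighborhood mass is zero get
    the eps mass folded back into the neighborhood.
    """
    if S.kind not in ("similarity", "distance"):
        raise ValidationError("knn_affinity expects a similarity graph")
    M = np.asarray(S.matrix, dtype=float)
    n = M.shape[0]
    if not 1 <= k < n:
        raise ValidationError("k must satisfy 1 <= k < n")
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must lie in (0, 0.5)")
    nb = _neighbor_mask(M, k)
    out = ~nb
    np.fill_diagonal(out, False)
    A = np.zeros_like(M)
    for i in range(n):
        s_in = M[i, nb[i]].sum()
        if s_in <= 0:
            raise ValidationError(f"row {i}: zero similarity mass inside the neighborhood")
        s_out = M[i, out[i]].sum()
        if s_out > 0:
            A[i, nb[i]] = (1 - epsilon) * M[i, nb[i]] / s_in
            A[i, out[i]] = epsilon * M[i, out[i]] / s_out
        else:
            logger.warning("row %d: zero out-of-neighborhood mass; folding eps into neighborhood", i)
            A[i, nb[i]] = M[i, nb[i]] / s_in
    return AffinityGraph(matrix=A, kind="knn_affinity", k_neighbors=k, epsilon=epsilon)


def fuse(affinities: list[AffinityGraph], weights) -> AffinityGraph:
    """Convex combination of k-NN affinity graphs: A = sum_m w_m A^(m)."""
    w = np.asarray(weights, dtype=float)
    if len(affinities) != len(w):
        raise ValidationError("one weight per affinity graph required")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("fusion weights must be nonnegative and sum to 1")
    shapes = {g.matrix.shape for g in affinities}
    if len(shapes) != 1:
        raise ValidationError("all affinity graphs must share one shape")
    A = sum(wi * g.matrix for wi, g in zip(w, affinities))
    return AffinityGraph(matrix=A, kind="fused")


def spectral_check(A: AffinityGraph, labels, seed: int = 0) -> tuple[np.ndarray, float]:
    """Diagnostic 2-cluster spectral clustering of the fused affinity.

    Clusters the symmetrized graph (A + A^T)/2 and reports the
    adjusted-Rand agreement with the binary recurrence label.  Purely a
    sanity check on the fusion; it does not alter the pipeline.
    """
    sym = (A.matrix + A.matrix.T) / 2.0
    labels = np.asarray(labels)
    if labels.shape[0] != sym.shape[0]:
        raise ValidationError("labels length must equal the number of samples")
    ncomp, _ = connected_components((sym > 0).astype(int), directed=False)
    if ncomp > 2:
        logger.warning("fused graph has %d connected components; clustering anyway", ncomp)
    sc = SpectralClustering(
        n_clusters=2, affinity="precomputed", random_state=seed, assign_labels="kmeans"
    )
    assignments = sc.fit_predict(sym)
    return assignments, float(adjusted_rand_score(labels, assignments))


def extract_prior(A: AffinityGraph, K: int) -> PriorMatrix:
    """Distill the n x K prior R by PCA of the fused affinity matrix.

    The affinity is column-centered and its K leading principal-component
    score vectors are taken; each component is sign-fixed (the largest-
    magnitude loading entry is made positive) and min-max scaled into
    [0, 1] so R can serve as a nonnegative anchor for W.
    """
    M = A.matrix
    n = M.shape[0]
    if not 1 <= K < n:
        raise ValidationError("K must satisfy 1 <= K < n")
    centered = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    scores = U[:, :K] * s[:K]
    for k in range(K):
        v = Vt[k]
        if v[np.argmax(np.abs(v))] < 0:
            scores[:, k] = -scores[:, k]
    scaling: list[tuple[float, float]] = []
    R = np.empty_like(scores)
    for k in range(K):
        lo, hi = float(scores[:, k].min()), float(scores[:, k].max())
        scaling.append((lo, hi))
        if hi - lo <= 0:
            logger.warning("prior component %d is constant; mapped to zero", k + 1)
            R[:, k] = 0.0
        else:
            R[:, k] = (scores[:, k] - lo) / (hi - lo)
    return PriorMatrix(matrix=R, source_rank=K, column_scaling=scaling)


def build_prior(
    dataset: MultiOmicsDataset, config: RunConfig
) -> tuple[AffinityGraph, PriorMatrix, dict]:
    """Full fusion pipeline: blocks -> fused affinity -> prior R.

    Returns the fused graph, the prior, and a diagnostics dict holding the
    spectral-clustering agreement with the recurrence label.
    """
    n = dataset.n_samples
    k = config.k_neighbors if config.k_neighbors is not None else max(1, math.ceil(n / 10))
    if k >= n:
        raise ValidationError("k_neighbors must be smaller than the number of samples")
    graphs = []
    for X in dataset.blocks:
        D = pairwise_distance(X)
        S = similarity_kernel(D, k=k, mu=config.mu)
        graphs.append(knn_affinity(S, k=k, epsilon=config.epsilon))
    fused = fuse(graphs, config.fusion_weights)
    assignments, ari = spectral_check(fused, dataset.labels, seed=config.seed)
    prior = extract_prior(fused, config.K)
    return fused, prior, {"spectral_ari": ari, "assignments": assignments, "k_neighbors": k}
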