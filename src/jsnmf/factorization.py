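"""Joint NMF and its similarity/orthogonality-constrained extension.

Three nonnegative blocks X_I (n x q_I) sharing samples are factorized as
X_I ~= W H_I with one common basis W (n x K) and per-modality coefficient
matrices H_I (K x q_I).  The constrained model minimizes

    J(W, H) = sum_I ( ||X_I - W H_I||_F^2 + (beta/2) ||H_I H_I^T - M||_F^2 )
              + alpha ||W - R||_F^2

where R is the SNF/PCA prior and M is either the identity or the all-ones
K x K matrix (``ortho_target``).  The orthogonality penalty carries the
weight beta/2 so that the multiplicative update rules below are its exact
KKT fixed-point iterations and the objective is provably non-increasing;
this is the scale at which the model's printed gradients, updates and
convergence theorem are mutually consistent.

Updates (elementwise, with a small positive denominator guard):

    W   <- W  * (sum_I X_I H_I^T + alpha R) / (sum_I W H_I H_I^T + alpha W)
    H_I <- H_I * (W^T X_I + beta M H_I)     / (W^T W H_I + beta H_I H_I^T H_I)

The H denominator is written in its nonnegative-split arrangement (the
-beta*M*H_I part of the gradient moves to the numerator), which keeps every
denominator strictly positive and is the arrangement the auxiliary-function
convergence argument supports.  At alpha = beta = 0 both rules reduce
exactly to the classical joint-NMF multiplicative updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .io import MultiOmicsDataset, RunConfig, ValidationError
from .snf import PriorMatrix

logger = logging.getLogger(__name__)

#: additive guard keeping multiplicative denominators strictly positive
GUARD = 1e-10
#: floor replacing structural zeros in the NNDSVD initialization
NNDSVD_FLOOR = 1e-6

VARIANTS = ("jnmf", "oc_jnmf", "snf_jnmf", "jsnmf")


class NumericalError(RuntimeError):
    """NaN/Inf appeared during the multiplicative updates."""

    def __init__(self, message: str, trace: "ConvergenceTrace | None" = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class FactorizationModel:
    W: np.ndarray
    H: list[np.ndarray]
    config: RunConfig
    variant: str
    sample_ids: list[str]
    feature_ids: list[list[str]]

    def reconstruct(self, block: int) -> np.ndarray:
        return self.W @ self.H[block]

    @property
    def K(self) -> int:
        return self.W.shape[1]


@dataclass
class ConvergenceTrace:
    """Per-iteration objective, relative error and successive-iterate distances."""

    objective: list[float] = field(default_factory=list)
    relative_error: list[float] = field(default_factory=list)
    dW: list[float] = field(default_factory=list)
    dH: list[list[float]] = field(default_factory=lambda: [[], [], []])

    def __len__(self) -> int:
        return len(self.objective)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iter": np.arange(1, len(self) + 1),
                "objective": self.objective,
                "relative_error": self.relative_error,
                "dW": self.dW,
                "dH1": self.dH[0],
                "dH2": self.dH[1],
                "dH3": self.dH[2],
            }
        )


def _as_blocks(data) -> list[np.ndarray]:
    if isinstance(data, MultiOmicsDataset):
        return data.blocks
    return [np.asarray(X, dtype=float) for X in data]


def scale_blocks(blocks) -> list[np.ndarray]:
    """Scale every feature column by its maximum into [0, 1].

    Keeps any one modality from dominating the Frobenius terms when the raw
    blocks live on very different scales.  Dividing by the column maximum
    (rather than min-max shifting) keeps zero at zero, so the nonnegative
    rank of the data is preserved and an exact low-rank factorization stays
    exactly representable after scaling.
    """
    out = []
    for X in _as_blocks(blocks):
        hi = X.max(axis=0)
        if (hi <= 0).any():
            logger.warning("%d all-zero feature column(s) left unscaled", int((hi <= 0).sum()))
        out.append(X / np.where(hi > 0, hi, 1.0))
    return out


def ortho_matrix(K: int, ortho_target: str) -> np.ndarray:
    if ortho_target == "identity":
        return np.eye(K)
    if ortho_target == "ones":
        return np.ones((K, K))
    raise ValidationError(f"unknown ortho_target {ortho_target!r}")


def nndsvd_init(data, K: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Deterministic NNDSVD initialization on the column-concatenated blocks.

    Boutsidis-Gallopoulos zero-fill variant with zeros replaced by a small
    floor so multiplicative updates can escape structural zeros.  The
    coefficient matrix is split column-wise back into the three H_I.
    """
    blocks = _as_blocks(data)
    widths = [X.shape[1] for X in blocks]
    X = np.hstack(blocks)
    n, q = X.shape
    if K > min(n, q):
        raise ValidationError(f"K={K} exceeds min(n, sum q_I)={min(n, q)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * max(n, q) * np.finfo(float).eps).sum()) if s[0] > 0 else 0
    if K > rank:
        logger.warning("K=%d exceeds numerical rank %d; trailing components seeded at floor", K, rank)
    W = np.zeros((n, K))
    H = np.zeros((K, q))
    if rank > 0:
        # leading singular triplet of a nonnegative matrix is nonnegative
        W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
        H[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for k in range(1, min(K, rank)):
        u, v = U[:, k], Vt[k]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_pos = np.linalg.norm(up) * np.linalg.norm(vp)
        n_neg = np.linalg.norm(un) * np.linalg.norm(vn)
        if n_pos >= n_neg and n_pos > 0:
            W[:, k] = np.sqrt(s[k] * n_pos) * up / np.linalg.norm(up)
            H[k] = np.sqrt(s[k] * n_pos) * vp / np.linalg.norm(vp)
        elif n_neg > 0:
            W[:, k] = np.sqrt(s[k] * n_neg) * un / np.linalg.norm(un)
            H[k] = np.sqrt(s[k] * n_neg) * vn / np.linalg.norm(vn)
    W[W < NNDSVD_FLOOR] = NNDSVD_FLOOR
    H[H < NNDSVD_FLOOR] = NNDSVD_FLOOR
    return W, list(np.split(H, np.cumsum(widths)[:-1], axis=1))


def objective(
    W: np.ndarray,
    H: list[np.ndarray],
    data,
    R: np.ndarray | None,
    alpha: float,
    beta: float,
    ortho_target: str = "identity",
) -> float:
    """The constrained joint-NMF objective J(W, H) (see module docstring)."""
    blocks = _as_blocks(data)
    M = ortho_matrix(W.shape[1], ortho_target)
    val = 0.0
    for X, Hi in zip(blocks, H):
        val += float(np.linalg.norm(X - W @ Hi, "fro") ** 2)
        if beta:
            val += 0.5 * beta * float(np.linalg.norm(Hi @ Hi.T - M, "fro") ** 2)
    if alpha:
        if R is None:
            raise ValidationError("alpha > 0 requires a prior matrix R")
        val += alpha * float(np.linalg.norm(W - R, "fro") ** 2)
    return val


def gradients(
    W: np.ndarray,
    H: list[np.ndarray],
    data,
    R: np.ndarray | None,
    alpha: float,
    beta: float,
    ortho_target: str = "identity",
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Analytic gradients of :func:`objective` with respect to W and each H_I."""
    blocks = _as_blocks(data)
    M = ortho_matrix(W.shape[1], ortho_target)
    gW = sum(-2.0 * X @ Hi.T + 2.0 * W @ (Hi @ Hi.T) for X, Hi in zip(blocks, H))
    if alpha:
        gW = gW + 2.0 * alpha * W - 2.0 * alpha * R
    gH = []
    for X, Hi in zip(blocks, H):
        g = -2.0 * W.T @ X + 2.0 * (W.T @ W) @ Hi
        if beta:
            g = g + 2.0 * beta * (Hi @ Hi.T - M) @ Hi
        gH.append(g)
    return gW, gH


def _check_finite(W: np.ndarray, H: list[np.ndarray], it: int) -> None:
    if not np.all(np.isfinite(W)) or any(not np.all(np.isfinite(Hi)) for Hi in H):
        raise NumericalError(f"non-finite value appeared at iteration {it}")


def jsnmf_step(
    W: np.ndarray,
    H: list[np.ndarray],
    data,
    R: np.ndarray | None,
    alpha: float,
    beta: float,
    ortho_target: str = "identity",
) -> tuple[np.ndarray, list[np.ndarray]]:
    """One synchronous multiplicative update: W first, then each H_I with the new W."""
    blocks = _as_blocks(data)
    K = W.shape[1]
    M = ortho_matrix(K, ortho_target)
    if R is None:
        R = np.zeros_like(W)
    num = sum(X @ Hi.T for X, Hi in zip(blocks, H)) + alpha * R
    den = sum(W @ (Hi @ Hi.T) for Hi in H) + alpha * W + GUARD
    W_new = W * num / den
    H_new = []
    for X, Hi in zip(blocks, H):
        num_h = W_new.T @ X + beta * (M @ Hi)
        den_h = (W_new.T @ W_new) @ Hi + beta * ((Hi @ Hi.T) @ Hi) + GUARD
        H_new.append(Hi * num_h / den_h)
    return W_new, H_new


def jnmf_step(W: np.ndarray, H: list[np.ndarray], data) -> tuple[np.ndarray, list[np.ndarray]]:
    """One unconstrained joint-NMF multiplicative update (alpha = beta = 0)."""
    return jsnmf_step(W, H, data, R=None, alpha=0.0, beta=0.0)


def relative_error(data, W: np.ndarray, H: list[np.ndarray]) -> float:
    """Scale-free reconstruction error summed over the three blocks.

    Per block: column-means of |X_I - W H_I|, divided by the block grand
    mean, then averaged over columns.
    """
    blocks = _as_blocks(data)
    total = 0.0
    for X, Hi in zip(blocks, H):
        gm = float(X.mean())
        if gm <= 0:
            raise ValidationError("relative_error undefined for a zero-mean block")
        col_means = np.abs(X - W @ Hi).mean(axis=0)
        total += float(np.mean(col_means / gm))
    return total


def _effective_params(variant: str, config: RunConfig) -> tuple[float, float]:
    if variant == "jnmf":
        return 0.0, 0.0
    if variant == "oc_jnmf":
        return 0.0, config.beta
    if variant == "snf_jnmf":
        return config.alpha, 0.0
    if variant == "jsnmf":
        return config.alpha, config.beta
    raise ValidationError(f"unknown variant {variant!r}")


def fit(
    dataset,
    R: PriorMatrix | np.ndarray | None,
    config: RunConfig,
    variant: str | None = None,
) -> tuple[FactorizationModel, ConvergenceTrace]:
    """NNDSVD-initialized multiplicative descent with the relative-change stopping rule.

    Iterates until the relative objective change drops below ``config.tol``
    or ``config.max_iter`` is reached.  Fully deterministic: the
    initialization is SVD-based and the updates contain no randomness.
    """
    variant = variant or config.variant
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    alpha, beta = _effective_params(variant, config)
    if isinstance(R, PriorMatrix):
        R = R.matrix
    if alpha > 0 and R is None:
        raise ValidationError(f"variant {variant!r} requires a prior matrix R")
    if isinstance(dataset, MultiOmicsDataset):
        sample_ids = dataset.sample_ids
        feature_ids = dataset.feature_ids
    else:
        sample_ids = [f"s{i + 1}" for i in range(np.asarray(dataset[0]).shape[0])]
        feature_ids = [[f"b{b + 1}_f{j + 1}" for j in range(np.asarray(X).shape[1])]
                       for b, X in enumerate(dataset)]
    blocks = _as_blocks(dataset)
    if config.scale_blocks:
        blocks = scale_blocks(blocks)
    if R is not None and R.shape != (blocks[0].shape[0], config.K):
        raise ValidationError("prior R must be shaped n x K")

    W, H = nndsvd_init(blocks, config.K)
    trace = ConvergenceTrace()
    obj_prev = objective(W, H, blocks, R, alpha, beta, config.ortho_target)
    for it in range(1, config.max_iter + 1):
        W_new, H_new = jsnmf_step(W, H, blocks, R, alpha, beta, config.ortho_target)
        try:
            _check_finite(W_new, H_new, it)
        except NumericalError as exc:
            exc.trace = trace
            raise
        obj = objective(W_new, H_new, blocks, R, alpha, beta, config.ortho_target)
        trace.objective.append(obj)
        trace.relative_error.append(relative_error(blocks, W_new, H_new))
        trace.dW.append(float(np.linalg.norm(W_new - W, "fro")))
        for b in range(3):
            trace.dH[b].append(float(np.linalg.norm(H_new[b] - H[b], "fro")))
        W, H = W_new, H_new
        if abs(obj - obj_prev) / max(obj_prev, 1e-30) < config.tol:
            break
        obj_prev = obj
    model = FactorizationModel(
        W=W, H=H, config=config, variant=variant,
        sample_ids=list(sample_ids), feature_ids=[list(f) for f in feature_ids],
    )
    return model, trace


def per_sample_correlations(blocks, model: FactorizationModel) -> list[np.ndarray]:
    """Pearson correlation of each sample's observed vs reconstructed features, per block.

    Samples whose observed or reconstructed feature vector is constant get
    NaN (excluded from summaries with a warning).
    """
    out = []
    for b, X in enumerate(_as_blocks(blocks)):
        Xhat = model.reconstruct(b)
        r = np.full(X.shape[0], np.nan)
        for i in range(X.shape[0]):
            if np.ptp(X[i]) == 0 or np.ptp(Xhat[i]) == 0:
                continue
            r[i] = pearsonr(X[i], Xhat[i])[0]
        n_bad = int(np.isnan(r).sum())
        if n_bad:
            logger.warning("block %d: %d sample(s) with undefined correlation excluded", b + 1, n_bad)
        out.append(r)
    return out


def reconstruction_metrics(
    dataset,
    model: FactorizationModel,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Relative error, Euclidean distance and per-sample correlation summaries.

    The Euclidean distance is sum_I ||X_I - W H_I||_F.  Per-block mean
    sample correlations carry a seeded percentile-bootstrap 95% interval
    over samples.  Metrics are computed on the same (scaled) matrices the
    model was fitted on.
    """
    blocks = _as_blocks(dataset)
    if model.config.scale_blocks:
        blocks = scale_blocks(blocks)
    rng = np.random.default_rng(seed)
    euclid = sum(float(np.linalg.norm(X - model.reconstruct(b), "fro"))
                 for b, X in enumerate(blocks))
    corrs = per_sample_correlations(blocks, model)
    per_block = []
    for r in corrs:
        valid = r[~np.isnan(r)]
        if valid.size == 0:
            per_block.append({"mean_correlation": float("nan"), "ci95": (float("nan"),) * 2})
            continue
        boots = np.array([
            valid[rng.integers(0, valid.size, valid.size)].mean() for _ in range(n_boot)
        ])
        per_block.append({
            "mean_correlation": float(valid.mean()),
            "ci95": (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
        })
    return {
        "relative_error": relative_error(blocks, model.W, model.H),
        "euclidean_distance": euclid,
        "per_block": per_block,
        "per_sample_correlations": corrs,
    }


def match_components(W: np.ndarray, W_true: np.ndarray) -> tuple[np.ndarray, float]:
    """Hungarian matching of estimated to planted components on Pearson correlation.

    Returns the column permutation (estimated column for each true column)
    and the mean matched correlation.
    """
    Kt = W_true.shape[1]
    K = W.shape[1]
    C = np.zeros((Kt, K))
    for a in range(Kt):
        for b in range(K):
            if np.ptp(W_true[:, a]) == 0 or np.ptp(W[:, b]) == 0:
                continue
            C[a, b] = pearsonr(W_true[:, a], W[:, b])[0]
    rows, cols = linear_sum_assignment(-C)
    return cols, float(C[rows, cols].mean())
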