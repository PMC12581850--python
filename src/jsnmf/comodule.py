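"""Co-module extraction and the evaluation statistics built on the factors.

A co-module is one latent component k together with the features of each
modality loading strongly on it.  Association with the clinical recurrence
label runs through the basis matrix W; feature-level screening uses the
Mann-Whitney rank-sum test; cross-modal consistency is measured by the
overlap ratio O = m/n between pathways enriched in the module's genes and
the module's selected pathway-score features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .factorization import FactorizationModel
from .io import GeneSetCollection, MultiOmicsDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CoModule:
    """One component with its selected features and association statistics."""

    component_index: int  # 1-based, matching W column comp_<k>
    selected_features: list[set[str]] = field(default_factory=lambda: [set(), set(), set()])
    clinical_correlations: dict[str, tuple[float, float]] = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None
    overlap_ratio: float | None = None


def select_features(H: np.ndarray, k: int, feature_ids, T: float = 1.5) -> set[str]:
    """Features whose loading on component k exceeds mean + T * SD of that row.

    The SD is the population SD (ddof=0).  A constant row selects nothing.
    """
    if not 1 <= k <= H.shape[0]:
        raise ValidationError(f"component index {k} out of range 1..{H.shape[0]}")
    if T <= 0:
        raise ValidationError("threshold T must be positive")
    row = np.asarray(H[k - 1], dtype=float)
    sd = row.std()
    if sd == 0:
        logger.warning("component %d has a constant loading row; empty selection", k)
        return set()
    cut = row.mean() + T * sd
    return {fid for fid, v in zip(feature_ids, row) if v > cut}


def clinical_association(W: np.ndarray, clinical: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p of every W column against every clinical variable.

    Variables must be numeric (binary coded 0/1).  Returns a tidy frame with
    columns component, variable, r, p; constant variables are flagged with
    NaN statistics.
    """
    records = []
    K = W.shape[1]
    for var in clinical.columns:
        y = clinical[var].to_numpy(dtype=float)
        const = np.ptp(y) == 0
        if const:
            logger.warning("clinical variable %r is constant; correlation undefined", var)
        for k in range(K):
            if const or np.ptp(W[:, k]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = pearsonr(W[:, k], y)
            records.append({"component": k + 1, "variable": var, "r": r, "p": p})
    return pd.DataFrame(records)


def select_recurrence_component(W: np.ndarray, labels) -> int | None:
    """The component most associated with recurrence: max |r| among p < 0.05 columns.

    Returns a 1-based index, or None when no column is significant.
    """
    assoc = clinical_association(W, pd.DataFrame({"recurrence": np.asarray(labels)}))
    sig = assoc[(assoc["p"] < 0.05) & assoc["r"].notna()]
    if sig.empty:
        return None
    return int(sig.loc[sig["r"].abs().idxmax(), "component"])


def differential_filter(
    X: np.ndarray,
    feature_ids,
    labels,
    p_thresh: float = 0.01,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney (Wilcoxon rank-sum) screening.

    Normal approximation with tie correction (no continuity correction).
    Returns a frame with feature, p, q (Benjamini-Hochberg within the block)
    and a ``significant`` flag for raw p < ``p_thresh``.
    """
    labels = np.asarray(labels).astype(int)
    g1 = X[labels == 1]
    g0 = X[labels == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValidationError("both label groups must be non-empty")
    if min(len(g1), len(g0)) < 3:
        logger.warning("a label group has fewer than 3 samples; normal approximation is crude")
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            pvals[j] = 1.0  # every value tied: no evidence of a shift
            continue
        pvals[j] = mannwhitneyu(
            g1[:, j], g0[:, j], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )[1]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "feature": list(feature_ids),
        "p": pvals,
        "q": qvals,
        "significant": pvals < p_thresh,
    })


def pairwise_correlation(
    A: pd.DataFrame,
    B: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation and two-sided p for every (A-feature, B-feature) pair.

    ``method`` is ``pearson`` or ``spearman``; rows with a constant feature
    are flagged with NaN.  Adds a ``significant`` flag at p < 0.05.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    if len(A) != len(B):
        raise ValidationError("A and B must share samples")
    corr = pearsonr if method == "pearson" else spearmanr
    records = []
    for fa in A.columns:
        x = A[fa].to_numpy(dtype=float)
        for fb in B.columns:
            y = B[fb].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = corr(x, y)
            records.append({"feature_a": fa, "feature_b": fb, "r": float(r), "p": float(p)})
    df = pd.DataFrame(records)
    df["significant"] = df["p"] < 0.05
    return df


def enrich(
    genes: set[str],
    collection: GeneSetCollection,
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene selection in each set.

    p = P[overlap >= observed] with universe ``background``; q-values are
    Benjamini-Hochberg within the collection; ``enriched`` flags q < 0.05.
    """
    if not genes <= background:
        raise ValidationError("selection must be a subset of the background")
    if not genes:
        return pd.DataFrame(columns=["set", "overlap", "set_size", "p", "q", "enriched"])
    N = len(background)
    n_sel = len(genes)
    records = []
    for name, members in collection.sets.items():
        members = members & background
        ov = len(genes & members)
        p = float(hypergeom.sf(ov - 1, N, len(members), n_sel)) if members else 1.0
        records.append({"set": name, "overlap": ov, "set_size": len(members), "p": p})
    df = pd.DataFrame(records)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["enriched"] = df["q"] < 0.05
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def overlap_ratio(enriched_sets, significant_pathways) -> float | None:
    """O = |enriched ∩ significant| / |enriched|; None when nothing is enriched."""
    enriched = set(enriched_sets)
    if not enriched:
        return None
    return len(enriched & set(significant_pathways)) / len(enriched)


def _auc_rank(x: np.ndarray, labels: np.ndarray) -> float:
    from scipy.stats import rankdata

    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(x)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def feature_auc(x, labels) -> tuple[float, tuple[float, float]]:
    """ROC AUC via the rank (Mann-Whitney) formulation with a DeLong 95% CI.

    The variance uses the placement-value (structural component) estimator;
    the interval is clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = x[labels == 1]
    neg = x[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present for ROC analysis")
    auc = _auc_rank(x, labels)
    # DeLong placements: V10_i = P(X_neg < pos_i) + 0.5 P(X_neg = pos_i)
    v10 = np.array([((neg < xi).mean() + 0.5 * (neg == xi).mean()) for xi in pos])
    v01 = np.array([((pos > xj).mean() + 0.5 * (pos == xj).mean()) for xj in neg])
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    se = float(np.sqrt(s10 / len(pos) + s01 / len(neg)))
    lo, hi = max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se)
    return auc, (lo, hi)


def extract_comodules(
    model: FactorizationModel,
    dataset: MultiOmicsDataset,
    collection: GeneSetCollection | None = None,
    T: float | None = None,
) -> list[CoModule]:
    """Build one CoModule per component: selections, clinical r, enrichment, O.

    Gene enrichment (modality 2) runs against ``collection`` with the
    dataset's modality-2 features as the background; the overlap ratio
    compares enriched set names with the selected modality-3 features.
    """
    T = T if T is not None else model.config.zscore_T
    clin = pd.DataFrame({"recurrence": dataset.labels}, index=dataset.sample_ids)
    if dataset.covariates is not None:
        clin = pd.concat([clin, dataset.covariates], axis=1)
    assoc = clinical_association(model.W, clin)
    modules = []
    for k in range(1, model.K + 1):
        mod = CoModule(component_index=k)
        mod.selected_features = [
            select_features(model.H[b], k, model.feature_ids[b], T=T) for b in range(3)
        ]
        rows = assoc[assoc["component"] == k]
        mod.clinical_correlations = {
            r["variable"]: (r["r"], r["p"]) for _, r in rows.iterrows()
        }
        if collection is not None:
            background = set(model.feature_ids[1])
            mod.enrichment = enrich(mod.selected_features[1] & background, collection, background)
            enriched = set(mod.enrichment.loc[mod.enrichment["enriched"], "set"])
            mod.overlap_ratio = overlap_ratio(enriched, mod.selected_features[2])
        modules.append(mod)
    return modules
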