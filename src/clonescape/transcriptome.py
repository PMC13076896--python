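"""Bulk-expression scoring and cell-fraction deconvolution.

Implements the expression-side read-outs of the pipeline: mean-z gene-set
scores, the squamous-minus-classical gradient score, rank-based
single-sample enrichment for stromal/immune (ESTIMATE-like) scores,
constrained-least-squares cell-type deconvolution with an explicit
uncharacterized remainder, and PCA + k-means sample clustering.

All scores operate on log2(TPM + 1); the enrichment score is rank-based
and therefore invariant to monotone within-sample transformations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "CellFractionEstimate",
    "gene_set_score",
    "gradient_score",
    "ssgsea_score",
    "estimate_scores",
    "deconvolve_fractions",
    "pca_cluster",
]


@dataclass
class CellFractionEstimate:
    sample_id: str
    fractions: dict[str, float]
    uncharacterized: float

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.fractions.values()):
            raise ValueError("negative cell fraction")
        total = sum(self.fractions.values()) + self.uncharacterized
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, expected 1")


def _log_expr(expr: pd.DataFrame) -> pd.DataFrame:
    return np.log2(expr + 1.0)


def gene_set_score(expr: pd.DataFrame, gene_set: Sequence[str]) -> pd.Series:
    """Mean z-score of a gene set per sample.

    log2(TPM+1), per-gene z-score across samples, then the mean over the
    set genes present in the matrix.  Genes constant across samples
    contribute 0.
    """
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise KeyError(
            f"no gene-set members in matrix; missing {list(gene_set)[:5]}...")
    lg = _log_expr(expr.loc[present])
    mu = lg.mean(axis=1)
    sd = lg.std(axis=1, ddof=0)
    z = lg.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z.mean(axis=0)


def gradient_score(expr: pd.DataFrame, squamous_set: Sequence[str],
                   classical_set: Sequence[str]) -> pd.Series:
    """Squamous score minus classical score; higher = more squamous-like."""
    return gene_set_score(expr, squamous_set) - gene_set_score(expr, classical_set)


def ssgsea_score(expr: pd.DataFrame, gene_set: Sequence[str],
                 exponent: float = 0.25) -> pd.Series:
    """Single-sample rank-based enrichment score.

    Per sample, genes are ranked by expression (descending; ties broken by
    gene-id order so the score is deterministic).  A running sum increases
    by the rank weight ``|r|^exponent`` at set genes (normalized) and
    decreases uniformly at non-set genes; the score is the signed maximum
    deviation of that walk.
    """
    set_genes = set(gene_set) & set(expr.index)
    if not set_genes:
        raise KeyError("gene set has no members in the matrix")
    genes = np.array(expr.index)
    in_set = np.isin(genes, list(set_genes))
    n = len(genes)
    scores = {}
    for col in expr.columns:
        vals = expr[col].values
        # descending expression, gene-id order breaks ties
        order = np.lexsort((genes, -vals))
        ranks = np.arange(n, 0, -1, dtype=float)   # top gene gets rank n
        hit = in_set[order]
        w = ranks ** exponent
        w[~hit] = 0.0
        hit_cdf = np.cumsum(w) / w.sum()
        miss_cdf = np.cumsum(~hit) / (n - len(set_genes))
        dev = hit_cdf - miss_cdf
        scores[col] = float(dev[np.argmax(np.abs(dev))])
    return pd.Series(scores)


def estimate_scores(expr: pd.DataFrame, stromal_set: Sequence[str],
                    immune_set: Sequence[str],
                    exponent: float = 0.25) -> pd.DataFrame:
    """Stromal, immune and combined (ESTIMATE-like) enrichment per sample."""
    stromal = ssgsea_score(expr, stromal_set, exponent)
    immune = ssgsea_score(expr, immune_set, exponent)
    return pd.DataFrame({"stromal": stromal, "immune": immune,
                         "estimate": stromal + immune})


def deconvolve_fractions(expr_sample: pd.Series,
                         reference_profiles: pd.DataFrame,
                         ridge: float = 0.0) -> CellFractionEstimate:
    """Constrained least-squares cell-type fractions for one sample.

    Minimizes ``||R w - g||^2`` over ``w >= 0, sum(w) <= 1`` on the shared
    reference-gene subspace; ``1 - sum(w)`` is reported as the
    uncharacterized fraction.  Near-collinear references trigger a warning
    and a small ridge penalty.
    """
    genes = [g for g in reference_profiles.index if g in expr_sample.index]
    if len(genes) < reference_profiles.shape[1]:
        raise ValueError("fewer shared genes than cell types")
    if len(genes) < 50:
        warnings.warn(f"only {len(genes)} shared reference genes",
                      stacklevel=2)
    R = reference_profiles.loc[genes].values.astype(float)
    g = expr_sample.loc[genes].values.astype(float)
    # scale for conditioning only; solution in original units
    scale = np.linalg.norm(R, axis=0)
    scale[scale == 0] = 1.0
    cond = np.linalg.cond(R / scale)
    if cond > 1e8 and ridge == 0.0:
        warnings.warn(f"ill-conditioned reference (cond={cond:.2g}); "
                      "adding ridge", stacklevel=2)
        ridge = 1e-6 * float((R ** 2).sum())
    k = R.shape[1]
    norm2 = float(g @ g) or 1.0

    def obj(w):
        r = R @ w - g
        return (r @ r + ridge * w @ w) / norm2

    def grad(w):
        return (2.0 * R.T @ (R @ w - g) + 2.0 * ridge * w) / norm2

    cons = [{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
             "jac": lambda w: -np.ones_like(w)}]
    w0 = np.full(k, 1.0 / (k + 1))
    res = minimize(obj, w0, jac=grad, method="SLSQP",
                   bounds=[(0.0, 1.0)] * k, constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-14})
    w = np.clip(res.x, 0.0, None)
    if w.sum() > 1.0:
        w /= w.sum()
    fractions = {ct: float(v)
                 for ct, v in zip(reference_profiles.columns, w)}
    return CellFractionEstimate(
        sample_id=str(expr_sample.name),
        fractions=fractions,
        uncharacterized=float(1.0 - w.sum()))


def deconvolve_matrix(expr: pd.DataFrame, reference_profiles: pd.DataFrame
                      ) -> pd.DataFrame:
    """Fractions for every sample; columns are cell types plus
    'uncharacterized'."""
    rows = {}
    for col in expr.columns:
        est = deconvolve_fractions(expr[col], reference_profiles)
        rows[col] = {**est.fractions, "uncharacterized": est.uncharacterized}
    return pd.DataFrame(rows).T


def pca_cluster(expr: pd.DataFrame, n_clusters: int = 2, n_pcs: int = 10,
                seed: Optional[int] = None,
                squamous_set: Optional[Sequence[str]] = None,
                classical_set: Optional[Sequence[str]] = None) -> pd.Series:
    """PCA + k-means clustering of samples.

    Expression is log-transformed and per-gene z-scored; k-means (10
    restarts, seeded) runs on the top principal components.  When marker
    sets are given, cluster labels are ordered by decreasing mean gradient
    score (cluster 1 = most squamous-like); otherwise by decreasing cluster
    size.  Returned labels are 1-based and invariant to sample order.
    """
    if expr.shape[1] < n_clusters:
        raise ValueError("need at least n_clusters samples")
    # canonical sample order for determinism under permutation
    cols = sorted(expr.columns)
    lg = _log_expr(expr[cols])
    sd = lg.std(axis=1, ddof=0)
    z = lg.sub(lg.mean(axis=1), axis=0).div(sd.replace(0, np.nan),
                                            axis=0).dropna()
    max_pcs = min(z.shape[0], len(cols) - 1)
    if n_pcs > max_pcs:
        logger.warning("reducing n_pcs from %d to matrix rank %d",
                       n_pcs, max_pcs)
        n_pcs = max_pcs
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(z.values.T)
    km = KMeans(n_clusters=n_clusters, n_init=10,
                random_state=seed if seed is not None else 0)
    raw = km.fit_predict(pcs)
    labels = pd.Series(raw, index=cols)
    if squamous_set is not None and classical_set is not None:
        gs = gradient_score(expr[cols], squamous_set, classical_set)
        means = gs.groupby(labels).mean().sort_values(ascending=False)
        remap = {old: i + 1 for i, old in enumerate(means.index)}
    else:
        sizes = labels.value_counts()
        remap = {old: i + 1 for i, old in enumerate(sizes.index)}
    return labels.map(remap).reindex(expr.columns)
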