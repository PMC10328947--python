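"""Gene-signature scoring and correlation analyses.

Single-sample GSEA scores summarise how coordinately the genes of a set
are up- or down-regulated within one sample: genes are ranked by
expression, and the score is the sum over the ranking of the difference
between the rank-weighted in-set ECDF and the uniform out-of-set ECDF.
Preranked GSEA computes the classic weighted Kolmogorov-Smirnov enrichment
statistic against a gene-permutation null with a normalized enrichment
score (NES). The HOXB13/IL17BR (H/I) log-ratio and Spearman correlation
analyses against covariates (plasma estradiol, stromal TILs) round out the
module. :class:`SignatureScorer` wraps ssGSEA as a scikit-learn
transformer.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .de import NormalizedMatrix, bh_adjust
from .stats import spearman

logger = logging.getLogger(__name__)

__all__ = [
    "ssgsea_score",
    "score_matrix",
    "preranked_gsea",
    "hi_ratio",
    "score_correlation_matrix",
    "covariate_score_correlation",
    "SignatureScorer",
]


def _values(norm) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedMatrix) else norm


def _ranked_order(expr: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Descending expression order (ties broken by gene ID) and average ranks.

    Average ranks are ascending-in-expression, so the top gene carries the
    largest rank value; they feed the ssGSEA weights.
    """
    df = pd.DataFrame({"expr": expr.to_numpy(dtype=float)}, index=expr.index)
    order = np.lexsort((expr.index.to_numpy(), -df["expr"].to_numpy()))
    ranks = sps.rankdata(df["expr"].to_numpy(), method="average")
    return order, ranks


def ssgsea_score(sample_expression: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment score for one gene set.

    Walks the genes in descending expression order accumulating the
    rank-weighted in-set ECDF (weights ``rank**alpha`` normalized over the
    set) minus the uniform out-of-set ECDF; the score is the sum of the
    stepwise differences. Returns NaN with a warning when the set does not
    intersect the expressed genes.
    """
    genes = sample_expression.index
    in_set = np.asarray(genes.isin(set(gene_set)))
    n_in = int(in_set.sum())
    n = len(genes)
    if n_in == 0:
        warnings.warn("gene set has no overlap with the expression profile")
        return float("nan")
    if n_in == n:
        return 0.0
    order, ranks = _ranked_order(sample_expression)
    in_ordered = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(in_ordered, w, 0.0)
    ecdf_in = np.cumsum(w_in) / w_in.sum()
    ecdf_out = np.cumsum(~in_ordered) / (n - n_in)
    return float((ecdf_in - ecdf_out).sum())


def score_matrix(
    norm,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    min_size: int = 5,
    max_size: int = 2000,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA scores for every set (rows) and sample (columns).

    Sets are filtered to those whose overlap with the expressed genes lies
    within ``[min_size, max_size]`` (dropped sets are logged). With
    ``normalize=True`` all scores are divided by the overall score range
    across the matrix.
    """
    values = _values(norm)
    genes = values.index
    rows = {}
    for name, members in sets.items():
        overlap = int(genes.isin(set(members)).sum())
        if not min_size <= overlap <= max_size:
            logger.info("set %s dropped (overlap %d outside [%d, %d])", name, overlap, min_size, max_size)
            continue
        rows[name] = [
            ssgsea_score(values[c], members, alpha=alpha) for c in values.columns
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=values.columns)
    if normalize and out.size and np.isfinite(out.to_numpy()).any():
        rng_ = np.nanmax(out.to_numpy()) - np.nanmin(out.to_numpy())
        if rng_ > 0:
            out = out / rng_
    out.index.name = "set"
    return out


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclasses.dataclass
class GseaResult:
    """Per-set enrichment results from preranked GSEA."""

    table: pd.DataFrame  # columns: es, nes, p_value, fdr, size
    leading_edge: dict[str, list[str]]


def _es_and_leading(stat_sorted: np.ndarray, in_set: np.ndarray) -> tuple[float, int]:
    """Weighted KS enrichment score and the index of the extreme deviation."""
    w = np.abs(stat_sorted) * in_set
    total_in = w.sum()
    n_out = (~in_set.astype(bool)).sum()
    if total_in == 0 or n_out == 0:
        return 0.0, 0
    hits = np.cumsum(w) / total_in
    misses = np.cumsum(~in_set.astype(bool)) / n_out
    dev = hits - misses
    i = int(np.argmax(np.abs(dev)))
    return float(np.clip(dev[i], -1.0, 1.0)), i


def preranked_gsea(
    ranked_stats: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 2000,
) -> GseaResult:
    """Preranked GSEA with a gene-permutation null.

    Genes are ordered by the supplied statistic (descending); the
    enrichment score is the extreme deviation of the weighted KS running
    sum (weight = |stat|). The null redraws random sets of the same size;
    NES is ES divided by the mean |null ES| of the same sign, and the
    permutation p-value is one-sided within the same sign with a +1
    continuity term. BH adjustment is applied across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if ranked_stats.index.has_duplicates:
        raise ValueError("duplicate gene IDs in the ranking")
    order = np.lexsort((ranked_stats.index.to_numpy(), -ranked_stats.to_numpy(dtype=float)))
    genes_sorted = ranked_stats.index.to_numpy()[order]
    stat_sorted = ranked_stats.to_numpy(dtype=float)[order]
    n = len(genes_sorted)
    pos = {g: i for i, g in enumerate(genes_sorted)}

    rng = np.random.default_rng(seed)
    rows = []
    leading: dict[str, list[str]] = {}
    for name, members in sets.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        size = idx.size
        if not min_size <= size <= max_size:
            logger.info("set %s dropped (size %d)", name, size)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[idx] = True
        es, i_ext = _es_and_leading(stat_sorted, in_set)
        null = np.empty(n_perm)
        for b in range(n_perm):
            ridx = rng.choice(n, size=size, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[ridx] = True
            null[b], _ = _es_and_leading(stat_sorted, mask)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            p = 1.0 / (n_perm + 1.0)
            nes = 0.0
        else:
            frac = (np.abs(same) >= abs(es)).sum() / same.size
            p = max(frac, 1.0 / (n_perm + 1.0))
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else 0.0
        if es >= 0:
            le = [g for g in genes_sorted[: i_ext + 1] if g in set(members)]
        else:
            le = [g for g in genes_sorted[i_ext:] if g in set(members)]
        leading[name] = le
        rows.append({"set": name, "es": es, "nes": nes, "p_value": p, "size": size})
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["es", "nes", "p_value", "size"]
    )
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["fdr"] = []
    return GseaResult(table=table, leading_edge=leading)


# ---------------------------------------------------------------------------
# simple signatures and correlations


def hi_ratio(norm, hoxb13: str = "HOXB13", il17br: str = "IL17BR") -> pd.Series:
    """HOXB13/IL17BR log-ratio per sample from log2-normalized expression."""
    values = _values(norm)
    for gene in (hoxb13, il17br):
        if gene not in values.index:
            raise KeyError(f"{gene} absent from the expression matrix")
    out = values.loc[hoxb13] - values.loc[il17br]
    out.name = "hi_ratio"
    return out


def score_correlation_matrix(
    scores: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise set-score correlations with BH FDR over the upper triangle.

    Returns (rho matrix, fdr matrix); both are symmetric, rho has unit
    diagonal and the fdr diagonal is NaN.
    """
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    names = scores.index
    x = scores.to_numpy(dtype=float)
    k = len(names)
    rho = np.eye(k)
    pmat = np.full((k, k), np.nan)
    iu = np.triu_indices(k, 1)
    pvals = []
    for i, j in zip(*iu):
        if method == "spearman":
            r, p = spearman(x[i], x[j])
        else:
            r, p = sps.pearsonr(x[i], x[j])
        rho[i, j] = rho[j, i] = r
        pvals.append(p)
    if pvals:
        fdr = bh_adjust(np.array(pvals))
        for (i, j), q in zip(zip(*iu), fdr):
            pmat[i, j] = pmat[j, i] = q
    return (
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(pmat, index=names, columns=names),
    )


def covariate_score_correlation(
    covariate: pd.Series,
    scores: pd.DataFrame,
    exclusion_threshold: float | None = None,
) -> pd.DataFrame:
    """Spearman correlation of a per-sample covariate with every set score.

    Samples with a null covariate — or one strictly above the exclusion
    threshold (e.g. plasma estradiol above 130 pmol/L, not plausibly
    postmenopausal) — are dropped; BH adjustment is applied across sets.
    """
    cov = covariate.reindex(scores.columns)
    usable = cov.notna()
    if exclusion_threshold is not None:
        usable &= ~(cov > exclusion_threshold)
    if usable.sum() < 3:
        raise ValueError(f"only {int(usable.sum())} usable covariate values")
    cov = cov[usable]
    rows = []
    for name in scores.index:
        r, p = spearman(cov.to_numpy(), scores.loc[name, usable.index[usable]].to_numpy())
        rows.append({"set": name, "rho": r, "p_value": p, "n": int(usable.sum())})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


class SignatureScorer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer computing ssGSEA scores per sample.

    ``transform(X)`` takes samples-by-genes expression and returns a
    samples-by-sets score DataFrame. ``fit`` records which sets pass the
    size filters against the training gene universe.
    """

    def __init__(
        self,
        gene_sets: dict[str, list[str]] = None,
        alpha: float = 0.25,
        min_size: int = 5,
        max_size: int = 2000,
        normalize: bool = False,
    ):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.min_size = min_size
        self.max_size = max_size
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None):
        if self.gene_sets is None:
            raise ValueError("gene_sets is required")
        genes = X.columns
        self.kept_sets_ = {
            name: members
            for name, members in self.gene_sets.items()
            if self.min_size <= int(genes.isin(set(members)).sum()) <= self.max_size
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "kept_sets_"):
            self.fit(X)
        return score_matrix(
            X.T,
            self.kept_sets_,
            alpha=self.alpha,
            min_size=self.min_size,
            max_size=self.max_size,
            normalize=self.normalize,
        ).T
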