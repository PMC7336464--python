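"""Normalization, filtering and clustering of the expression matrices.

The association scan expects, per condition, FPKM-like abundances that
have been (1) quantile-normalized across samples to remove technical
depth differences and (2) inverse-normal transformed per gene so each
etrait is marginally Gaussian.  This module also carries the expression
filter, a differential-expression caller aggregated over accessions, the
k-means profile clustering and a transcriptome PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, wilcoxon
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionSet


@dataclass
class ClusterAssignment:
    labels: pd.Series        # gene_id -> cluster (1-based, canonical order)
    centroids: pd.DataFrame  # cluster x condition


def quantile_normalize(exprset: ExpressionSet) -> ExpressionSet:
    """Force every sample onto the across-sample mean order statistics.

    After the transform, each sample's sorted values equal the row-wise
    mean of the per-sample sorted values; ties within a sample receive
    the mean of the reference values they span.
    """
    x = exprset.values.to_numpy(float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return ExpressionSet(exprset.condition, exprset.values.copy())
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires a complete matrix")
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = np.empty(n_genes)
        col[order[:, j]] = reference
        # tie groups share the mean of the reference values they span
        vals = x[:, j]
        if len(np.unique(vals)) < n_genes:
            df = pd.DataFrame({"v": vals, "r": col})
            col = df.groupby("v")["r"].transform("mean").to_numpy()
        out[:, j] = col
    values = pd.DataFrame(out, index=exprset.values.index, columns=exprset.values.columns)
    return ExpressionSet(exprset.condition, values)


def inverse_normal_transform(exprset: ExpressionSet) -> ExpressionSet:
    """Per-gene rank-based mapping to normal quantiles.

    value_i -> Phi^-1((rank_i - a) / (n + 1 - 2a)) with the qqnorm
    offset convention a = 0.5 for n > 10 and a = 3/8 for n <= 10; ties
    get the average rank; missing values stay missing and are excluded
    from n.  Constant genes map to all zeros (flagged with a warning).
    """
    x = exprset.values.to_numpy(float)
    out = np.full_like(x, np.nan)
    n_constant = 0
    for i in range(x.shape[0]):
        row = x[i]
        obs = ~np.isnan(row)
        n = int(obs.sum())
        if n == 0:
            continue
        vals = row[obs]
        if np.ptp(vals) == 0:
            out[i, obs] = 0.0
            n_constant += 1
            continue
        a = 0.5 if n > 10 else 3.0 / 8.0
        ranks = rankdata(vals, method="average")
        out[i, obs] = norm.ppf((ranks - a) / (n + 1.0 - 2.0 * a))
    if n_constant:
        warnings.warn(f"{n_constant} constant genes mapped to all zeros")
    transformed = pd.DataFrame(out, index=exprset.values.index, columns=exprset.values.columns)
    return ExpressionSet(exprset.condition, exprset.values, transformed=transformed)


def expression_filter(
    exprset: ExpressionSet,
    min_value: float = 0.05,
    min_fraction: float = 0.2,
    strict: bool = True,
) -> list[str]:
    """Genes expressed above ``min_value`` in at least a fraction of samples.

    "Above" is read as strict ``>`` by default (configurable);
    the sample count threshold is ``ceil(min_fraction * n_samples)``,
    so exactly 20% of samples passes the default rule.
    """
    x = exprset.values.to_numpy(float)
    n_needed = ceil(min_fraction * x.shape[1])
    hits = (x > min_value) if strict else (x >= min_value)
    keep = np.nansum(hits, axis=1) >= n_needed
    return [g for g, k in zip(exprset.values.index, keep) if k]


def call_degs(
    sets: dict[str, ExpressionSet],
    lfc_min: float = 1.0,
    min_fraction: float = 0.2,
    fdr: float = 0.05,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Differential-expression calls aggregated over accessions.

    For every condition pair and gene: the fraction of paired accessions
    with |log2 fold change| > ``lfc_min`` (a small ``eps`` guards zero
    abundances), a paired Wilcoxon signed-rank p across accessions, and
    Benjamini-Hochberg adjustment across genes within the pair.  A gene
    is a DEG when, for at least one pair, the changed fraction reaches
    ``min_fraction`` and the adjusted p is below ``fdr``.
    """
    conds = list(sets)
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    rows = []
    for c1, c2 in combinations(conds, 2):
        s1, s2 = sets[c1], sets[c2]
        shared = [s for s in s1.sample_ids if s in set(s2.sample_ids)]
        if len(shared) < 6:
            raise ValueError(f"fewer than 6 paired accessions for {c1} vs {c2}")
        genes = [g for g in s1.genes if g in set(s2.genes)]
        a = s1.values.loc[genes, shared].to_numpy(float)
        b = s2.values.loc[genes, shared].to_numpy(float)
        lfc = np.log2((a + eps) / (b + eps))
        frac = (np.abs(lfc) > lfc_min).mean(axis=1)
        pvals = np.ones(len(genes))
        for i in range(len(genes)):
            d = lfc[i]
            if np.allclose(d, 0.0):
                continue
            pvals[i] = wilcoxon(d, zero_method="wilcox").pvalue
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for i, g in enumerate(genes):
            rows.append(
                {
                    "gene_id": g,
                    "condition_pair": f"{c1}|{c2}",
                    "fraction_changed": frac[i],
                    "fdr": qvals[i],
                    "is_deg": bool(frac[i] >= min_fraction and qvals[i] < fdr),
                }
            )
    out = pd.DataFrame(rows)
    any_deg = out.groupby("gene_id")["is_deg"].transform("max").astype(bool)
    out["is_deg_any_pair"] = any_deg
    return out


def kmeans_profiles(deg_matrix: pd.DataFrame, k: int = 3, seed: int = 0) -> ClusterAssignment:
    """Cluster z-scored condition-mean profiles with canonical labels.

    Labels are re-ordered by descending centroid slope (last minus first
    condition), so cluster 1 is the most induced profile and cluster k
    the most repressed; the ordering makes cluster ids stable across
    runs and seeds.
    """
    if k > len(deg_matrix):
        raise ValueError("k exceeds number of genes")
    X = deg_matrix.to_numpy(float)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(X)
    slopes = km.cluster_centers_[:, -1] - km.cluster_centers_[:, 0]
    order = np.argsort(-slopes, kind="stable")
    relabel = {int(old): i + 1 for i, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(l)] for l in km.labels_], index=deg_matrix.index, name="cluster"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=deg_matrix.columns
    )
    return ClusterAssignment(labels=labels, centroids=centroids)


def pca_transcriptomes(sets: dict[str, ExpressionSet], n_components: int | None = None):
    """PCA of all transcriptomes over genes common to every condition.

    Gene columns are standardized to unit variance before the
    eigendecomposition (constant genes are dropped with a warning);
    signs are fixed by making the largest-magnitude element of each
    loading vector positive.  Returns (scores, explained_fraction,
    loadings); score rows are indexed by (condition, sample).
    """
    conds = list(sets)
    genes = set(sets[conds[0]].genes)
    for c in conds[1:]:
        genes &= set(sets[c].genes)
    genes = sorted(genes)
    blocks, index = [], []
    for c in conds:
        m = sets[c].values.loc[genes]
        blocks.append(m.to_numpy(float).T)
        index += [(c, s) for s in sets[c].sample_ids]
    X = np.vstack(blocks)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene columns")
    X = X[:, keep]
    genes = [g for g, k in zip(genes, keep) if k]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    if n_components is not None:
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    sign = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    sign[sign == 0] = 1.0
    vt = vt * sign[:, None]
    u = u * sign[None, :]
    scores = pd.DataFrame(
        u * s,
        index=pd.MultiIndex.from_tuples(index, names=["condition", "sample"]),
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    explained = s**2 / (s**2).sum()
    loadings = pd.DataFrame(vt.T, index=genes, columns=scores.columns)
    return scores, explained, loadings


def fpkm(counts: pd.DataFrame, gene_length_bp: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments from raw counts."""
    total = counts.sum(axis=0)
    return counts.mul(1e9).div(gene_length_bp, axis=0).div(total, axis=1)
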