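"""Developmental differential expression (devDEGs), trend fitting and
clustering, sharing classes, refinement scores and eigentrends.

Per cell type, raw counts are pseudobulked by sample and each gene is
tested for an age effect with a moderated F-test on log2-CPM (residual
variances squeezed toward a lowess mean–variance trend); genes at
BH FDR < 0.05 are devDEGs. Their per-age pseudobulk means are fitted with
a penalized cubic spline on the age-rank axis, min–max normalized and
hierarchically clustered (Ward / Euclidean). Across cell types a gene is
"shared" if detected in more than 70% of cell types, "cell-type-specific"
below 20%, and "intermediate" in between. A gene set's refinement score is
the fraction of its expressed gene x cell-type combinations that change
significantly between two refinement stages (default P10 vs P65); its
eigentrend is the first principal component of the centred member trends.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
import statsmodels.api as sm
from anndata import AnnData
from dataclasses import dataclass
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import make_smoothing_spline

from .contrast import adjust_bh

__all__ = [
    "pseudobulk_by_sample",
    "devdeg_test",
    "fit_trend",
    "TrendClusterResult",
    "cluster_trends",
    "classify_sharing",
    "two_age_contrast",
    "refinement_score",
    "eigentrend",
    "filter_gene_sets",
]


def pseudobulk_by_sample(adata: AnnData) -> pd.DataFrame:
    """Sum raw counts per sample (rows) over genes (columns).

    Samples present in the metadata vocabulary but with no cells yield a
    row of zeros with a warning.
    """
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    samp = adata.obs["sample_id"]
    ids = list(samp.cat.categories) if isinstance(samp.dtype, pd.CategoricalDtype) \
        else list(pd.unique(samp))
    vals = samp.astype(str).to_numpy()
    rows = []
    for s in ids:
        mask = vals == s
        if not mask.any():
            warnings.warn(f"sample {s!r} has no cells; emitting a zero row")
            rows.append(np.zeros(adata.n_vars, dtype=np.int64))
        else:
            rows.append(np.asarray(X[mask].sum(axis=0), dtype=np.int64).ravel())
    return pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="sample_id"),
                        columns=adata.var_names)


def devdeg_test(pseudobulk: pd.DataFrame, ages: pd.Series,
                prior_df: float = 4.0) -> pd.DataFrame:
    """Per-gene age-effect test on sample-pseudobulk counts.

    ``ages`` maps sample id -> age stage. Ages with a single sample are
    excluded with a warning. The test is a one-way F-test of the age factor
    on log2-CPM with the residual variance squeezed toward a lowess
    mean-variance trend; returns a frame with p_value and fdr per gene.
    """
    ages = pd.Series(ages).astype(str)
    ages = ages.loc[pseudobulk.index]
    counts = ages.value_counts()
    singles = counts[counts < 2].index.tolist()
    if singles:
        warnings.warn(f"ages with a single sample excluded: {sorted(singles)}")
        keep = ~ages.isin(singles)
        pseudobulk, ages = pseudobulk[keep.to_numpy()], ages[keep]
    levels = sorted(ages.unique())
    if len(levels) < 2:
        raise ValueError("devDEG testing requires at least 2 ages with >= 2 samples")

    lib = pseudobulk.sum(axis=1).to_numpy()
    if (lib == 0).any():
        raise ValueError("pseudobulk samples with zero totals cannot be tested")
    logcpm = np.log2(pseudobulk.to_numpy() / lib[:, None] * 1e6 + 0.5)
    n, G = logcpm.shape
    groups = [np.flatnonzero((ages == a).to_numpy()) for a in levels]
    grand = logcpm.mean(axis=0)
    ss_between = np.zeros(G)
    ss_within = np.zeros(G)
    for idx in groups:
        gm = logcpm[idx].mean(axis=0)
        ss_between += len(idx) * (gm - grand) ** 2
        ss_within += ((logcpm[idx] - gm) ** 2).sum(axis=0)
    df_between = len(levels) - 1
    df_within = n - len(levels)
    s2 = ss_within / df_within
    trend = sm.nonparametric.lowess(s2, logcpm.mean(axis=0), frac=0.5,
                                    return_sorted=False)
    trend = np.maximum(trend, 1e-12)
    s2_mod = np.maximum((prior_df * trend + df_within * s2) / (prior_df + df_within),
                        1e-12)
    F = (ss_between / df_between) / s2_mod
    p = st.f.sf(F, df_between, df_within + prior_df)
    out = pd.DataFrame({"gene": pseudobulk.columns, "F": F, "p_value": p})
    out["fdr"] = adjust_bh(out["p_value"].to_numpy())
    return out


def fit_trend(age_means: np.ndarray | pd.Series, lam: float | None = None
              ) -> np.ndarray:
    """Smooth a gene's per-age means on the age-rank axis.

    Five or more ages: penalized cubic smoothing spline with the penalty
    chosen by generalized cross-validation. Exactly four: cubic least
    squares. Fewer: linear fit, with a warning. Returns fitted values at
    the observed ranks.
    """
    y = np.asarray(age_means, dtype=float)
    x = np.arange(len(y), dtype=float)
    if len(y) >= 5:
        return np.asarray(make_smoothing_spline(x, y, lam=lam)(x))
    if len(y) == 4:
        return np.polyval(np.polyfit(x, y, 3), x)
    warnings.warn(f"only {len(y)} ages; falling back to a linear fit")
    if len(y) < 2:
        return y.copy()
    return np.polyval(np.polyfit(x, y, 1), x)


@dataclass
class TrendClusterResult:
    normalized: pd.DataFrame      # instances x age grid, min-max per row
    linkage: np.ndarray
    labels: pd.Series             # cluster id per instance
    cluster_means: pd.DataFrame   # cluster x age grid


def cluster_trends(trends: pd.DataFrame, n_clusters: int) -> TrendClusterResult:
    """Min–max normalize each trend to [0, 1] (constant trends map to 0.5)
    and cut a Ward/Euclidean hierarchical tree into ``n_clusters``."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if len(trends) < n_clusters:
        raise ValueError(f"{len(trends)} trends cannot form {n_clusters} clusters")
    vals = trends.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    span = vals.max(axis=1, keepdims=True) - lo
    normed = np.where(span > 0, (vals - lo) / np.where(span == 0, 1, span), 0.5)
    Z = linkage(normed, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    normed_df = pd.DataFrame(normed, index=trends.index, columns=trends.columns)
    means = normed_df.groupby(pd.Series(labels, index=trends.index)).mean()
    return TrendClusterResult(
        normalized=normed_df, linkage=Z,
        labels=pd.Series(labels, index=trends.index, name="cluster"),
        cluster_means=means,
    )


def classify_sharing(detection: pd.DataFrame, shared_above: float = 0.7,
                     specific_below: float = 0.2) -> pd.Series:
    """Classify genes by the fraction of cell types in which they are
    devDEGs: shared (> 70%), cell-type-specific (< 20%) or intermediate.
    ``detection`` is a boolean gene x cell-type frame."""
    frac = detection.astype(bool).mean(axis=1)
    out = pd.Series("intermediate", index=detection.index, name="sharing")
    out[frac > shared_above] = "shared"
    out[frac < specific_below] = "cell-type-specific"
    return out


def two_age_contrast(adata: AnnData, age_a: str, age_b: str,
                     prior_df: float = 4.0) -> pd.DataFrame:
    """Dedicated two-age pseudobulk contrast (used for refinement scoring):
    devDEG test restricted to ``age_a`` vs ``age_b``, plus an ``expressed``
    flag (nonzero pseudobulk at one of the two ages or any other age)."""
    pb = pseudobulk_by_sample(adata)
    sample_age = (adata.obs[["sample_id", "age"]].drop_duplicates()
                  .set_index("sample_id")["age"].astype(str))
    expressed = pb.sum(axis=0) > 0
    keep = sample_age[sample_age.isin([age_a, age_b])].index
    res = devdeg_test(pb.loc[keep], sample_age.loc[keep], prior_df=prior_df)
    res = res.set_index("gene")
    res["expressed"] = expressed
    return res


def refinement_score(gene_set: list[str],
                     contrasts: dict[str, pd.DataFrame],
                     alpha: float = 0.05) -> float:
    """Fraction of expressed gene x cell-type combinations in ``gene_set``
    with a significant change between the refinement stages.

    ``contrasts`` maps cell type -> frame indexed by gene with ``fdr`` and
    ``expressed`` columns (see :func:`two_age_contrast`).
    """
    n_sig = 0
    n_expressed = 0
    for res in contrasts.values():
        hits = res.loc[res.index.intersection(gene_set)]
        expr = hits["expressed"].astype(bool)
        n_expressed += int(expr.sum())
        n_sig += int(((hits["fdr"] < alpha) & expr).sum())
    if n_expressed == 0:
        raise ValueError("no expressed gene x cell-type combinations in the set")
    return n_sig / n_expressed


def eigentrend(trends: pd.DataFrame) -> np.ndarray:
    """First principal component (over ages) of the gene-centred trend
    matrix, sign-oriented to correlate positively with the mean trend.

    With a single member, that trend (centred) is returned with a warning.
    """
    vals = trends.to_numpy(dtype=float)
    vals = vals - vals.mean(axis=1, keepdims=True)
    if len(vals) < 2:
        warnings.warn("eigentrend of fewer than 2 members is the trend itself")
        return vals.ravel()
    _, s, vt = np.linalg.svd(vals, full_matrices=False)
    component = vt[0] * s[0] / np.sqrt(len(vals))
    mean_trend = vals.mean(axis=0)
    if np.dot(component, mean_trend) < 0:
        component = -component
    return component


def filter_gene_sets(gene_sets: dict[str, list[str]],
                     detection: pd.DataFrame,
                     min_median_overlap: int = 40) -> dict[str, list[str]]:
    """Keep gene sets whose median devDEG overlap across cell types is at
    least ``min_median_overlap`` (inclusion rule for eigentrend summaries).
    ``detection`` is the boolean gene x cell-type devDEG frame."""
    kept = {}
    for name, genes in gene_sets.items():
        members = detection.index.intersection(genes)
        overlap = detection.loc[members].sum(axis=0)
        if len(overlap) and float(np.median(overlap)) >= min_median_overlap:
            kept[name] = list(genes)
    return kept
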