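"""Group separation statistics: inter/intra centroid distances and
pseudobulk two-group differential expression.

For one cell type, samples from two groups (sexes or genotypes) are placed
in a joint reduced expression space; each sample's centroid is computed and
all pairwise Manhattan distances are split into inter-group and intra-group
sets. The effect size is mean(inter) / mean(intra) — how separated the
groups are relative to within-group variability — with a two-sided t-test
of the two distance sets. Distance pairs are treated as independent
observations, as is conventional for this statistic; calibration is
verified empirically rather than assumed.

Pseudobulk DE sums raw counts per sample (after removing mitochondrial,
ribosomal, Y-chromosome and X-inactivation genes, which would otherwise
dominate any sex contrast) and applies a moderated t-test on log-CPM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
import statsmodels.api as sm
from anndata import AnnData

from .maturation import DistanceTrajectory, reduced_embedding
from .qc import ConfigurationError

__all__ = [
    "GroupContrast",
    "DEResult",
    "group_distance_contrast",
    "contrast_table",
    "adjust_bh",
    "sex_distance_difference",
    "pseudobulk_de",
]

DEFAULT_DE_EXCLUDE = ("mito", "ribo", "chrY", "xinact")


@dataclass
class GroupContrast:
    cell_type: str
    group_sizes: dict[str, int]           # samples per group
    inter_distances: np.ndarray
    intra_distances: np.ndarray
    effect_size: float                    # mean(inter) / mean(intra)
    p_value: float
    n_pcs: int


@dataclass
class DEResult:
    table: pd.DataFrame                   # gene, log2_fc, p, adjusted_p
    excluded_genes: list[str]
    design: pd.DataFrame                  # sample x condition


def group_distance_contrast(adata: AnnData, group_col: str = "sex",
                            min_cells: int = 10, n_hvgs: int = 2000,
                            n_pcs: int = 100, seed: int = 0) -> GroupContrast:
    """Inter- vs intra-group sample-centroid distance statistic for one
    cell type. ``adata`` holds raw counts; ``obs[group_col]`` gives the
    group of each cell and ``obs['sample_id']`` its sample."""
    sample_group = (adata.obs[[group_col, "sample_id"]]
                    .drop_duplicates().set_index("sample_id")[group_col])
    groups = sample_group.astype(str)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, found {labels}")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(
                f"group {g!r} has a single sample; intra-group distances undefined")
    counts = adata.obs["sample_id"].value_counts()
    small = counts[counts < min_cells].index.tolist()
    if small:
        warnings.warn(f"samples with fewer than {min_cells} cells: {small}")

    emb, m = reduced_embedding(adata, n_hvgs=n_hvgs, n_pcs=n_pcs, seed=seed)
    sample_vals = adata.obs["sample_id"].to_numpy()
    cents = {s: emb[sample_vals == s].mean(axis=0) for s in groups.index
             if (sample_vals == s).any()}
    inter, intra = [], []
    for s1, s2 in combinations(cents, 2):
        d = float(np.abs(cents[s1] - cents[s2]).sum())
        (intra if groups[s1] == groups[s2] else inter).append(d)
    inter, intra = np.array(inter), np.array(intra)
    effect = float(inter.mean() / intra.mean())
    p = float(st.ttest_ind(inter, intra, equal_var=False).pvalue)
    ct = str(adata.obs["cell_type"].iloc[0]) if "cell_type" in adata.obs else ""
    return GroupContrast(
        cell_type=ct,
        group_sizes={g: int((groups == g).sum()) for g in labels},
        inter_distances=inter, intra_distances=intra,
        effect_size=effect, p_value=p, n_pcs=m,
    )


def contrast_table(contrasts: list[GroupContrast]) -> pd.DataFrame:
    """Summarise contrasts across cell types, with BH-adjusted p-values."""
    df = pd.DataFrame({
        "cell_type": [c.cell_type for c in contrasts],
        "effect_size": [c.effect_size for c in contrasts],
        "p_value": [c.p_value for c in contrasts],
        "n_samples": [sum(c.group_sizes.values()) for c in contrasts],
    })
    df["adjusted_p"] = adjust_bh(df["p_value"].to_numpy())
    return df


def adjust_bh(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (cumulative-minimum
    enforced, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def sex_distance_difference(male: dict[str, DistanceTrajectory],
                            female: dict[str, DistanceTrajectory]) -> pd.DataFrame:
    """Per-age (female - male) maturation-distance differences across cell
    types, with a paired two-sided t-test per age.

    Trajectories are computed per sex on sex-split data; cell types missing
    either sex are skipped. Positive differences mean females are farther
    from the adult state (less mature) at that age.
    """
    shared = sorted(set(male) & set(female))
    skipped = sorted(set(male) ^ set(female))
    if skipped:
        warnings.warn(f"cell types missing one sex skipped: {skipped}")
    if len(shared) < 2:
        raise ValueError("need at least 2 cell types present in both sexes")
    rows = []
    ages = [a for a in male[shared[0]].ages]
    for age in ages:
        diffs, m_vals, f_vals = [], [], []
        for ct in shared:
            tm, tf = male[ct], female[ct]
            if age in tm.ages and age in tf.ages:
                dm = tm.mono_distance[tm.ages.index(age)]
                df_ = tf.mono_distance[tf.ages.index(age)]
                m_vals.append(dm)
                f_vals.append(df_)
                diffs.append(df_ - dm)
        if len(diffs) < 2:
            continue
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(st.ttest_rel(f_vals, m_vals).pvalue)
        rows.append({"age": age, "mean_difference": float(np.mean(diffs)),
                     "p_value": p, "n_cell_types": len(diffs)})
    return pd.DataFrame(rows)


def pseudobulk_de(adata: AnnData, condition_col: str = "sex",
                  exclude_categories: tuple[str, ...] = DEFAULT_DE_EXCLUDE,
                  alpha: float = 0.05, prior_df: float = 4.0) -> DEResult:
    """Two-group pseudobulk differential expression for one cell type.

    Raw counts are summed per sample, converted to log2-CPM, and tested
    per gene with a Welch t-test whose residual variance is squeezed toward
    a lowess mean–variance trend (``prior_df`` pseudo-observations).
    Genes flagged in ``exclude_categories`` are removed before testing.
    """
    missing = [c for c in exclude_categories if c not in adata.var.columns]
    if missing:
        raise ConfigurationError(f"exclusion categories not flagged in var: {missing}")
    drop = adata.var[list(exclude_categories)].any(axis=1) if exclude_categories \
        else pd.Series(False, index=adata.var_names)
    excluded = adata.var_names[drop].tolist()
    sub = adata[:, ~drop.to_numpy()]

    sample_cond = (adata.obs[[condition_col, "sample_id"]]
                   .drop_duplicates().set_index("sample_id")[condition_col].astype(str))
    labels = sorted(sample_cond.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 conditions, found {labels}")
    for g in labels:
        if (sample_cond == g).sum() < 2:
            raise ValueError(f"condition {g!r} has fewer than 2 samples")

    pb = _pseudobulk(sub)
    logcpm = np.log2(pb.div(pb.sum(axis=1), axis=0) * 1e6 + 0.5)
    g1 = logcpm.loc[sample_cond[sample_cond == labels[0]].index]
    g2 = logcpm.loc[sample_cond[sample_cond == labels[1]].index]
    stats = _moderated_welch(g1.to_numpy(), g2.to_numpy(), prior_df=prior_df)
    table = pd.DataFrame({
        "gene": logcpm.columns,
        "log2_fc": stats["delta"],
        "p_value": stats["p"],
    })
    table["adjusted_p"] = adjust_bh(table["p_value"].to_numpy())
    table["significant"] = table["adjusted_p"] < alpha
    design = pd.DataFrame({"condition": sample_cond})
    return DEResult(table=table, excluded_genes=excluded, design=design)


def _pseudobulk(adata: AnnData) -> pd.DataFrame:
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    samples = pd.Series(adata.obs["sample_id"].astype(str).to_numpy())
    ids = samples.unique()
    rows = [np.asarray(X[(samples == s).to_numpy()].sum(axis=0)).ravel() for s in ids]
    return pd.DataFrame(np.vstack(rows), index=ids, columns=adata.var_names)


def _moderated_welch(a: np.ndarray, b: np.ndarray, prior_df: float = 4.0) -> dict:
    """Welch t-statistics with gene variances squeezed toward a lowess
    trend of pooled variance on mean log-expression (limma-style)."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    df_res = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_res
    mean_expr = np.concatenate([a, b]).mean(axis=0)
    trend = sm.nonparametric.lowess(pooled, mean_expr, frac=0.5,
                                    return_sorted=False)
    trend = np.maximum(trend, 1e-12)
    shrunk = (prior_df * trend + df_res * pooled) / (prior_df + df_res)
    shrunk = np.maximum(shrunk, 1e-12)
    delta = m2 - m1
    se = np.sqrt(shrunk * (1 / n1 + 1 / n2))
    t = delta / se
    df_t = df_res + prior_df
    p = 2 * st.t.sf(np.abs(t), df_t)
    return {"delta": delta, "t": t, "p": p}
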