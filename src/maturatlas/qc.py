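"""Quality control, normalization, PCA and module scores.

This module is the shared substrate of every downstream analysis stage:
cell-level QC filters (library size, gene detection, single-gene
dominance, and category fractions such as mitochondrial or immediate-early
genes), library-size log-normalization, binned-dispersion highly variable
gene selection, PCA with the explained-variance component rule, gene-set
module scores against expression-matched control genes, per-age z-scoring,
and cell-type correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA

__all__ = [
    "QCThresholds",
    "ConfigurationError",
    "apply_qc_filters",
    "log_normalize",
    "select_hvgs",
    "PCASpace",
    "run_pca",
    "pc_count_for_variance",
    "module_score",
    "zscore_across_age",
    "celltype_correlation_matrix",
]

QC_CATEGORIES = ("mito", "ribo", "ieg", "apoptotic", "rbc")


class ConfigurationError(ValueError):
    """Required configuration (e.g. gene category flags) is missing."""


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds. A cell is kept only if every rule holds."""

    min_umis: int = 400
    max_umis: int = 100_000
    min_genes: int = 250
    max_top_gene_fraction: float = 0.20
    max_mito_fraction: float = 0.10
    max_ribo_fraction: float = 0.10
    max_ieg_fraction: float = 0.01
    max_apoptotic_fraction: float = 0.01
    max_rbc_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_umis >= self.max_umis:
            raise ValueError("min_umis must be < max_umis")
        for f in fields(self):
            if f.name.startswith("max_") and f.name.endswith("fraction"):
                v = getattr(self, f.name)
                if not 0 < v <= 1:
                    raise ValueError(f"{f.name} must be in (0, 1], got {v!r}")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def apply_qc_filters(adata: AnnData, th: QCThresholds = QCThresholds()
                     ) -> tuple[AnnData, pd.DataFrame]:
    """Filter cells by ``th``; return the retained subset and a per-cell
    report with each metric, the pass flag and the first failing rule."""
    missing = [c for c in QC_CATEGORIES if c not in adata.var.columns]
    if missing:
        raise ConfigurationError(
            f"gene category flags missing from var: {missing}")

    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    top = X.max(axis=1).toarray().ravel() if X.nnz else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        top_frac = np.where(total > 0, top / np.maximum(total, 1), 0.0)
        cat_frac = {}
        for cat in QC_CATEGORIES:
            mask = adata.var[cat].to_numpy()
            cat_sum = np.asarray(X[:, mask].sum(axis=1)).ravel() if mask.any() \
                else np.zeros(X.shape[0])
            cat_frac[cat] = np.where(total > 0, cat_sum / np.maximum(total, 1), 0.0)

    rules = [
        ("min_umis", total >= th.min_umis),
        ("max_umis", total <= th.max_umis),
        ("min_genes", n_genes >= th.min_genes),
        ("max_top_gene_fraction", top_frac <= th.max_top_gene_fraction),
        ("max_mito_fraction", cat_frac["mito"] <= th.max_mito_fraction),
        ("max_ribo_fraction", cat_frac["ribo"] <= th.max_ribo_fraction),
        ("max_ieg_fraction", cat_frac["ieg"] <= th.max_ieg_fraction),
        ("max_apoptotic_fraction", cat_frac["apoptotic"] <= th.max_apoptotic_fraction),
        ("max_rbc_fraction", cat_frac["rbc"] <= th.max_rbc_fraction),
    ]
    keep = np.ones(adata.n_obs, bool)
    first_fail = np.full(adata.n_obs, "", object)
    for name, ok in rules:
        first_fail[~ok & (first_fail == "")] = name
        keep &= ok

    report = pd.DataFrame({
        "total_umis": total,
        "n_genes": n_genes,
        "top_gene_fraction": top_frac,
        **{f"{c}_fraction": cat_frac[c] for c in QC_CATEGORIES},
        "passed": keep,
        "first_failing_rule": first_fail,
    }, index=adata.obs_names)
    return adata[keep].copy(), report


def log_normalize(adata: AnnData, scale_factor: float = 10_000.0) -> AnnData:
    """ln(1 + count / cell_total * scale_factor), keeping raw counts in
    ``layers['counts']``. Errors on any zero-total cell."""
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(total == 0)
    if len(zero):
        names = list(adata.obs_names[zero[:5]])
        raise ValueError(f"cells with zero total counts cannot be normalized: {names}")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    norm = X.astype(np.float64).multiply((scale_factor / total)[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.X = norm
    out.uns["scale_factor"] = float(scale_factor)
    return out


def select_hvgs(norm: AnnData, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Rank genes by dispersion standardized within expression-mean bins.

    Operates on log-normalized values; dispersion = variance / mean. Genes
    with zero mean (never detected) are excluded. Ties break by gene id, so
    the ranking is deterministic for a fixed input.
    """
    X = norm.X
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        X = np.asarray(X)
        mean = X.mean(axis=0)
        sq = (X ** 2).mean(axis=0)
    var = np.maximum(sq - mean ** 2, 0.0)
    expressed = mean > 0
    n_expr = int(expressed.sum())
    if n_expr < n:
        warnings.warn(f"only {n_expr} expressed genes available; returning all")
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(expressed, var / np.maximum(mean, 1e-300), -np.inf)

    df = pd.DataFrame({"gene": norm.var_names, "mean": mean, "disp": disp})
    df = df[expressed.astype(bool)].copy()
    # standardizing dispersion needs a handful of genes per bin
    n_bins_eff = max(1, min(n_bins, len(df) // 10, len(df)))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), n_bins_eff, labels=False)
    z = np.zeros(len(df))
    for _, idx in df.groupby("bin").groups.items():
        d = df.loc[idx, "disp"]
        sd = d.std(ddof=0)
        z[df.index.get_indexer(idx)] = 0.0 if sd == 0 else (d - d.mean()) / sd
    df["z"] = z
    df = df.sort_values(["z", "gene"], ascending=[False, True])
    return df["gene"].head(n).tolist()


@dataclass
class PCASpace:
    """A fitted PCA embedding over a gene subset (centred, unit-scaled)."""

    genes: list[str]
    loadings: np.ndarray          # genes x K
    scores: np.ndarray            # cells x K
    variance_fraction: np.ndarray
    center: np.ndarray
    scale: np.ndarray

    def transform(self, norm: AnnData) -> np.ndarray:
        """Project (log-normalized) cells into this space, using the genes
        shared with the fitted gene set (missing genes contribute 0)."""
        shared = [g for g in self.genes if g in norm.var_names]
        if not shared:
            raise ValueError("no genes shared with the fitted PCA space")
        pos = [self.genes.index(g) for g in shared]
        X = _dense(norm[:, shared].X)
        Z = (X - self.center[pos]) / self.scale[pos]
        return Z @ self.loadings[pos, :]


def run_pca(norm: AnnData, genes: list[str] | None = None, n_components: int = 100,
            seed: int = 0) -> PCASpace:
    """PCA of centred, unit-variance-scaled log-normalized expression over
    ``genes`` (default: all). Randomized solver, seeded, hence deterministic."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    genes = list(norm.var_names) if genes is None else list(genes)
    X = _dense(norm[:, genes].X).astype(np.float64)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    k = min(n_components, Z.shape[0] - 1 if Z.shape[0] > 1 else 1, Z.shape[1])
    solver = "randomized" if 0 < k < min(Z.shape) // 2 and min(Z.shape) > 200 else "full"
    pca = PCA(n_components=k, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(Z)
    return PCASpace(
        genes=genes,
        loadings=pca.components_.T,
        scores=scores,
        variance_fraction=pca.explained_variance_ratio_,
        center=center,
        scale=scale,
    )


def pc_count_for_variance(space: PCASpace, target: float = 0.20, cap: int = 100) -> int:
    """Smallest number of leading components whose cumulative variance
    fraction reaches ``target``; capped at ``cap`` (or the number of
    available components, whichever is smaller)."""
    if not 0 < target < 1:
        raise ValueError(f"target must be in (0, 1), got {target!r}")
    cum = np.cumsum(space.variance_fraction[:cap])
    hit = np.flatnonzero(cum >= target)
    if len(hit):
        return int(hit[0]) + 1
    return int(min(cap, len(space.variance_fraction)))


def module_score(norm: AnnData, gene_set: list[str], n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Per-cell gene-set score: mean expression of the set minus mean
    expression of expression-matched control genes.

    All genes are placed into ``n_bins`` equal-frequency bins of mean
    expression; for each set gene, ``n_ctrl`` control genes are drawn
    (seeded) from its bin, and the pooled unique controls form the
    reference. Deterministic given ``seed``.
    """
    present = [g for g in gene_set if g in norm.var_names]
    if not present:
        missing = [g for g in gene_set if g not in norm.var_names]
        raise ValueError(f"no gene of the set is present in the matrix; missing: "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    X = norm.X
    mean = (np.asarray(X.mean(axis=0)).ravel() if sp.issparse(X)
            else np.asarray(X).mean(axis=0))
    mean = pd.Series(mean, index=norm.var_names)
    # never-expressed genes carry no information: excluding them keeps the
    # score invariant to padding the matrix with silent genes
    expressed = mean[mean > 0]
    order = expressed.rank(method="first")
    n_bins_eff = min(n_bins, len(expressed))
    bins = pd.qcut(order, n_bins_eff, labels=False)

    rng = np.random.default_rng(seed)
    ctrl: set[str] = set()
    for g in present:
        g_bin = bins[g] if g in bins.index else 0
        pool = bins.index[bins == g_bin]
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False))
    ctrl -= set(present)
    if not ctrl:
        raise ValueError("control pool is empty; increase n_ctrl or n_bins")

    def _mean_over(genes):
        sub = norm[:, list(genes)].X
        return (np.asarray(sub.mean(axis=1)).ravel() if sp.issparse(sub)
                else np.asarray(sub).mean(axis=1))

    score = _mean_over(present) - _mean_over(sorted(ctrl))
    return pd.Series(score, index=norm.obs_names, name="module_score")


def zscore_across_age(scores: pd.Series, ages: pd.Series) -> pd.Series:
    """Average ``scores`` within each age, then z-score the age means
    (population SD). Constant means return all zeros."""
    ages = pd.Series(ages)
    groups = scores.groupby(ages.values, observed=True).mean()
    if isinstance(ages.dtype, pd.CategoricalDtype):
        order = [a for a in ages.cat.categories if a in groups.index]
        groups = groups.loc[order]
    if len(groups) < 2:
        raise ValueError("z-scoring across age requires at least 2 ages with cells")
    sd = groups.std(ddof=0)
    if sd == 0:
        return pd.Series(0.0, index=groups.index, name="z")
    return ((groups - groups.mean()) / sd).rename("z")


def celltype_correlation_matrix(norm: AnnData, labels: pd.Series | None = None
                                ) -> pd.DataFrame:
    """Pearson correlation between per-cell-type mean *scaled* profiles.

    Genes are z-scored across cells before averaging within cell types.
    Cell types with fewer than 2 cells are excluded with a warning.
    """
    labels = norm.obs["cell_type"] if labels is None else pd.Series(labels, index=norm.obs_names)
    counts = labels.value_counts()
    keep_types = counts[counts >= 2].index
    dropped = counts[counts < 2].index.tolist()
    if dropped:
        warnings.warn(f"cell types with < 2 cells excluded: {dropped}")
    if len(keep_types) < 2:
        raise ValueError("need at least 2 cell types with >= 2 cells")
    X = _dense(norm.X).astype(np.float64)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    profiles = np.vstack([
        Z[(labels == ct).to_numpy()].mean(axis=0) for ct in keep_types
    ])
    corr = np.corrcoef(profiles)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(keep_types), columns=list(keep_types))
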