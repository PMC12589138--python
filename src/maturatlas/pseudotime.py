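"""Maturation pseudotime: principal-curve fitting, projection of held-out
cells, developmental-delay testing and the core maturation gene set.

For one cell type, control cells spanning all ages are embedded in a fixed
reduced space (log-normalization, 2,000 highly variable genes, top 20
principal components) and a one-dimensional principal curve is fitted by
the classic project-then-smooth iteration: each coordinate is smoothed
against the current arc-length parameter, cells are re-projected onto the
resulting polyline, and the loop repeats until projections stop moving.
Pseudotime is normalized arc length, oriented so adult cells score high.
Held-out (e.g. mutant) cells are projected through the stored centering,
scaling and rotation onto the same curve, making genotypes directly
comparable on one maturity axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from anndata import AnnData
from scipy.interpolate import make_smoothing_spline

from .qc import PCASpace, log_normalize, module_score, run_pca, select_hvgs

__all__ = [
    "PseudotimeCurve",
    "CoreMaturationGeneSet",
    "fit_pseudotime_curve",
    "project_cells",
    "delay_test",
    "estimate_delay",
    "identify_core_maturation_genes",
    "maturation_module_comparison",
]


@dataclass
class PseudotimeCurve:
    cell_type: str
    space: PCASpace               # 20-component embedding of the control data
    control_points: np.ndarray    # ordered curve points in the reduced space
    cum_arclen: np.ndarray        # arc length at each control point
    flipped: bool                 # True if raw arc length ran adult -> young
    lam_lo: float                 # training arc-length range, for [0, 1] scaling
    lam_hi: float
    converged: bool
    training_pseudotime: pd.Series = field(repr=False)


@dataclass
class CoreMaturationGeneSet:
    genes: list[str]
    log2_fc: pd.Series
    adult_fraction: pd.Series
    lfc_min: float
    pct_min: float
    n_per_type: int
    seed: int


# ---------------------------------------------------------------------------
# principal curve machinery

def _project_polyline(points: np.ndarray, ctrl: np.ndarray,
                      cum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project ``points`` onto the polyline through ``ctrl``; return the
    arc-length parameter and the projected coordinates."""
    a = ctrl[:-1]                                   # S x d
    seg = ctrl[1:] - a
    seg_len2 = np.maximum((seg ** 2).sum(axis=1), 1e-300)
    diff = points[:, None, :] - a[None, :, :]       # N x S x d
    t = np.clip((diff * seg[None, :, :]).sum(axis=2) / seg_len2, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    rows = np.arange(len(points))
    lam = cum[best] + t[rows, best] * np.sqrt(seg_len2[best])
    return lam, proj[rows, best]


def _smooth_curve(Y: np.ndarray, lam: np.ndarray, n_ctrl: int,
                  spline: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """One smoothing pass: average cells within quantile bins of ``lam``
    (a regressogram smoother); optionally polish the control points with a
    GCV-penalized cubic spline across bins (used for the final curve)."""
    order = np.argsort(lam, kind="stable")
    n_ctrl = max(2, min(n_ctrl, len(lam) // 5, len(lam)))
    bins = [b for b in np.array_split(order, n_ctrl) if len(b)]
    lam_b = np.array([lam[b].mean() for b in bins])
    ctrl = np.vstack([Y[b].mean(axis=0) for b in bins])
    if spline and len(lam_b) >= 5:
        # strictly increasing abscissae are required by the spline
        lam_b = lam_b + np.arange(len(lam_b)) * 1e-9
        for j in range(ctrl.shape[1]):
            ctrl[:, j] = make_smoothing_spline(lam_b, ctrl[:, j])(lam_b)
    steps = np.sqrt(((np.diff(ctrl, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return ctrl, cum


def fit_pseudotime_curve(adata: AnnData, adult_age: str | None = None,
                         n_hvgs: int = 2000, n_pcs: int = 20,
                         n_ctrl_points: int = 50,
                         max_iter: int = 50, tol: float = 1e-4,
                         seed: int = 0) -> PseudotimeCurve:
    """Fit the maturation principal curve for one cell type.

    ``adata`` holds raw counts of control cells across >= 3 ages, with
    ordered ``obs['age']``. Initialization is the first principal
    component; convergence is declared when the mean squared projection
    distance stops improving (relative change below ``tol``) or the mean
    projection displacement falls below ``tol`` times the data scale.
    The converged curve is polished once with a smoothing spline before
    arc lengths are finalized.
    """
    ages_present = [a for a in adata.obs["age"].cat.categories
                    if (adata.obs["age"] == a).any()]
    if len(ages_present) < 3:
        raise ValueError(f"need >= 3 ages, have {ages_present}")
    if adata.n_obs < 50:
        raise ValueError(f"need >= 50 cells, have {adata.n_obs}")
    adult_age = ages_present[-1] if adult_age is None else adult_age

    norm = log_normalize(adata)
    hvgs = select_hvgs(norm, n=n_hvgs)
    space = run_pca(norm, hvgs, n_components=n_pcs, seed=seed)
    Y = space.scores
    scale = float(np.sqrt((Y.var(axis=0)).sum()))
    lam = Y[:, 0].copy()

    converged = False
    prev_proj, prev_d2 = None, None
    for _ in range(max_iter):
        ctrl, cum = _smooth_curve(Y, lam, n_ctrl_points)
        lam, proj = _project_polyline(Y, ctrl, cum)
        d2 = float(((Y - proj) ** 2).sum(axis=1).mean())
        if prev_proj is not None:
            move = float(np.linalg.norm(proj - prev_proj, axis=1).mean())
            if move < tol * scale or abs(prev_d2 - d2) <= tol * max(prev_d2, 1e-12):
                converged = True
                break
        prev_proj, prev_d2 = proj, d2
    if not converged:
        warnings.warn("principal curve did not converge; returning last iterate")
    ctrl, cum = _smooth_curve(Y, lam, n_ctrl_points, spline=True)
    lam, _ = _project_polyline(Y, ctrl, cum)

    age_vals = adata.obs["age"].to_numpy()
    flipped = (lam[age_vals == adult_age].mean()
               < lam[age_vals == ages_present[0]].mean())
    if flipped:
        lam = cum[-1] - lam
    lam_lo, lam_hi = float(lam.min()), float(lam.max())
    if lam_hi <= lam_lo:
        lam_hi = lam_lo + 1.0
    pt = pd.Series((lam - lam_lo) / (lam_hi - lam_lo), index=adata.obs_names,
                   name="pseudotime")
    ct = str(adata.obs["cell_type"].iloc[0]) if "cell_type" in adata.obs else ""
    return PseudotimeCurve(
        cell_type=ct, space=space, control_points=ctrl, cum_arclen=cum,
        flipped=flipped, lam_lo=lam_lo, lam_hi=lam_hi,
        converged=converged, training_pseudotime=pt,
    )


def project_cells(curve: PseudotimeCurve, adata: AnnData) -> pd.Series:
    """Pseudotime of new cells (raw counts): log-normalize, map through the
    stored centering/scaling/rotation, project onto the curve, and rescale
    with the training normalization; values are clipped to [0, 1]."""
    norm = log_normalize(adata)
    Y = curve.space.transform(norm)
    lam, _ = _project_polyline(Y, curve.control_points, curve.cum_arclen)
    if curve.flipped:
        lam = curve.cum_arclen[-1] - lam
    t = (lam - curve.lam_lo) / (curve.lam_hi - curve.lam_lo)
    return pd.Series(np.clip(t, 0.0, 1.0), index=adata.obs_names, name="pseudotime")


# ---------------------------------------------------------------------------
# delay analysis

def delay_test(pseudotime: pd.DataFrame, min_cell_types: int = 5) -> pd.DataFrame:
    """Per-age two-sided t-test of mutant vs control cell-type mean
    pseudotime.

    ``pseudotime`` has one row per cell with columns ``cell_type``,
    ``genotype`` ('control'/'mutant'), ``age`` and ``pseudotime``. Cells
    are first averaged within (age, genotype, cell type); ages with fewer
    than ``min_cell_types`` cell types in either genotype are skipped.
    """
    genotypes = set(pseudotime["genotype"].astype(str))
    if not {"control", "mutant"} <= genotypes:
        missing = {"control", "mutant"} - genotypes
        raise ValueError(f"genotype(s) absent from the data: {sorted(missing)}")
    ages = (list(pseudotime["age"].cat.categories)
            if isinstance(pseudotime["age"].dtype, pd.CategoricalDtype)
            else list(pd.unique(pseudotime["age"])))
    rows = []
    for age in ages:
        at_age = pseudotime[pseudotime["age"] == age]
        if not len(at_age):
            continue
        means = (at_age.groupby(["genotype", "cell_type"], observed=True)["pseudotime"]
                 .mean())
        try:
            ctl = means.loc["control"]
            mut = means.loc["mutant"]
        except KeyError:
            warnings.warn(f"age {age!r}: a genotype has no cells; skipped")
            continue
        if len(ctl) < min_cell_types or len(mut) < min_cell_types:
            warnings.warn(f"age {age!r}: fewer than {min_cell_types} cell types "
                          "per genotype; skipped")
            continue
        res = st.ttest_ind(mut.to_numpy(), ctl.to_numpy())
        rows.append({"age": age, "p_value": float(res.pvalue),
                     "mean_difference": float(mut.mean() - ctl.mean()),
                     "n_control": len(ctl), "n_mutant": len(mut)})
    return pd.DataFrame(rows)


def estimate_delay(pseudotime: pd.DataFrame, max_shift: int = 3,
                   exclude_final_age: bool = True) -> int:
    """Estimate the developmental delay, in whole age stages, as the shift
    d minimizing the squared discrepancy between the mutant per-age mean
    pseudotime and the control means shifted d stages earlier.

    The final (adult) age is excluded by default because a transient delay
    has converged there.
    """
    ages = (list(pseudotime["age"].cat.categories)
            if isinstance(pseudotime["age"].dtype, pd.CategoricalDtype)
            else list(pd.unique(pseudotime["age"])))
    prof = (pseudotime.groupby(["genotype", "age", "cell_type"], observed=True)
            ["pseudotime"].mean()
            .groupby(["genotype", "age"], observed=True).mean())
    use_ages = ages[:-1] if exclude_final_age else ages
    ctl = np.array([prof.get(("control", a), np.nan) for a in use_ages])
    mut = np.array([prof.get(("mutant", a), np.nan) for a in use_ages])
    best_d, best_err = 0, np.inf
    for d in range(0, max_shift + 1):
        j = np.arange(d, len(use_ages))
        pair_ok = ~np.isnan(mut[j]) & ~np.isnan(ctl[j - d])
        if pair_ok.sum() < 2:
            continue
        err = float(np.mean((mut[j][pair_ok] - ctl[j - d][pair_ok]) ** 2))
        if err < best_err:
            best_d, best_err = d, err
    return best_d


# ---------------------------------------------------------------------------
# core maturation genes

def identify_core_maturation_genes(adata: AnnData, n_per_type: int = 10,
                                   lfc_min: float = 0.5, pct_min: float = 0.3,
                                   youngest_ages: tuple[str, ...] | None = None,
                                   adult_age: str | None = None,
                                   seed: int = 0) -> CoreMaturationGeneSet:
    """Genes upregulated with age in all cell types.

    A balanced subsample (seeded) of ``n_per_type`` cells per cell type is
    drawn at the youngest stage(s) (default: the first two, pooled) and at
    the adult stage; genes with adult-vs-young log2 fold change above
    ``lfc_min`` that are expressed in at least ``pct_min`` of the sampled
    adult cells are kept. Cell types lacking either stage are excluded.
    """
    ages = list(adata.obs["age"].cat.categories)
    youngest_ages = tuple(ages[:2]) if youngest_ages is None else youngest_ages
    adult_age = ages[-1] if adult_age is None else adult_age
    rng = np.random.default_rng(seed)

    young_mask = adata.obs["age"].isin(youngest_ages).to_numpy()
    adult_mask = (adata.obs["age"] == adult_age).to_numpy()
    young_idx, adult_idx = [], []
    for ct in adata.obs["cell_type"].cat.categories:
        in_ct = (adata.obs["cell_type"] == ct).to_numpy()
        y = np.flatnonzero(in_ct & young_mask)
        a = np.flatnonzero(in_ct & adult_mask)
        if not len(y) or not len(a):
            warnings.warn(f"cell type {ct!r} lacks a stage; excluded")
            continue
        young_idx.extend(rng.choice(y, size=min(n_per_type, len(y)), replace=False))
        adult_idx.extend(rng.choice(a, size=min(n_per_type, len(a)), replace=False))
    if not young_idx or not adult_idx:
        raise ValueError("no cell type has cells at both stages")

    pooled = adata[np.concatenate([young_idx, adult_idx])].copy()
    norm = log_normalize(pooled)
    ny = len(young_idx)
    Xn = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X)
    young_mean = np.expm1(Xn[:ny]).mean(axis=0)
    adult_mean = np.expm1(Xn[ny:]).mean(axis=0)
    eps = 1e-9
    log2_fc = np.log2((adult_mean + eps) / (young_mean + eps))
    Xa = pooled.X[len(young_idx):]
    pct = np.asarray((Xa > 0).mean(axis=0)).ravel()

    keep = (log2_fc > lfc_min) & (pct >= pct_min)
    genes = list(np.asarray(norm.var_names)[keep])
    return CoreMaturationGeneSet(
        genes=genes,
        log2_fc=pd.Series(log2_fc, index=norm.var_names, name="log2_fc"),
        adult_fraction=pd.Series(pct, index=norm.var_names, name="adult_fraction"),
        lfc_min=lfc_min, pct_min=pct_min, n_per_type=n_per_type, seed=seed,
    )


def maturation_module_comparison(adata: AnnData, gene_set: list[str],
                                 seed: int = 0) -> tuple[pd.DataFrame, float]:
    """Module score of ``gene_set`` per cell (computed jointly so genotypes
    share control bins), averaged per (genotype, cell type), with a
    two-sided t-test of mutant vs control cell-type means."""
    if not gene_set:
        raise ValueError("gene set is empty")
    norm = log_normalize(adata)
    score = module_score(norm, gene_set, seed=seed)
    df = pd.DataFrame({
        "genotype": adata.obs["genotype"].astype(str).to_numpy(),
        "cell_type": adata.obs["cell_type"].astype(str).to_numpy(),
        "score": score.to_numpy(),
    })
    means = df.groupby(["genotype", "cell_type"], observed=True)["score"].mean()
    ctl = means.loc["control"]
    mut = means.loc["mutant"]
    p = float(st.ttest_ind(mut.to_numpy(), ctl.to_numpy()).pvalue)
    return means.reset_index(), p
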