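"""Per-cell-type maturation-distance trajectories and maturity measures.

For one cell type observed across an ordered series of age stages, maturity
is quantified as the Manhattan (L1) distance between each age's centroid
and the adult centroid in a reduced expression space (log-normalization,
2,000 highly variable genes, PCA, and as many leading components as are
needed to explain 20% of variance, capped at 100). The distance series is
then *monotonized* — any increase is clamped to the previous value — and
classified as gradual, intermediate or stepwise by how few inter-age steps
carry 90% of the total decline.

A complementary neighbourhood measure asks, for the cells of each age,
what fraction of their k nearest neighbours (default 50, same reduced
space, Euclidean metric) are adult cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

from .qc import log_normalize, pc_count_for_variance, run_pca, select_hvgs

__all__ = [
    "DistanceTrajectory",
    "age_centroid_distances",
    "NNMaturity",
    "reduced_embedding",
    "distance_trajectory",
    "monotonize",
    "classify_trajectory",
    "nn_maturity",
    "compare_trajectory_groups",
]


@dataclass
class DistanceTrajectory:
    cell_type: str
    ages: list[str]
    n_pcs: int
    raw_distance: np.ndarray     # per age; 0 at the adult stage
    mono_distance: np.ndarray
    step_decrease: np.ndarray    # per consecutive age pair, >= 0
    trajectory_class: int | None
    n_cells: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_type": self.cell_type, "age": self.ages,
            "raw_distance": self.raw_distance,
            "mono_distance": self.mono_distance,
            "n_cells": self.n_cells,
        })


@dataclass
class NNMaturity:
    cell_type: str
    ages: list[str]
    k: int
    adult_fraction: np.ndarray   # per age, in [0, 1]


def reduced_embedding(adata: AnnData, n_hvgs: int = 2000, n_pcs: int = 100,
                      variance_target: float = 0.20, seed: int = 0
                      ) -> tuple[np.ndarray, int]:
    """Shared reduction pipeline: log-normalize raw counts, select HVGs,
    PCA, and keep the leading components explaining ``variance_target`` of
    variance (capped at ``n_pcs``). Returns (cells x m scores, m)."""
    norm = log_normalize(adata)
    hvgs = select_hvgs(norm, n=n_hvgs)
    space = run_pca(norm, hvgs, n_components=n_pcs, seed=seed)
    m = pc_count_for_variance(space, target=variance_target, cap=n_pcs)
    return space.scores[:, :m], m


def _ages_with_enough_cells(adata: AnnData, min_cells: int) -> list[str]:
    counts = adata.obs["age"].value_counts()
    ages = [a for a in adata.obs["age"].cat.categories if counts.get(a, 0) > 0]
    kept = [a for a in ages if counts[a] >= min_cells]
    dropped = sorted(set(ages) - set(kept))
    if dropped:
        warnings.warn(f"ages with fewer than {min_cells} cells dropped: {dropped}")
    return kept


def distance_trajectory(adata: AnnData, adult_age: str | None = None,
                        min_cells: int = 10, n_hvgs: int = 2000,
                        n_pcs: int = 100, seed: int = 0) -> DistanceTrajectory:
    """Maturation-distance trajectory of one cell type (raw counts in
    ``adata``; all cells are assumed to belong to the cell type)."""
    kept = _ages_with_enough_cells(adata, min_cells)
    if len(kept) < 2:
        raise ValueError(f"need at least 2 ages with >= {min_cells} cells, have {kept}")
    adult_age = kept[-1] if adult_age is None else adult_age
    if adult_age not in kept:
        raise ValueError(f"adult age {adult_age!r} absent or below min_cells")
    sub = adata[adata.obs["age"].isin(kept)].copy()
    emb, m = reduced_embedding(sub, n_hvgs=n_hvgs, n_pcs=n_pcs, seed=seed)
    age_vals = sub.obs["age"].to_numpy()
    raw = age_centroid_distances(emb, age_vals, kept, adult_age)
    mono = monotonize(raw)
    steps = -np.diff(mono)
    ct = str(sub.obs["cell_type"].iloc[0]) if "cell_type" in sub.obs else ""
    return DistanceTrajectory(
        cell_type=ct, ages=kept, n_pcs=m,
        raw_distance=raw, mono_distance=mono, step_decrease=steps,
        trajectory_class=classify_trajectory(mono),
        n_cells=np.array([(age_vals == a).sum() for a in kept]),
    )


def age_centroid_distances(embedding: np.ndarray, age_values: np.ndarray,
                           ages: list[str], adult_age: str) -> np.ndarray:
    """Manhattan (L1) distance between each age's centroid and the adult
    centroid in the given embedding; the adult entry is exactly 0."""
    centroids = {a: embedding[np.asarray(age_values) == a].mean(axis=0)
                 for a in ages}
    return np.array([np.abs(centroids[a] - centroids[adult_age]).sum()
                     for a in ages])


def monotonize(raw: np.ndarray | list[float]) -> np.ndarray:
    """Clamp the distance series to be non-increasing: any value above its
    predecessor is replaced by the predecessor (running minimum)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("monotonize requires at least one value")
    return np.minimum.accumulate(raw)


def classify_trajectory(mono: np.ndarray | list[float]) -> int | None:
    """Gradual (1), intermediate (2) or stepwise (3) maturation mode.

    k is the smallest number of inter-age steps, taken largest first, whose
    decreases sum to at least 90% of the total decline: k <= 2 is stepwise
    (class 3), k == 3 intermediate (class 2), k >= 4 gradual (class 1).
    Returns None when there is no decline to classify.
    """
    mono = np.asarray(mono, dtype=float)
    total = mono[0] - mono[-1]
    if total <= 0:
        return None
    steps = np.sort(-np.diff(mono))[::-1]
    k = int(np.searchsorted(np.cumsum(steps), 0.9 * total - 1e-12)) + 1
    if k <= 2:
        return 3
    if k == 3:
        return 2
    return 1


def nn_maturity(adata: AnnData, adult_age: str | None = None, k: int = 50,
                min_cells: int = 10, n_hvgs: int = 2000, n_pcs: int = 100,
                seed: int = 0) -> NNMaturity:
    """Fraction of adult cells among the k nearest neighbours (Euclidean,
    self excluded) of each age's cells, in the shared reduced space."""
    kept = _ages_with_enough_cells(adata, min_cells)
    if len(kept) < 2:
        raise ValueError("need at least 2 ages")
    adult_age = kept[-1] if adult_age is None else adult_age
    sub = adata[adata.obs["age"].isin(kept)].copy()
    if sub.n_obs <= k:
        raise ValueError(
            f"need more than k={k} cells, have {sub.n_obs}; use a smaller k")
    emb, _ = reduced_embedding(sub, n_hvgs=n_hvgs, n_pcs=n_pcs, seed=seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    idx = idx[:, 1:]                               # drop self
    is_adult = (sub.obs["age"] == adult_age).to_numpy()
    adult_neighbour = is_adult[idx]
    age_vals = sub.obs["age"].to_numpy()
    frac = np.array([adult_neighbour[age_vals == a].mean() for a in kept])
    ct = str(sub.obs["cell_type"].iloc[0]) if "cell_type" in sub.obs else ""
    return NNMaturity(cell_type=ct, ages=kept, k=k, adult_fraction=frac)


def compare_trajectory_groups(trajectories: dict[str, DistanceTrajectory],
                              groups: dict[str, str],
                              use_monotonized: bool = True) -> float:
    """Two-way fixed-effects ANOVA of distance on age and cell-type group
    (cell types as replicates); returns the group main-effect p-value."""
    labels = set(groups.values())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        members = [ct for ct, lab in groups.items() if lab == g and ct in trajectories]
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cell types")
    rows = []
    for ct, traj in trajectories.items():
        if ct not in groups:
            continue
        d = traj.mono_distance if use_monotonized else traj.raw_distance
        for age, dist in zip(traj.ages, d):
            rows.append({"distance": dist, "age": age, "grp": groups[ct]})
    df = pd.DataFrame(rows)
    fit = smf.ols("distance ~ C(age) + C(grp)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return float(table.loc["C(grp)", "PR(>F)"])
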