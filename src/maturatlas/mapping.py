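"""Reference-based cell-type label transfer with threshold-gated assignment.

Younger (or perturbed) cells are labelled by projecting them into a PCA
space fitted on a labelled reference and taking distance-weighted k-nearest
-neighbour votes among reference cells. The resulting per-cell score vector
over reference labels sums to one; labels are accepted only when the top
score clears an absolute threshold, or a lower threshold together with a
dominance ratio over the runner-up — otherwise the cell stays unassigned
and is excluded from downstream per-cell-type statistics.

Iterative age mapping proceeds from the adult stage backwards: each age is
labelled against the union of all older, already-labelled ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

from .qc import PCASpace, log_normalize, run_pca, select_hvgs

__all__ = [
    "UNASSIGNED",
    "ReferenceModel",
    "train_reference",
    "prediction_scores",
    "assign_labels",
    "identity_ratio",
    "score_matrix",
    "map_ages_iteratively",
]

UNASSIGNED = "unassigned"


@dataclass
class ReferenceModel:
    space: PCASpace
    labels: np.ndarray            # per reference cell
    label_names: list[str]
    k: int
    nn: NearestNeighbors


def train_reference(norm_ref: AnnData, labels: pd.Series | None = None,
                    n_hvgs: int = 2000, n_pcs: int = 150, k: int = 30,
                    seed: int = 0) -> ReferenceModel:
    """Fit the reference projection (HVGs + PCA, up to ``n_pcs`` components)
    and index the labelled reference cells for neighbour voting."""
    labels = (norm_ref.obs["cell_type"] if labels is None
              else pd.Series(labels, index=norm_ref.obs_names))
    labels = labels.astype(str)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("reference needs at least 2 distinct labels")
    small = [n for n in names if (labels == n).sum() < k]
    if small:
        warnings.warn(f"labels with fewer than k={k} cells (retained): {small}")
    hvgs = select_hvgs(norm_ref, n=n_hvgs)
    space = run_pca(norm_ref, hvgs, n_components=n_pcs, seed=seed)
    nn = NearestNeighbors(n_neighbors=min(k, norm_ref.n_obs)).fit(space.scores)
    return ReferenceModel(space=space, labels=labels.to_numpy(),
                          label_names=names, k=k, nn=nn)


def prediction_scores(model: ReferenceModel, query_norm: AnnData) -> pd.DataFrame:
    """Distance-weighted neighbour vote fractions over reference labels.

    Each row sums to 1. Weights are inverse distances; an exact match
    (distance 0) takes the whole vote.
    """
    Q = model.space.transform(query_norm)
    dist, idx = model.nn.kneighbors(Q)
    votes = model.labels[idx]                          # cells x k
    scores = np.zeros((Q.shape[0], len(model.label_names)))
    pos = {n: j for j, n in enumerate(model.label_names)}
    exact = dist < 1e-12
    w = np.where(exact, 0.0, 1.0 / np.maximum(dist, 1e-12))
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact].astype(float)
    w /= w.sum(axis=1, keepdims=True)
    for j in range(votes.shape[1]):
        np.add.at(scores, (np.arange(Q.shape[0]),
                           [pos[v] for v in votes[:, j]]), w[:, j])
    return pd.DataFrame(scores, index=query_norm.obs_names, columns=model.label_names)


def assign_labels(scores: pd.DataFrame, hi: float = 0.8, lo: float = 0.5,
                  ratio: float = 2.0) -> pd.Series:
    """Accept the top label if its score exceeds ``hi``; or if it exceeds
    ``lo`` and is at least ``ratio`` times the second-best score."""
    vals = scores.to_numpy()
    order = np.argsort(vals, axis=1)
    top = vals[np.arange(len(vals)), order[:, -1]]
    second = vals[np.arange(len(vals)), order[:, -2]] if vals.shape[1] > 1 \
        else np.zeros(len(vals))
    accept = (top > hi) | ((top > lo) & (top >= ratio * second))
    labels = np.where(accept,
                      np.asarray(scores.columns)[order[:, -1]], UNASSIGNED)
    return pd.Series(labels, index=scores.index, name="assigned")


def identity_ratio(row: pd.Series, diagonal_label: str) -> float:
    """(diagonal - best off-diagonal) / diagonal for one row of a mean
    prediction-score matrix."""
    diag = row[diagonal_label]
    off = row.drop(diagonal_label)
    if diag == 0:
        return float("nan")
    return float((diag - (off.max() if len(off) else 0.0)) / diag)


def score_matrix(scores: pd.DataFrame, assigned: pd.Series) -> pd.DataFrame:
    """Mean prediction scores per assigned query cell type (rows) over
    reference labels (columns); unassigned cells are excluded."""
    keep = assigned != UNASSIGNED
    if not keep.any():
        raise ValueError("no assigned cells to aggregate")
    mat = scores[keep].groupby(assigned[keep], observed=True).mean()
    mat["identity_ratio"] = [
        identity_ratio(mat.loc[ct].drop("identity_ratio", errors="ignore"), ct)
        if ct in mat.columns else float("nan")
        for ct in mat.index
    ]
    return mat


def map_ages_iteratively(adata: AnnData, adult_age: str | None = None,
                         n_hvgs: int = 2000, n_pcs: int = 150, k: int = 30,
                         hi: float = 0.8, lo: float = 0.5, ratio: float = 2.0,
                         seed: int = 0) -> tuple[pd.Series, dict[str, pd.DataFrame],
                                                 pd.Series]:
    """Label all pre-adult ages against progressively growing references.

    ``adata`` holds raw counts with ordered ``obs['age']``; adult cells must
    carry ``obs['cell_type']``. Ages are processed oldest to youngest, each
    mapped onto the union of all older (already labelled) ages. Returns the
    per-cell labels, the per-age mean score matrices, and per-age assignment
    rates. Aborts if an age yields zero assigned cells.
    """
    ages = list(adata.obs["age"].cat.categories)
    adult_age = ages[-1] if adult_age is None else adult_age
    labels = pd.Series(UNASSIGNED, index=adata.obs_names, name="assigned", dtype=object)
    adult_mask = (adata.obs["age"] == adult_age).to_numpy()
    labels[adult_mask] = adata.obs.loc[adult_mask, "cell_type"].astype(str)

    matrices: dict[str, pd.DataFrame] = {}
    rates: dict[str, float] = {}
    younger = [a for a in ages if a != adult_age][::-1]  # oldest first
    for age in younger:
        ref_mask = (labels != UNASSIGNED).to_numpy()
        ref = log_normalize(adata[ref_mask].copy())
        model = train_reference(ref, labels[ref_mask], n_hvgs=n_hvgs,
                                n_pcs=n_pcs, k=k, seed=seed)
        q_mask = (adata.obs["age"] == age).to_numpy()
        query = log_normalize(adata[q_mask].copy())
        scores = prediction_scores(model, query)
        assigned = assign_labels(scores, hi=hi, lo=lo, ratio=ratio)
        if (assigned == UNASSIGNED).all():
            raise RuntimeError(
                f"age {age!r}: no cell passed the assignment thresholds "
                f"(top-score max {scores.max().max():.3f})")
        labels[q_mask] = assigned.values
        matrices[age] = score_matrix(scores, assigned)
        rates[age] = float((assigned != UNASSIGNED).mean())
    return labels, matrices, pd.Series(rates, name="assignment_rate")
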