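"""Synthetic single-nucleus count data with planted developmental structure.

The generator emulates a developmental atlas design: an ordered series of
age stages (default E16 through P65), a small number of biological samples
per sex per age, many transcriptomically distinct cell types, and
negative-binomial UMI counts with cell-specific library sizes.

Planted structure, all recorded in a :class:`GroundTruth` table:

* per-gene age trends (flat / gradual / step / transient) with a
  configurable log-amplitude;
* a per-cell-type *maturation clock* — a monotone progress curve over the
  age axis that gradual trend genes follow, so that each cell type can be
  planted with a gradual, intermediate, or stepwise maturation trajectory;
* marker genes giving each cell type a stable identity (baseline
  multiplier, so label transfer is learnable);
* optional sex effects (log-fold shifts in chosen genes / cell types /
  ages, applied to female cells);
* an optional "mutant" genotype whose maturation clock lags the control
  clock by a whole number of age stages, converging by the final (adult)
  stage — emulating a transient developmental delay.

Counts for gene g in cell i of cell type c at (effective) age t are

    X ~ NB(mean = mu_gc(t) * depth_i / E[depth],  dispersion = theta)

with Var = mu + mu^2 / theta, so theta -> infinity recovers Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "DEFAULT_AGES",
    "GENE_CATEGORIES",
    "SyntheticSpec",
    "SexEffect",
    "GroundTruth",
    "generate_dataset",
    "trajectory_class_suite",
]

#: Ordered developmental stages of the default design (embryonic day 16
#: through postnatal day 65); the last stage is the adult reference.
DEFAULT_AGES: tuple[str, ...] = ("E16", "E18", "P0", "P4", "P10", "P18", "P28", "P65")

#: Gene category flags carried in ``var`` and used by QC / gene exclusion.
GENE_CATEGORIES: tuple[str, ...] = (
    "mito", "ribo", "ieg", "apoptotic", "rbc", "chrY", "xinact",
)

TREND_SHAPES = ("flat", "gradual-up", "gradual-down", "step", "transient")


@dataclass(frozen=True)
class SexEffect:
    """A planted sex difference: ``genes`` are shifted by ``log_fc`` (natural
    log) in female cells of ``cell_type`` at the listed ``ages``."""

    cell_type: str
    genes: tuple[str, ...]
    log_fc: float
    ages: tuple[str, ...]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults give a small but complete atlas: 12 cell types, 2,000 genes,
    2 samples per sex at each of 8 stages, 60 cells per cell type per
    sample, library sizes centred on ~5,000 UMIs per cell.
    """

    n_cell_types: int = 12
    n_genes: int = 2000
    ages: tuple[str, ...] = DEFAULT_AGES
    samples_per_sex_per_age: int = 2
    cells_per_type_per_sample: int = 60
    # log-normal library-size model; E[depth] = exp(mean + sd^2/2)
    depth_log_mean: float = float(np.log(5000.0))
    depth_log_sd: float = 0.35
    nb_dispersion: float = 2.0
    #: real cell types differ in dozens of well-expressed program genes;
    #: fewer make identities unlearnable in a 150-component space
    marker_genes_per_type: int = 50
    marker_multiplier: float = 8.0
    #: the gene panel emulates the highly-variable-gene subspace of a real
    #: atlas, in which developmentally regulated genes are a large fraction
    #: (thousands of shared devDEGs against a 2,000-gene HVG panel)
    trend_gene_fraction: float = 0.5
    #: per-gene shape assignment; None draws shapes with `trend_shape_weights`
    trend_library: dict[str, str] | None = None
    trend_shape_weights: dict[str, float] = field(
        default_factory=lambda: {
            "gradual-up": 0.4, "gradual-down": 0.2, "step": 0.2, "transient": 0.2,
        }
    )
    trend_amplitude: float = 2.0
    sex_effect: tuple[SexEffect, ...] = ()
    #: number of "mutant" genotype samples per sex per age (0 = control only)
    mutant_samples_per_sex_per_age: int = 0
    delay_stages: int = 0
    #: planted maturation class per cell type (1 gradual / 2 intermediate /
    #: 3 stepwise); None plants class 1 (linear clock) everywhere
    maturation_classes: tuple[int, ...] | None = None
    gene_category_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "mito": 0.005, "ribo": 0.01, "ieg": 0.005,
            "apoptotic": 0.005, "rbc": 0.002, "chrY": 0.002, "xinact": 0.002,
        }
    )
    #: expected share of a healthy cell's counts carried by each category;
    #: kept well below the QC thresholds so default data passes QC
    category_expression_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "mito": 0.03, "ribo": 0.03, "ieg": 0.003,
            "apoptotic": 0.003, "rbc": 0.003, "chrY": 0.002, "xinact": 0.002,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        def _positive(name):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")

        for f in ("n_cell_types", "n_genes", "samples_per_sex_per_age",
                  "cells_per_type_per_sample", "nb_dispersion",
                  "trend_amplitude", "marker_multiplier"):
            _positive(f)
        if len(self.ages) < 2:
            raise ValueError("ages must contain at least 2 stages (last stage is the adult)")
        if len(set(self.ages)) != len(self.ages):
            raise ValueError("ages must be unique stage labels")
        if not 0.0 <= self.trend_gene_fraction <= 1.0:
            raise ValueError(f"trend_gene_fraction must be in [0, 1], got {self.trend_gene_fraction!r}")
        if self.delay_stages < 0 or self.delay_stages >= len(self.ages):
            raise ValueError(f"delay_stages must be in [0, n_ages), got {self.delay_stages!r}")
        if self.mutant_samples_per_sex_per_age < 0:
            raise ValueError("mutant_samples_per_sex_per_age must be >= 0")
        if self.depth_log_sd < 0:
            raise ValueError(f"depth_log_sd must be >= 0, got {self.depth_log_sd!r}")
        bad = {k: v for k, v in self.gene_category_fractions.items()
               if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"gene_category_fractions outside [0, 1]: {bad}")
        if sum(self.gene_category_fractions.values()) > 1.0:
            raise ValueError("gene_category_fractions must sum to <= 1")
        unknown = set(self.gene_category_fractions) - set(GENE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown gene categories: {sorted(unknown)}")
        if self.maturation_classes is not None:
            if len(self.maturation_classes) != self.n_cell_types:
                raise ValueError("maturation_classes must have one entry per cell type")
            if not set(self.maturation_classes) <= {1, 2, 3}:
                raise ValueError("maturation_classes entries must be 1, 2 or 3")
        if self.trend_library is not None:
            bad_shapes = {v for v in self.trend_library.values()} - set(TREND_SHAPES)
            if bad_shapes:
                raise ValueError(f"trend_library contains unknown shapes: {sorted(bad_shapes)}")


@dataclass
class GroundTruth:
    """Planted effects of one generated dataset."""

    genes: pd.DataFrame          # gene_id, trend_class, stage, amplitude
    cell_types: pd.DataFrame     # cell_type, maturation_class
    sex_effects: pd.DataFrame    # cell_type, gene, log_fc, age
    delay_stages: int


# ---------------------------------------------------------------------------
# maturation clocks

def _clock_increments(mat_class: int, n_steps: int) -> np.ndarray:
    """Per-step increments of a maturation progress curve (sum to 1).

    Class 1 advances evenly across all steps; class 2 concentrates ~93% of
    progress in three steps; class 3 concentrates ~95% in two steps. The
    concentrated steps are the late ones (indices -5, -3, -1 of the step
    axis), mimicking the pre-weaning and pubertal maturation bursts.
    """
    inc = np.full(n_steps, 1.0 / n_steps)
    if mat_class == 1 or n_steps < 4:
        return inc
    if mat_class == 2:
        big = [n_steps - 5, n_steps - 3, n_steps - 1]
        big = [max(0, b) for b in big]
        inc = np.full(n_steps, 0.07 / max(1, n_steps - 3))
        for b in big:
            inc[b] = 0.0
        for b in big:
            inc[b] += 0.93 / 3
    elif mat_class == 3:
        big = [n_steps - 3, n_steps - 1]
        inc = np.full(n_steps, 0.05 / max(1, n_steps - 2))
        for b in big:
            inc[b] = 0.0
        for b in big:
            inc[b] += 0.95 / 2
    else:  # pragma: no cover - guarded in validate()
        raise ValueError(f"unknown maturation class {mat_class!r}")
    return inc / inc.sum()


def _clock_curve(mat_class: int, n_ages: int) -> np.ndarray:
    """Progress curve p(t) in [0, 1] over age ranks, p(adult) = 1."""
    p = np.concatenate([[0.0], np.cumsum(_clock_increments(mat_class, n_ages - 1))])
    p[-1] = 1.0
    return p


# ---------------------------------------------------------------------------
# generation

def _gene_log_effects(spec: SyntheticSpec, genes: pd.DataFrame,
                      clock: np.ndarray) -> np.ndarray:
    """Log-scale age effect per (gene, age rank) for one cell type.

    Gradual genes follow the cell type's maturation clock; step genes jump
    at their planted stage; transient genes peak at their planted stage.
    Each gene's effect is mean-centred across ages so library-size
    calibration is insensitive to the trend assignment.
    """
    n_ages = len(spec.ages)
    ranks = np.arange(n_ages)
    eff = np.zeros((len(genes), n_ages))
    amp = genes["amplitude"].to_numpy()
    shape = genes["trend_class"].to_numpy()
    stage = genes["stage"].to_numpy()
    up = shape == "gradual-up"
    eff[up] = amp[up, None] * clock[None, :]
    down = shape == "gradual-down"
    eff[down] = amp[down, None] * (1.0 - clock[None, :])
    st = shape == "step"
    eff[st] = amp[st, None] * (ranks[None, :] >= stage[st, None])
    tr = shape == "transient"
    eff[tr] = amp[tr, None] * (ranks[None, :] == stage[tr, None])
    eff -= eff.mean(axis=1, keepdims=True)
    return eff


def generate_dataset(spec: SyntheticSpec) -> tuple[AnnData, GroundTruth]:
    """Draw one dataset from ``spec``; deterministic given ``spec.seed``.

    Returns an :class:`~anndata.AnnData` with sparse integer counts in
    ``.X``, per-cell metadata in ``.obs`` (sample, age, sex, genotype,
    cell_type) and gene category flags in ``.var``, plus the
    :class:`GroundTruth` of all planted effects.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_ages = len(spec.ages)
    adult_rank = n_ages - 1

    gene_ids = np.array([f"g{i:05d}" for i in range(spec.n_genes)])
    cell_types = [f"ct{c:02d}" for c in range(spec.n_cell_types)]

    # gene categories (disjoint flags, assigned from the front of a shuffle)
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    order = rng.permutation(spec.n_genes)
    start = 0
    for cat in GENE_CATEGORIES:
        k = int(round(spec.gene_category_fractions.get(cat, 0.0) * spec.n_genes))
        flags = np.zeros(spec.n_genes, bool)
        flags[order[start:start + k]] = True
        var[cat] = flags
        start += k

    # baseline relative abundances (log-normal across genes); flagged
    # categories are rescaled to realistic count shares, and no single gene
    # may dominate a library (cap at 2% of total)
    rel = rng.lognormal(mean=0.0, sigma=1.5, size=spec.n_genes)
    for cat in GENE_CATEGORIES:
        mask = var[cat].to_numpy()
        if mask.any() and rel[mask].sum() > 0:
            target = spec.category_expression_fractions.get(cat, 0.0)
            rel[mask] *= target * rel[~mask].sum() / ((1 - target) * rel[mask].sum())
    rel = np.minimum(rel, 0.02 * rel.sum())

    # marker genes: per-cell-type multiplier on a reserved block of genes
    flagged = var[list(GENE_CATEGORIES)].any(axis=1).to_numpy()
    free = np.flatnonzero(~flagged)
    rng.shuffle(free)
    n_marker_total = spec.marker_genes_per_type * spec.n_cell_types
    if n_marker_total > len(free):
        raise ValueError("not enough unflagged genes for the requested marker genes")
    marker_idx = {
        ct: free[c * spec.marker_genes_per_type:(c + 1) * spec.marker_genes_per_type]
        for c, ct in enumerate(cell_types)
    }
    free = free[n_marker_total:]

    # trend genes drawn from the remaining unflagged, non-marker genes,
    # restricted to detectably expressed ones: a planted trend on a gene
    # with near-zero counts is not recoverable ground truth
    n_trend = int(round(spec.trend_gene_fraction * spec.n_genes))
    floor = np.quantile(rel, 0.3)
    eligible = free[rel[free] >= floor]
    if len(eligible) < n_trend:
        # not enough genes above the floor: take the most abundant ones
        eligible = free[np.argsort(rel[free])[::-1]]
    n_trend = min(n_trend, len(eligible))
    trend_idx = np.sort(eligible[:n_trend])
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "trend_class": "flat",
        "stage": 0,
        "amplitude": 0.0,
    }).set_index("gene_id")
    if spec.trend_library is not None:
        for g, shp in spec.trend_library.items():
            genes.loc[g, "trend_class"] = shp
    else:
        shapes = list(spec.trend_shape_weights)
        w = np.array([spec.trend_shape_weights[s] for s in shapes], float)
        assigned = rng.choice(shapes, size=n_trend, p=w / w.sum())
        genes.iloc[trend_idx, genes.columns.get_loc("trend_class")] = assigned
    is_trend = genes["trend_class"] != "flat"
    genes.loc[is_trend, "amplitude"] = spec.trend_amplitude
    # step stages: any rank after the first; transient peaks: strictly
    # intermediate ranks, so a transient gene never mimics a monotone one
    n_step = int((genes["trend_class"] == "step").sum())
    genes.loc[genes["trend_class"] == "step", "stage"] = rng.integers(
        1, n_ages, size=n_step)
    n_tr = int((genes["trend_class"] == "transient").sum())
    genes.loc[genes["trend_class"] == "transient", "stage"] = rng.integers(
        1, max(2, n_ages - 1), size=n_tr)

    mat_classes = (spec.maturation_classes
                   if spec.maturation_classes is not None
                   else tuple([1] * spec.n_cell_types))
    clocks = {ct: _clock_curve(k, n_ages) for ct, k in zip(cell_types, mat_classes)}

    # per-cell-type mean profiles: baseline (markers boosted, renormalised to
    # the expected library size) times exp(age effect)
    mean_depth = float(np.exp(spec.depth_log_mean + spec.depth_log_sd ** 2 / 2))
    base = {}
    for ct in cell_types:
        b = rel.copy()
        b[marker_idx[ct]] *= spec.marker_multiplier
        base[ct] = b / b.sum() * mean_depth
    effects = {ct: _gene_log_effects(spec, genes, clocks[ct]) for ct in cell_types}

    sex_fx: list[dict] = []
    for fx in spec.sex_effect:
        for g in fx.genes:
            for a in fx.ages:
                sex_fx.append({"cell_type": fx.cell_type, "gene": g,
                               "log_fc": fx.log_fc, "age": a})
    sex_fx_df = pd.DataFrame(sex_fx, columns=["cell_type", "gene", "log_fc", "age"])
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # sample table: sample_id uniquely determines (age, sex, genotype)
    samples = []
    for age in spec.ages:
        for sex in ("M", "F"):
            for r in range(spec.samples_per_sex_per_age):
                samples.append((f"{age}_{sex}_ctl{r}", age, sex, "control"))
            for r in range(spec.mutant_samples_per_sex_per_age):
                samples.append((f"{age}_{sex}_mut{r}", age, sex, "mutant"))

    blocks, obs_rows = [], []
    theta = spec.nb_dispersion
    cell_counter = 0
    for sample_id, age, sex, genotype in samples:
        rank = spec.ages.index(age)
        if genotype == "mutant" and rank < adult_rank:
            # transient delay: the clock lags by delay_stages at pre-adult
            # stages and has converged by the final stage
            eff_rank = max(0, rank - spec.delay_stages)
        else:
            eff_rank = rank
        for ct in cell_types:
            mu = base[ct] * np.exp(effects[ct][:, eff_rank])
            # constitutive sex-chromosome biases: Y-linked genes are near-
            # silent in females, X-inactivation escapees strongly female-biased
            chrY = var["chrY"].to_numpy()
            xin = var["xinact"].to_numpy()
            if chrY.any() or xin.any():
                mu = mu.copy()
                if sex == "F":
                    mu[chrY] *= 0.01
                else:
                    mu[xin] *= 0.05
            if sex == "F" and len(sex_fx_df):
                hits = sex_fx_df[(sex_fx_df.cell_type == ct) & (sex_fx_df.age == age)]
                if len(hits):
                    mu = mu.copy()
                    for g, lfc in zip(hits["gene"], hits["log_fc"]):
                        mu[gene_pos[g]] *= np.exp(lfc)
            n = spec.cells_per_type_per_sample
            depth = np.exp(rng.normal(spec.depth_log_mean, spec.depth_log_sd, size=n))
            cell_mu = mu[None, :] * (depth / mean_depth)[:, None]
            p = theta / (theta + cell_mu)
            counts = rng.negative_binomial(theta, p).astype(np.int32)
            blocks.append(sp.csr_matrix(counts))
            for i in range(n):
                obs_rows.append((f"cell{cell_counter + i:07d}", sample_id, age,
                                 sex, genotype, ct))
            cell_counter += n

    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(
        obs_rows,
        columns=["cell_id", "sample_id", "age", "sex", "genotype", "cell_type"],
    ).set_index("cell_id")
    obs["age"] = pd.Categorical(obs["age"], categories=list(spec.ages), ordered=True)
    for col in ("sample_id", "sex", "genotype", "cell_type"):
        obs[col] = obs[col].astype("category")

    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["ages"] = list(spec.ages)
    truth = GroundTruth(
        genes=genes.reset_index(),
        cell_types=pd.DataFrame({"cell_type": cell_types,
                                 "maturation_class": list(mat_classes)}),
        sex_effects=sex_fx_df,
        delay_stages=spec.delay_stages,
    )
    return adata, truth


def trajectory_class_suite(n_per_class: int = 10, cells_per_age: int = 300,
                           seed: int = 0, n_genes: int = 2000) -> SyntheticSpec:
    """Spec planting equal numbers of gradual / intermediate / stepwise cell
    types, with all trend genes following the per-cell-type maturation clock
    (so the clock alone determines each planted trajectory class)."""
    n_types = 3 * n_per_class
    per_sample = max(1, cells_per_age // 4)  # 2 samples/sex/age
    return SyntheticSpec(
        n_cell_types=n_types,
        n_genes=n_genes,
        cells_per_type_per_sample=per_sample,
        maturation_classes=tuple([1] * n_per_class + [2] * n_per_class
                                 + [3] * n_per_class),
        trend_shape_weights={"gradual-up": 0.6, "gradual-down": 0.4},
        # identities are given in this suite; few markers leave the gene
        # budget to the clock-following trend genes
        marker_genes_per_type=10,
        seed=seed,
    )
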