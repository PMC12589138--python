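"""Validation studies: parameter-recovery and calibration experiments.

Each function simulates data under the study's design (8 ordered ages, two
samples per sex per age unless stated otherwise), runs the corresponding
analysis end to end, and reports recovery or calibration metrics against
the generator's ground truth. These are the experiments behind the
package's quantitative claims; `scripts/acceptance.py` and the test suite
both run them.

Sub-seeds for replicate runs are derived from the caller's seed with
`numpy.random.SeedSequence`, so every study is reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .contrast import group_distance_contrast
from .devdeg import devdeg_test, pseudobulk_by_sample
from .mapping import UNASSIGNED, map_ages_iteratively
from .maturation import distance_trajectory
from .pseudotime import (delay_test, estimate_delay, fit_pseudotime_curve,
                         project_cells)
from .synthetic import (SexEffect, SyntheticSpec, generate_dataset,
                        trajectory_class_suite)

__all__ = [
    "trajectory_class_study",
    "group_contrast_null_study",
    "group_contrast_power_study",
    "delay_recovery_study",
    "core_gene_recovery_study",
    "devdeg_calibration_study",
    "devdeg_power_study",
    "label_recovery_study",
]


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def trajectory_class_study(seed: int = 0, n_per_class: int = 10,
                           cells_per_age: int = 300) -> dict:
    """Plant equal numbers of gradual/intermediate/stepwise cell types and
    measure the fraction whose maturation-distance class is recovered."""
    spec = trajectory_class_suite(n_per_class=n_per_class,
                                  cells_per_age=cells_per_age, seed=seed)
    adata, truth = generate_dataset(spec)
    correct = 0
    for ct, planted in zip(truth.cell_types["cell_type"],
                           truth.cell_types["maturation_class"]):
        sub = adata[adata.obs["cell_type"] == ct].copy()
        traj = distance_trajectory(sub, seed=seed)
        correct += int(traj.trajectory_class == planted)
    n = len(truth.cell_types)
    return {"recovery_pct": 100.0 * correct / n, "n": n}


def _homogeneous_spec(seed: int, sex_effect=(), n_genes: int = 1000) -> SyntheticSpec:
    """One cell type at two ages, 4 samples per sex, no constitutive
    sex-chromosome biases — the homogeneous background for calibration."""
    cats = {"mito": 0.005, "ribo": 0.01, "ieg": 0.005, "apoptotic": 0.005,
            "rbc": 0.002, "chrY": 0.0, "xinact": 0.0}
    return SyntheticSpec(
        n_cell_types=1, n_genes=n_genes, ages=("P10", "P65"),
        samples_per_sex_per_age=4, cells_per_type_per_sample=50,
        gene_category_fractions=cats, sex_effect=tuple(sex_effect), seed=seed)


def group_contrast_null_study(seed: int = 0, n_replicates: int = 200) -> dict:
    """Label-permuted null calibration of the inter/intra distance statistic:
    median effect size and the empirical type-I error rate at p < 0.05."""
    effects, pvals = [], []
    for s in _subseeds(seed, n_replicates):
        adata, _ = generate_dataset(_homogeneous_spec(s))
        sub = adata[adata.obs["age"] == "P10"].copy()
        rng = np.random.default_rng(s)
        samples = list(sub.obs["sample_id"].cat.categories)
        perm = rng.permutation(samples)
        grp = {smp: ("A" if i < len(samples) // 2 else "B")
               for i, smp in enumerate(perm)}
        sub.obs["grp"] = sub.obs["sample_id"].map(grp).astype("category")
        c = group_distance_contrast(sub, "grp", seed=0)
        effects.append(c.effect_size)
        pvals.append(c.p_value)
    return {
        "median_effect_size": float(np.median(effects)),
        "type_i_rate": float(np.mean(np.asarray(pvals) < 0.05)),
        "n": n_replicates,
    }


def group_contrast_power_study(seed: int = 0, n_replicates: int = 25,
                               n_shift_genes: int = 300,
                               log_fc: float = 0.5) -> dict:
    """Detection rate (p < 0.05) of a planted expression shift in one group
    (``n_shift_genes`` genes shifted by ``log_fc`` natural-log units)."""
    detected, effects = [], []
    for s in _subseeds(seed, n_replicates):
        genes = tuple(f"g{i:05d}" for i in range(n_shift_genes))
        fx = SexEffect("ct00", genes, log_fc, ("P10",))
        adata, _ = generate_dataset(_homogeneous_spec(s, sex_effect=(fx,)))
        sub = adata[adata.obs["age"] == "P10"].copy()
        c = group_distance_contrast(sub, "sex", seed=0)
        detected.append(c.p_value < 0.05)
        effects.append(c.effect_size)
    return {
        "detection_pct": 100.0 * float(np.mean(detected)),
        "median_effect_size": float(np.median(effects)),
        "n": n_replicates,
    }


def delay_recovery_study(seed: int = 0, n_runs: int = 20, delay_stages: int = 1,
                         n_cell_types: int = 6) -> dict:
    """Recovery of a planted one-stage developmental delay via pseudotime.

    Per run: curves are fitted per cell type on reference control samples,
    held-out littermate-control and mutant cells are projected, the per-age
    delay t-test is applied, and the delay (in stages) is estimated.
    Reports how often the estimate equals the planted value, and how often
    the expected significance pattern holds (p < 0.01 at the intermediate
    ages P4/P10/P18, p >= 0.05 at the final age).
    """
    exact, mid_sig, final_ns = [], [], []
    for s in _subseeds(seed, n_runs):
        spec = SyntheticSpec(
            n_cell_types=n_cell_types, n_genes=1000,
            cells_per_type_per_sample=15, mutant_samples_per_sex_per_age=2,
            delay_stages=delay_stages, seed=s)
        adata, _ = generate_dataset(spec)
        is_ref = adata.obs["sample_id"].astype(str).str.endswith("ctl0").to_numpy()
        is_ctl = (adata.obs["genotype"] == "control").to_numpy()
        rows = []
        for ct in adata.obs["cell_type"].cat.categories:
            in_ct = (adata.obs["cell_type"] == ct).to_numpy()
            curve = fit_pseudotime_curve(adata[in_ct & is_ref].copy(), seed=s)
            for geno, mask in (("control", in_ct & is_ctl & ~is_ref),
                               ("mutant", in_ct & ~is_ctl)):
                sub = adata[mask].copy()
                pt = project_cells(curve, sub)
                rows.append(pd.DataFrame({
                    "cell_type": ct, "genotype": geno,
                    "age": sub.obs["age"].to_numpy(), "pseudotime": pt.to_numpy()}))
        df = pd.concat(rows, ignore_index=True)
        df["age"] = pd.Categorical(df["age"], categories=list(spec.ages),
                                   ordered=True)
        res = delay_test(df).set_index("age")
        exact.append(estimate_delay(df) == delay_stages)
        mid_sig.append(bool((res.loc[["P4", "P10", "P18"], "p_value"] < 0.01).all()))
        final_ns.append(bool(res.loc["P65", "p_value"] >= 0.05))
    return {
        "delay_exact_pct": 100.0 * float(np.mean(exact)),
        "mid_age_significant_pct": 100.0 * float(np.mean(mid_sig)),
        "final_age_ns_pct": 100.0 * float(np.mean(final_ns)),
        "n": n_runs,
    }


def core_gene_recovery_study(seed: int = 0) -> dict:
    """Precision/recall of the core maturation gene derivation against the
    planted globally increasing genes.

    The truth set holds gradual-up genes and step genes whose step falls
    after the pooled young reference stages (a step between E16 and E18
    rises *within* the young pool, so such genes are not "increasing from
    young to adult" by construction).
    """
    from .pseudotime import identify_core_maturation_genes

    spec = SyntheticSpec(n_cell_types=8, n_genes=1500,
                         cells_per_type_per_sample=20, seed=seed)
    adata, truth = generate_dataset(spec)
    core = identify_core_maturation_genes(adata, seed=seed)
    found = set(core.genes)
    g = truth.genes
    planted = set(g.loc[(g["trend_class"] == "gradual-up")
                        | ((g["trend_class"] == "step") & (g["stage"] >= 2)),
                        "gene_id"])
    tp = len(found & planted)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(planted) if planted else 0.0
    return {"precision": precision, "recall": recall,
            "n_found": len(found), "n_planted": len(planted)}


def devdeg_calibration_study(seed: int = 0, n_simulations: int = 50) -> dict:
    """False discovery under a complete null: fraction of trend-free
    simulations yielding any devDEG at FDR < 0.05 (estimates the FDR, since
    every discovery under the null is false)."""
    any_hit = []
    for s in _subseeds(seed, n_simulations):
        spec = SyntheticSpec(n_cell_types=1, n_genes=1000,
                             cells_per_type_per_sample=20,
                             trend_gene_fraction=0.0, seed=s)
        adata, _ = generate_dataset(spec)
        pb = pseudobulk_by_sample(adata)
        ages = (adata.obs[["sample_id", "age"]].drop_duplicates()
                .set_index("sample_id")["age"].astype(str))
        res = devdeg_test(pb, ages.loc[pb.index])
        any_hit.append(bool((res["fdr"] < 0.05).any()))
    return {"null_fdr": float(np.mean(any_hit)), "n": n_simulations}


def devdeg_power_study(seed: int = 0, n_simulations: int = 10,
                       fold: float = 4.0) -> dict:
    """Recall of planted monotone (gradual) trend genes of the given fold
    change at FDR < 0.05, with 4 samples per age."""
    recalls = []
    for s in _subseeds(seed, n_simulations):
        spec = SyntheticSpec(
            n_cell_types=1, n_genes=1000, cells_per_type_per_sample=20,
            trend_gene_fraction=0.3, trend_amplitude=float(np.log(fold)),
            trend_shape_weights={"gradual-up": 0.5, "gradual-down": 0.5},
            seed=s)
        adata, truth = generate_dataset(spec)
        pb = pseudobulk_by_sample(adata)
        ages = (adata.obs[["sample_id", "age"]].drop_duplicates()
                .set_index("sample_id")["age"].astype(str))
        res = devdeg_test(pb, ages.loc[pb.index]).set_index("gene")
        planted = truth.genes.loc[truth.genes["trend_class"] != "flat", "gene_id"]
        recalls.append(float((res.loc[planted, "fdr"] < 0.05).mean()))
    return {"recall": float(np.mean(recalls)), "n": n_simulations}


def label_recovery_study(seed: int = 0) -> dict:
    """Iterative age mapping on default-marker synthetic data: minimum
    per-age assignment rate and label accuracy against ground truth."""
    spec = SyntheticSpec(n_cell_types=6, n_genes=1000,
                         cells_per_type_per_sample=20, seed=seed)
    adata, _ = generate_dataset(spec)
    labels, _, rates = map_ages_iteratively(adata, seed=seed)
    truth = adata.obs["cell_type"].astype(str)
    assigned = labels != UNASSIGNED
    accuracy = float((labels[assigned] == truth[assigned]).mean())
    return {
        "min_assignment_rate_pct": 100.0 * float(rates.min()),
        "label_accuracy_pct": 100.0 * accuracy,
        "n": int(adata.n_obs),
    }
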