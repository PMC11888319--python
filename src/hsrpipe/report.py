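"""Graded-response analytics and pipeline orchestration.

Covers the post-quantification summaries: PCA of expression profiles,
k-means with elbow-based model selection on condition fold changes,
hierarchical clustering of samples on a 1 - Spearman-correlation distance,
growth-curve integration into relative fitness, and an all-synthetic demo
pipeline that exercises every stage end to end under one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import __version__, epistasis, expr, foci as foci_mod, synth, threec

__all__ = [
    "ClusteringResult",
    "FitnessResult",
    "pca_embed",
    "kmeans_elbow",
    "hclust_spearman",
    "growth_auc",
    "relative_fitness",
    "run_pipeline",
]

# Minimum relative drop in within-cluster SS from k=1 to k=2 for the data to
# count as clustered at all; below it the elbow search returns k=1.
ELBOW_MIN_FIRST_DROP = 0.25


@dataclass
class ClusteringResult:
    k_selected: int
    assignments: dict
    within_ss_by_k: list
    linkage: np.ndarray | None = None
    dropped: list = field(default_factory=list)


@dataclass
class FitnessResult:
    genotype: str
    auc: float
    relative_fitness: float


def pca_embed(matrix: pd.DataFrame, n_components: int = 2,
              log_transform: bool = True, center: bool = True):
    """PCA of a samples x genes matrix.

    Input is log2(x+1)-transformed and gene-centered by default (the usual
    treatment of normalized expression).  Returns (scores DataFrame,
    explained-variance fractions).  A constant matrix is degenerate and
    raises.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if log_transform:
        if np.any(X < 0):
            raise ValueError("log transform requires nonnegative values")
        X = np.log2(X + 1.0)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("matrix is constant; PCA undefined")
    n_components = min(n_components, min(X.shape) - (1 if center else 0))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=matrix.index, columns=cols),
            pca.explained_variance_ratio_.copy())


def _within_ss(X: np.ndarray, k: int, seed: int) -> tuple[float, np.ndarray]:
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        return float(((X - centroid) ** 2).sum()), np.zeros(len(X), dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return float(km.inertia_), labels


def kmeans_elbow(matrix: pd.DataFrame, k_max: int = 6,
                 seed: int = 0) -> ClusteringResult:
    """k-means over k = 1..k_max with elbow-based selection.

    The elbow is the k maximizing the second difference of log W(k), the
    log within-cluster sum of squares; working on relative drops makes the
    selection invariant to the overall data scale and robust to elongated
    cluster geometries, where the raw-SS curvature peaks one k too early.
    When even the first drop (W1 - W2)/W1 is below ``ELBOW_MIN_FIRST_DROP``
    the data are treated as a single cluster (a second-difference rule
    cannot express k = 1 on its own).
    """
    X = matrix.to_numpy(dtype=float)
    if k_max >= len(X):
        raise ValueError("k_max must be smaller than the number of items")
    within, labels_by_k = [], {}
    for k in range(1, k_max + 1):
        w, labels = _within_ss(X, k, seed)
        within.append(w)
        labels_by_k[k] = labels
    within_arr = np.array(within)
    if within_arr[0] == 0 or (within_arr[0] - within_arr[1]) / within_arr[0] < ELBOW_MIN_FIRST_DROP:
        k_selected = 1
    elif k_max < 3:
        k_selected = 2
    else:
        # floor at a relative epsilon: W = 0 (perfect clustering) has no log
        log_w = np.log(np.maximum(within_arr, 1e-12 * within_arr[0]))
        second_diff = log_w[:-2] - 2 * log_w[1:-1] + log_w[2:]
        k_selected = int(np.argmax(second_diff)) + 2  # interior k = 2..k_max-1
    assignments = {
        item: int(lab)
        for item, lab in zip(matrix.index, labels_by_k[k_selected])
    }
    return ClusteringResult(k_selected=k_selected, assignments=assignments,
                            within_ss_by_k=[float(w) for w in within_arr])


def hclust_spearman(matrix: pd.DataFrame, method: str = "average") -> ClusteringResult:
    """Hierarchical clustering of samples (rows) on 1 - Spearman rho.

    Rank ties are resolved by average rank (spearmanr's convention).
    Constant rows have undefined rho; they are dropped and reported in
    ``dropped``.
    """
    X = matrix.to_numpy(dtype=float)
    keep = [i for i in range(len(X)) if np.ptp(X[i]) > 0]
    dropped = [matrix.index[i] for i in range(len(X)) if i not in keep]
    if len(keep) < 2:
        raise ValueError("need at least two non-constant samples")
    sub = X[keep]
    rho = spearmanr(sub, axis=1).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses 2 samples to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    leaves = hierarchy.leaves_list(Z)
    assignments = {matrix.index[keep[i]]: int(pos)
                   for pos, i in enumerate(leaves)}
    return ClusteringResult(k_selected=len(keep), assignments=assignments,
                            within_ss_by_k=[], linkage=Z, dropped=dropped)


def growth_auc(time_h, od600) -> float:
    """Integrated growth: trapezoidal area of OD minus the initial OD.

    Baseline subtraction makes the integral insensitive to inoculum density
    and sensitive to lag-phase length.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing with >= 2 points")
    return float(np.trapezoid(od - od[0], t))


def relative_fitness(curves: pd.DataFrame, wt_genotype: str = "WT") -> list:
    """Per-genotype AUC (replicate-averaged) and fitness relative to WT."""
    aucs = {}
    for (genotype, _rep), grp in curves.groupby(["genotype", "replicate"]):
        grp = grp.sort_values("time_h")
        aucs.setdefault(genotype, []).append(
            growth_auc(grp["time_h"], grp["od600"]))
    if wt_genotype not in aucs:
        raise KeyError(f"WT genotype {wt_genotype!r} absent from curves")
    mean_auc = {g: float(np.mean(v)) for g, v in aucs.items()}
    wt = mean_auc[wt_genotype]
    return [
        FitnessResult(genotype=g, auc=a,
                      relative_fitness=a / wt if wt != 0 else float("inf"))
        for g, a in sorted(mean_auc.items())
    ]


# ---------------------------------------------------------------------------
# demo pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "threec": {
        "interaction_freqs": {"HSP104-SSA2": 0.5, "HSP12-SSA4": 1.2},
        "digestion_effs": {"site1": 0.85, "site2": 0.9},
    },
    "rtqpcr": {
        "rel_expression": {
            "SSA4": {"NHS": 1.0, "HS": 40.0},
            "HSP104": {"NHS": 1.0, "HS": 25.0},
        },
        "reference_condition": "NHS",
    },
    "epistasis": {
        "n_genes": 42, "lfc_m1": 1.0, "lfc_m2": 2.0,
        "interaction_gamma": 0.0, "cv": 0.1, "n_reps": 2,
    },
    "foci": {"n_stacks": 12, "max_foci": 4},
    "growth": {
        "genotypes": {
            "WT": {"rate": 0.35}, "mutA": {"rate": 0.25}, "mutB": {"rate": 0.15},
        },
        "noise_sd": 0.01,
    },
}


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config=None, outdir="pipeline_out") -> dict:
    """Run the all-synthetic demo pipeline: simulate -> quantify (3C,
    RT-qPCR) -> epistasis -> foci -> clustering/fitness report.

    ``config`` may be a dict, a YAML/JSON file path, or None for the
    packaged demo configuration.  Writes TSV/JSON outputs plus a manifest
    into ``outdir``; deterministic (byte-identical reruns) under a fixed
    seed.  Returns the manifest.
    """
    if config is None:
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = json.loads(json.dumps(config))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg.get("seed", 0))
    rng = np.random.default_rng(master)
    seeds = {name: int(rng.integers(2 ** 31))
             for name in ("threec", "rtqpcr", "epistasis", "foci", "growth")}
    manifest = {"version": __version__, "seed": master, "stage_seeds": seeds,
                "outputs": {}}

    @_stage("threec")
    def stage_threec():
        c = cfg["threec"]
        table = synth.gen_3c_ct_table(
            synth.QpcrTruth(seed=seeds["threec"]),
            interaction_freqs=c["interaction_freqs"],
            digestion_effs=c["digestion_effs"])
        table.to_csv(out / "threec_ct_table.csv", index=False)
        results, qc = threec.quantify_ct_table(table)
        threec.write_results(results, qc, out / "threec_interactions.tsv",
                             out / "threec_qc.json")
        manifest["outputs"]["threec"] = ["threec_ct_table.csv",
                                         "threec_interactions.tsv",
                                         "threec_qc.json"]

    @_stage("rtqpcr")
    def stage_rtqpcr():
        c = cfg["rtqpcr"]
        table = synth.gen_rtqpcr_ct_table(
            synth.QpcrTruth(seed=seeds["rtqpcr"]),
            rel_expression=c["rel_expression"])
        table.to_csv(out / "rtqpcr_ct_table.csv", index=False)
        rel = expr.quantify_rtqpcr_table(
            table, reference_condition=c["reference_condition"])
        rel.to_csv(out / "rtqpcr_fold_changes.tsv", sep="\t", index=False)
        manifest["outputs"]["rtqpcr"] = ["rtqpcr_ct_table.csv",
                                         "rtqpcr_fold_changes.tsv"]

    @_stage("epistasis")
    def stage_epistasis():
        c = cfg["epistasis"]
        spec = synth.GenotypeEffectSpec(
            n_genes=c["n_genes"], lfc_m1=c["lfc_m1"], lfc_m2=c["lfc_m2"],
            interaction_gamma=c["interaction_gamma"], cv=c["cv"],
            n_reps=c["n_reps"], seed=seeds["epistasis"])
        matrix, meta, _truth = synth.gen_expression_matrix(spec)
        matrix.to_csv(out / "expression_matrix.tsv", sep="\t")
        meta.to_csv(out / "expression_metadata.tsv", sep="\t", index=False)
        result = epistasis.double_mutant_cycle(matrix, meta)
        result.per_gene.rename_axis("gene").to_csv(
            out / "epistasis_per_gene.tsv", sep="\t")
        summary = {
            "test_statistic": result.test_statistic,
            "p_value": result.p_value, "n_genes": result.n_genes,
            "verdict": result.verdict, "mean_epsilon": result.mean_epsilon,
        }
        (out / "epistasis_summary.json").write_text(
            json.dumps(summary, indent=2))
        manifest["outputs"]["epistasis"] = [
            "expression_matrix.tsv", "expression_metadata.tsv",
            "epistasis_per_gene.tsv", "epistasis_summary.json"]

    @_stage("foci")
    def stage_foci():
        c = cfg["foci"]
        frng = np.random.default_rng(seeds["foci"])
        params = foci_mod.FociParams()
        rows, by_cell = [], {}
        for i in range(c["n_stacks"]):
            k = int(frng.integers(0, c["max_foci"] + 1))
            if k == 0:
                truth = synth.ImageTruth(seed=int(frng.integers(2 ** 31)))
            else:
                truth = synth.sample_image_truth(frng, k)
            stack, _sidecar = synth.gen_image_stack(truth)
            mask = (truth.nucleus_mask if truth.nucleus_mask is not None
                    else synth.default_nucleus_mask(truth.shape_zyx))
            detected = foci_mod.detect_foci(stack, mask, params,
                                            cell_id=f"cell{i + 1:02d}")
            by_cell[f"cell{i + 1:02d}"] = detected
            for f in detected:
                rows.append({
                    "cell": f.cell_id, "channel": f.channel,
                    "z": f.centroid_zyx[0], "y": f.centroid_zyx[1],
                    "x": f.centroid_zyx[2], "peak": f.peak_intensity,
                    "size": f.size,
                })
        pd.DataFrame(rows, columns=["cell", "channel", "z", "y", "x",
                                    "peak", "size"]).to_csv(
            out / "foci_table.tsv", sep="\t", index=False)
        stats = foci_mod.cell_foci_stats(by_cell)
        (out / "foci_stats.json").write_text(json.dumps({
            "n_cells": stats.n_cells,
            "mean_foci_per_cell": stats.mean_foci_per_cell,
            "pct_cells_gt2": stats.pct_cells_gt_threshold,
        }, indent=2))
        manifest["outputs"]["foci"] = ["foci_table.tsv", "foci_stats.json"]

    @_stage("report")
    def stage_report():
        c = cfg["growth"]
        truths = {
            g: synth.GrowthTruth(noise_sd=c.get("noise_sd", 0.0), **params)
            for g, params in c["genotypes"].items()
        }
        curves = synth.gen_growth_curves(truths, seed=seeds["growth"])
        curves.to_csv(out / "growth_curves.csv", index=False)
        fitness = relative_fitness(curves)
        pd.DataFrame([vars(f) for f in fitness]).to_csv(
            out / "fitness.tsv", sep="\t", index=False)
        # graded-response clustering on the epistasis expression matrix
        matrix = pd.read_csv(out / "expression_matrix.tsv", sep="\t",
                             index_col=0)
        scores, evr = pca_embed(matrix.T)
        scores.to_csv(out / "pca_scores.tsv", sep="\t")
        clust = hclust_spearman(matrix.T)
        (out / "clustering.json").write_text(json.dumps({
            "pca_explained_variance": [float(v) for v in evr],
            "hclust_leaf_order": {str(k): v for k, v in clust.assignments.items()},
        }, indent=2))
        manifest["outputs"]["report"] = ["growth_curves.csv", "fitness.tsv",
                                         "pca_scores.tsv", "clustering.json"]

    stage_threec()
    stage_rtqpcr()
    stage_epistasis()
    stage_foci()
    stage_report()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
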