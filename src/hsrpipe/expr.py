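"""ddCt relative-expression quantification and fold-change matrices.

Relative transcript levels from RT-qPCR are computed with the ddCt method:
per condition, dCt = Ct(target) - Ct(normalizer); the fold change of a
condition relative to the reference condition is 2**-(dCt - dCt_ref).  The
normalizer is a transcript whose abundance is condition-independent (SCR1,
a Pol III transcript, in the heat-shock setting this package was built
for).  Technical-replicate Cts are averaged per biological replicate before
exponentiation; fold changes are then summarized as mean +/- SD across
biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelExpression",
    "delta_delta_ct",
    "quantify_rtqpcr_table",
    "fold_change_matrix",
    "basal_fold_vs_wt",
]

DEFAULT_NORMALIZER = "SCR1"


@dataclass
class RelExpression:
    """Fold change of one gene in one condition relative to the reference
    condition, with per-biological-replicate values."""

    gene: str
    condition: str
    value: float
    per_rep: list = field(default_factory=list)
    flags: list = field(default_factory=list)


def delta_delta_ct(
    ct_target: dict,
    ct_normalizer: dict,
    reference_condition: str,
    gene: str = "target",
) -> list:
    """ddCt fold changes across conditions for one gene.

    ``ct_target`` and ``ct_normalizer`` map condition -> Ct (scalar, already
    averaged over technical replicates).  Returns one
    :class:`RelExpression` per condition; the reference condition is 1.0 by
    construction.
    """
    missing = set(ct_target) - set(ct_normalizer)
    if missing:
        raise KeyError(f"normalizer Ct missing for conditions: {sorted(missing)}")
    if reference_condition not in ct_target:
        raise KeyError(f"reference condition {reference_condition!r} absent")
    dct = {c: ct_target[c] - ct_normalizer[c] for c in ct_target}
    ref = dct[reference_condition]
    return [
        RelExpression(gene=gene, condition=c, value=2.0 ** -(d - ref),
                      per_rep=[2.0 ** -(d - ref)])
        for c, d in dct.items()
    ]


def quantify_rtqpcr_table(
    ct_table: pd.DataFrame,
    reference_condition: str,
    normalizer: str = DEFAULT_NORMALIZER,
) -> pd.DataFrame:
    """ddCt quantification of a long-format RT-qPCR Ct table.

    Expects cDNA rows with columns primer_pair (gene), condition, bio_rep,
    tech_rep, ct.  Per biological replicate, technical Cts are averaged and
    dCt is taken against the normalizer; fold changes relative to the
    reference condition are reported per gene x condition as mean/SD over
    biological replicates.  For the reference condition itself the mean is
    flagged when it strays more than 20% from 1 (it is 1 by construction
    only when computed within-replicate).
    """
    cdna = ct_table[ct_table["template_class"] == "cDNA"]
    if normalizer not in set(cdna["primer_pair"]):
        raise KeyError(f"normalizer {normalizer!r} not present in Ct table")
    mean = cdna.groupby(["primer_pair", "condition", "bio_rep"],
                        as_index=False)["ct"].mean()
    norm = mean[mean["primer_pair"] == normalizer].set_index(
        ["condition", "bio_rep"])["ct"]
    rows = []
    for gene, gdf in mean[mean["primer_pair"] != normalizer].groupby("primer_pair"):
        dct = {}
        for row in gdf.itertuples():
            key = (row.condition, row.bio_rep)
            if key not in norm.index:
                raise KeyError(
                    f"normalizer Ct missing for condition {row.condition!r} "
                    f"bio_rep {row.bio_rep}")
            dct[key] = row.ct - norm[key]
        bio_reps = sorted({b for _, b in dct})
        conditions = sorted({c for c, _ in dct})
        if reference_condition not in conditions:
            raise KeyError(f"reference condition {reference_condition!r} absent")
        for cond in conditions:
            per_rep = [
                2.0 ** -(dct[(cond, b)] - dct[(reference_condition, b)])
                for b in bio_reps
                if (cond, b) in dct and (reference_condition, b) in dct
            ]
            value = float(np.mean(per_rep))
            flags = []
            if cond == reference_condition and abs(value - 1.0) > 0.2:
                flags.append("reference_mean_deviates")
            rows.append({
                "gene": gene, "condition": cond, "value": value,
                "sd": float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0,
                "n_bio_reps": len(per_rep),
                "flags": ";".join(flags),
                **{f"bio_rep_{b}": v for b, v in zip(bio_reps, per_rep)},
            })
    return pd.DataFrame(rows)


def _replicate_means(matrix: pd.DataFrame, metadata: pd.DataFrame,
                     genotype: str, condition: str) -> pd.Series:
    samples = metadata[(metadata["genotype"] == genotype)
                       & (metadata["condition"] == condition)]["sample"]
    if samples.empty:
        raise KeyError(f"no samples for genotype {genotype!r}, condition {condition!r}")
    return matrix[list(samples)].mean(axis=1)


def fold_change_matrix(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    numerator_cond: str,
    denominator_cond: str,
    log2: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Gene x genotype matrix of condition fold changes.

    For each genotype, the ratio of replicate-mean expression between the
    two conditions.  Genes whose denominator mean is zero in any genotype
    are excluded and returned as flags (they cannot enter downstream
    clustering).
    """
    if np.any(matrix.to_numpy() < 0):
        raise ValueError("expression matrix must be nonnegative")
    genotypes = list(dict.fromkeys(metadata["genotype"]))
    cols = {}
    bad: set = set()
    for genotype in genotypes:
        num = _replicate_means(matrix, metadata, genotype, numerator_cond)
        den = _replicate_means(matrix, metadata, genotype, denominator_cond)
        bad |= set(matrix.index[den == 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[genotype] = num / den
    out = pd.DataFrame(cols).drop(index=sorted(bad), errors="ignore")
    if log2:
        out = np.log2(out)
    return out, sorted(bad)


def basal_fold_vs_wt(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    wt_genotype: str = "WT",
    condition: str = "basal",
) -> tuple[pd.DataFrame, list]:
    """Gene x genotype matrix of expression relative to the WT mean under
    basal conditions.  Genes with zero WT mean are excluded and flagged."""
    wt = _replicate_means(matrix, metadata, wt_genotype, condition)
    bad = sorted(matrix.index[wt == 0])
    genotypes = list(dict.fromkeys(metadata["genotype"]))
    cols = {}
    for genotype in genotypes:
        vals = _replicate_means(matrix, metadata, genotype, condition)
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[genotype] = vals / wt
    out = pd.DataFrame(cols).drop(index=bad, errors="ignore")
    return out, bad
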