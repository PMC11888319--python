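"""Double-mutant-cycle epistasis on gene expression.

Two mutations act independently when their effects on expression combine
additively in log space: the expected log2 fold change of the double mutant
is the sum of the single-mutant log2 fold changes relative to wild type.
The per-gene deviation epsilon = observed - expected measures epistasis; a
two-tailed paired t-test across genes (genes as the pairing unit) asks
whether the observed double-mutant values are distinguishable from the
additive expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EpistasisResult",
    "log_fold_change",
    "expected_double",
    "epistasis_test",
    "double_mutant_cycle",
]


@dataclass
class EpistasisResult:
    per_gene: pd.DataFrame
    test_statistic: float
    p_value: float
    n_genes: int
    alpha: float
    verdict: str  # "independent" | "interdependent"
    mean_epsilon: float
    flags: list = field(default_factory=list)


def log_fold_change(mutant_expr, wt_expr, genes=None) -> pd.Series:
    """Per-gene log2(mutant / WT) from replicate-mean expression values.

    Genes with a nonpositive value in either genotype are excluded (returned
    series simply omits them); callers needing the flags can compare
    indices.
    """
    mutant = pd.Series(np.asarray(mutant_expr, dtype=float), index=genes)
    wt = pd.Series(np.asarray(wt_expr, dtype=float), index=mutant.index)
    ok = (mutant > 0) & (wt > 0)
    return np.log2(mutant[ok] / wt[ok])


def expected_double(lfc_m1: pd.Series, lfc_m2: pd.Series) -> pd.Series:
    """Additive (independent-action) expectation: elementwise sum."""
    lfc_m1, lfc_m2 = pd.Series(lfc_m1), pd.Series(lfc_m2)
    if not lfc_m1.index.equals(lfc_m2.index):
        raise ValueError("single-mutant fold changes are not aligned on genes")
    return lfc_m1 + lfc_m2


def epistasis_test(
    observed_double: pd.Series,
    expected_double: pd.Series,
    alpha: float = 0.05,
    lfc_m1: pd.Series | None = None,
    lfc_m2: pd.Series | None = None,
) -> EpistasisResult:
    """Paired t-test of observed vs expected double-mutant log fold changes.

    Verdict is "independent" when p >= alpha.  A zero-variance epsilon
    vector is degenerate for the t statistic: epsilon identically 0 returns
    p = 1 (perfect additivity), a constant nonzero epsilon returns p = 0,
    both flagged.
    """
    observed = pd.Series(observed_double)
    expected = pd.Series(expected_double)
    if not observed.index.equals(expected.index):
        raise ValueError("observed and expected are not aligned on genes")
    n = len(observed)
    if n < 3:
        raise ValueError(f"need >= 3 genes after filtering, got {n}")
    epsilon = observed - expected
    flags: list = []
    sd = float(np.std(epsilon, ddof=1))
    if sd == 0.0:
        mean = float(np.mean(epsilon))
        stat = 0.0 if mean == 0 else float("inf")
        p = 1.0 if mean == 0 else 0.0
        flags.append("zero_variance")
    else:
        stat, p = stats.ttest_rel(observed, expected)
        stat, p = float(stat), float(p)
    per_gene = pd.DataFrame({
        "lfc_double_observed": observed,
        "lfc_double_expected": expected,
        "epsilon": epsilon,
    })
    if lfc_m1 is not None:
        per_gene.insert(0, "lfc_m1", pd.Series(lfc_m1))
    if lfc_m2 is not None:
        per_gene.insert(1, "lfc_m2", pd.Series(lfc_m2))
    return EpistasisResult(
        per_gene=per_gene,
        test_statistic=stat,
        p_value=p,
        n_genes=n,
        alpha=alpha,
        verdict="independent" if p >= alpha else "interdependent",
        mean_epsilon=float(np.mean(epsilon)),
        flags=flags,
    )


def double_mutant_cycle(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    wt: str = "WT",
    m1: str = "m1",
    m2: str = "m2",
    double: str = "m1m2",
    condition: str = "basal",
    alpha: float = 0.05,
    scale: str = "log",
) -> EpistasisResult:
    """Full double-mutant cycle from an expression matrix + sample metadata.

    Replicates are collapsed to per-genotype means first; the paired test is
    run on log2 values by default (``scale="linear"`` compares linear
    expression instead, with the additive expectation still formed in log
    space and exponentiated).
    """
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")

    def means(genotype):
        samples = metadata[(metadata["genotype"] == genotype)
                           & (metadata["condition"] == condition)]["sample"]
        if samples.empty:
            raise KeyError(f"no samples for genotype {genotype!r}")
        return matrix[list(samples)].mean(axis=1)

    wt_mean = means(wt)
    lfc1 = log_fold_change(means(m1), wt_mean)
    lfc2 = log_fold_change(means(m2), wt_mean)
    lfc_double = log_fold_change(means(double), wt_mean)
    genes = lfc1.index.intersection(lfc2.index).intersection(lfc_double.index)
    lfc1, lfc2, lfc_double = lfc1[genes], lfc2[genes], lfc_double[genes]
    expected = expected_double(lfc1, lfc2)
    if scale == "linear":
        result = epistasis_test(2.0 ** lfc_double, 2.0 ** expected, alpha=alpha,
                                lfc_m1=lfc1, lfc_m2=lfc2)
    else:
        result = epistasis_test(lfc_double, expected, alpha=alpha,
                                lfc_m1=lfc1, lfc_m2=lfc2)
    return result
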