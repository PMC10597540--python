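"""Cluster-vs-rest differential expression.

Each feature of the scaled matrix is tested between the flagged cluster
and the remaining cohort with a two-sample t-test (pooled-variance
Student by default, Welch by flag), p-values are Benjamini-Hochberg
adjusted across features, and a shifted log2 fold change is attached:
because scaled values can be negative, every feature is first translated
so its minimum becomes a small positive floor before the ratio of group
means is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .hierarchy import ClusterAssignment


def two_sample_ttest(values_in, values_out, variant: str = "student") -> tuple[float, float]:
    """Two-sided t-test of two groups; ``variant`` selects pooled or Welch.

    A zero-variance comparison (all values identical) returns t=0, p=1.
    """
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    if not np.isfinite(p):
        return 0.0, 1.0
    return float(t), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def shifted_fold_change(values_in, values_out, epsilon: float = 0.001) -> float:
    """log2 ratio of group means after shifting the feature to positivity.

    All values of the feature (both groups jointly) are translated so the
    smallest becomes ``epsilon``; the log2 of the ratio of shifted group
    means is returned.
    """
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    shift = -min(a.min(), b.min()) + epsilon
    return float(np.log2((a.mean() + shift) / (b.mean() + shift)))


@dataclass
class DETable:
    """Per-feature statistics for one cluster-vs-rest comparison."""

    table: pd.DataFrame  # index: feature id; columns t, p, fdr, log2fc, mean_in, mean_out, direction
    cluster: int
    modality: str

    def significant(self, fdr_cut: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr_cut]

    def ranked_stats(self) -> pd.Series:
        """Features ranked by fold change (ties broken by id), for GSEA."""
        t = self.table.sort_values(
            ["log2fc"], ascending=False, kind="mergesort"
        )
        return t["log2fc"]


def differential_expression(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    cluster_label: int,
    variant: str = "student",
    epsilon: float = 0.001,
) -> DETable:
    """Per-feature t + BH + shifted log2 FC for one cluster vs the rest."""
    members = [s for s in matrix.sample_ids if assignment.labels.get(s) == cluster_label]
    others = [
        s for s in matrix.sample_ids
        if s in assignment.labels and assignment.labels[s] != cluster_label
    ]
    if len(members) < 2 or len(others) < 2:
        raise ValueError("cluster and remainder each need >= 2 samples with data")
    A = np.asarray(matrix.values[members], dtype=float)
    B = np.asarray(matrix.values[others], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=(variant == "student"))
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = bh_adjust(p)
    shift = -np.minimum(A.min(axis=1), B.min(axis=1)) + epsilon
    log2fc = np.log2((A.mean(axis=1) + shift) / (B.mean(axis=1) + shift))
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "fdr": fdr,
            "log2fc": log2fc,
            "mean_in": A.mean(axis=1),
            "mean_out": B.mean(axis=1),
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=matrix.values.index,
    ).sort_values("fdr", kind="mergesort")
    return DETable(table=table, cluster=cluster_label, modality=matrix.modality)
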