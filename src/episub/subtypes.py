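"""Outcome-guided subtype discovery.

A dendrogram built from expression profiles alone is cut at k = 2, 3, ...
clusters; at every cut each cluster is tested against the rest of the
cohort with a multiple logistic regression of seizure recurrence on
cluster membership, adjusted for sex, pathology, surgical side and
epilepsy duration. Benjamini-Hochberg correction is applied across the
clusters of a cut. The search stops at the first cut with an FDR-significant
cluster, then keeps splitting only while the minimum nominal p-value keeps
improving; across the distance x linkage grid the configuration whose best
cluster has the lowest FDR wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import PATHOLOGY_LEVELS, CohortMetadata, ExpressionMatrix
from .de import bh_adjust
from .hierarchy import (
    DEFAULT_GRID_METRICS,
    LINKAGES,
    METRICS,
    ClusterAssignment,
    Dendrogram,
    DistanceSpec,
    LinkageSpec,
    agglomerate,
    compute_distance,
    cut_dendrogram,
)

log = logging.getLogger(__name__)

#: |coefficient| beyond which a logistic fit is treated as separated.
SEPARATION_COEF = 15.0


@dataclass
class AssociationResult:
    cluster: int
    n_in: int
    n_recurrence_in: int
    coef: float
    wald_p: float
    fdr_p: float = np.nan
    converged: bool = True
    separation_flag: bool = False


@dataclass
class SubtypeCall:
    optimal_k: int
    assignment: ClusterAssignment
    results: list[AssociationResult]
    best_cluster: int
    best_fdr: float
    direction: str  # "risk" or "protective"
    distance: DistanceSpec | None = None
    linkage: LinkageSpec | None = None

    def flagged_members(self) -> list[str]:
        return self.assignment.members(self.best_cluster)

    def to_dict(self) -> dict:
        return {
            "config": {
                "metric": self.distance.metric if self.distance else None,
                "linkage": self.linkage.method if self.linkage else None,
            },
            "k": self.optimal_k,
            "clusters": [
                {
                    "label": r.cluster,
                    "n": r.n_in,
                    "n_recur": r.n_recurrence_in,
                    "wald_p": None if np.isnan(r.wald_p) else r.wald_p,
                    "fdr_p": None if np.isnan(r.fdr_p) else r.fdr_p,
                    "converged": r.converged,
                    "separation": r.separation_flag,
                }
                for r in self.results
            ],
            "best_cluster": self.best_cluster,
            "best_fdr": self.best_fdr,
            "direction": self.direction,
            "members": {str(s): int(l) for s, l in self.assignment.labels.items()},
        }


def _design_matrix(metadata: CohortMetadata, sample_ids: list[str], member: set[str]):
    tab = metadata.table.loc[sample_ids]
    cols = {"in_cluster": [1.0 if s in member else 0.0 for s in sample_ids]}
    cols["sex"] = tab["sex"].astype(float).to_numpy()
    for level in PATHOLOGY_LEVELS[1:]:  # hippocampal sclerosis is the reference
        if (tab["pathology"] == level).any():
            cols[f"pathology_{level}"] = (tab["pathology"] == level).astype(float).to_numpy()
    cols["surgical_side"] = tab["surgical_side"].astype(float).to_numpy()
    cols["epilepsy_duration"] = tab["epilepsy_duration"].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=sample_ids)
    # drop covariates that are constant in this subcohort (not identifiable)
    keep = ["in_cluster"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
    return sm.add_constant(X[keep], has_constant="add"), tab["outcome"].astype(float)


def cluster_outcome_association(
    assignment: ClusterAssignment,
    metadata: CohortMetadata,
    cluster_label: int,
    firth: bool = False,
) -> AssociationResult:
    """Covariate-adjusted logistic association of one cluster with recurrence.

    Returns the Wald two-sided p-value for the cluster-membership
    indicator. Fits whose fitted probabilities hit 0/1 (within 1e-8) or
    whose coefficients blow past +/-15 are flagged as separated and
    reported as produced, with ``converged=False``.
    """
    sample_ids = list(assignment.labels)
    member = set(assignment.members(cluster_label))
    if not member or len(member) == len(sample_ids):
        raise ValueError("cluster must have at least one sample inside and outside")
    y_all = metadata.outcomes(sample_ids)
    if y_all.nunique() < 2:
        raise ValueError("outcome is constant in the cohort; the model is degenerate")
    X, y = _design_matrix(metadata, sample_ids, member)

    if firth:
        coef, se, converged, fitted = _firth_logit(np.asarray(X, float), y.to_numpy())
        params = pd.Series(coef, index=X.columns)
        bse = pd.Series(se, index=X.columns)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            params, bse, fitted = res.params, res.bse, np.asarray(res.fittedvalues)
            converged = bool(res.converged)
        except Exception as exc:  # singular design etc.
            log.warning("logistic fit failed for cluster %s: %s", cluster_label, exc)
            n_in = len(member)
            n_rec = int(y_all[list(member)].sum())
            return AssociationResult(cluster_label, n_in, n_rec, np.nan, np.nan,
                                     converged=False, separation_flag=True)

    separated = bool(
        np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8)
        or np.any(np.abs(params.drop("const", errors="ignore")) > SEPARATION_COEF)
    )
    z = params["in_cluster"] / bse["in_cluster"]
    from scipy.stats import norm

    wald_p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return AssociationResult(
        cluster=cluster_label,
        n_in=len(member),
        n_recurrence_in=int(y_all[list(member)].sum()),
        coef=float(params["in_cluster"]),
        wald_p=wald_p,
        converged=converged and not separated,
        separation_flag=separated,
    )


def _firth_logit(X: np.ndarray, y: np.ndarray, maxiter: int = 50, tol: float = 1e-8):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X * w[:, None] ** 0.5, info_inv, X * w[:, None] ** 0.5)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1 - mu)
    info = (X.T * w) @ X
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se, converged, mu


def split_and_test(
    dendro: Dendrogram,
    metadata: CohortMetadata,
    k: int,
    firth: bool = False,
) -> list[AssociationResult]:
    """Test every cluster at cut k against the rest; BH-adjust within the cut."""
    assignment = cut_dendrogram(dendro, k)
    results = [
        cluster_outcome_association(assignment, metadata, label, firth=firth)
        for label in range(1, k + 1)
    ]
    pvals = np.array([r.wald_p for r in results], dtype=float)
    adj = bh_adjust(np.where(np.isnan(pvals), 1.0, pvals))
    for r, a in zip(results, adj):
        r.fdr_p = float(a)
    return results


def _min_nominal(results: list[AssociationResult]) -> float:
    ps = [r.wald_p for r in results if np.isfinite(r.wald_p)]
    return min(ps) if ps else 1.0


def _min_fdr(results: list[AssociationResult]) -> float:
    ps = [r.fdr_p for r in results if np.isfinite(r.fdr_p)]
    return min(ps) if ps else 1.0


def find_optimal_clusters(
    dendro: Dendrogram,
    metadata: CohortMetadata,
    max_k: int = 10,
    fdr_threshold: float = 0.2,
    firth: bool = False,
    tester=None,
) -> SubtypeCall | None:
    """Two-phase search for the optimal cluster count.

    Phase 1 raises k from 2 until some cluster clears the exploratory FDR
    threshold (returning ``None`` if none does by ``max_k``). Phase 2 keeps
    splitting while the minimum nominal p-value over clusters still
    improves, and stops at the cut just before it degrades.

    ``tester(k)`` may be supplied to replace the default cluster-vs-rest
    association (used by unit tests to trace the stopping rule).
    """
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    max_k = min(max_k, dendro.n_leaves)
    test = tester if tester is not None else (
        lambda k: split_and_test(dendro, metadata, k, firth=firth)
    )

    results_at: dict[int, list[AssociationResult]] = {}
    k_sig = None
    for k in range(2, max_k + 1):
        results_at[k] = test(k)
        if _min_fdr(results_at[k]) < fdr_threshold:
            k_sig = k
            break
    if k_sig is None:
        return None

    k = k_sig
    while k < max_k:
        nxt = test(k + 1)
        results_at[k + 1] = nxt
        if _min_nominal(nxt) < _min_nominal(results_at[k]):
            k += 1
        else:
            break

    results = results_at[k]
    fdrs = [r.fdr_p if np.isfinite(r.fdr_p) else np.inf for r in results]
    best_idx = int(np.argmin(fdrs))
    best = results[best_idx]
    assignment = cut_dendrogram(dendro, k)
    y = metadata.outcomes(list(assignment.labels))
    inside = y[assignment.members(best.cluster)]
    outside = y.drop(inside.index)
    direction = "risk" if inside.mean() > outside.mean() else "protective"
    return SubtypeCall(
        optimal_k=k,
        assignment=assignment,
        results=results,
        best_cluster=best.cluster,
        best_fdr=float(best.fdr_p),
        direction=direction,
    )


def subtype_grid(
    matrix: ExpressionMatrix,
    metadata: CohortMetadata,
    metrics: tuple[str, ...] = DEFAULT_GRID_METRICS,
    linkages: tuple[str, ...] = LINKAGES,
    max_k: int = 10,
    fdr_threshold: float = 0.2,
    minkowski_power: float = 2.0,
    firth: bool = False,
) -> list[SubtypeCall]:
    """Run the optimal-k search for every metric x linkage combination."""
    calls: list[SubtypeCall] = []
    for metric in metrics:
        dspec = DistanceSpec(metric, minkowski_power=minkowski_power)
        dist = compute_distance(matrix, dspec)
        for method in linkages:
            lspec = LinkageSpec(method)
            dendro = agglomerate(dist, lspec)
            call = find_optimal_clusters(
                dendro, metadata, max_k=max_k, fdr_threshold=fdr_threshold, firth=firth
            )
            if call is not None:
                call.distance = dspec
                call.linkage = lspec
                calls.append(call)
    return calls


def _grid_rank(call: SubtypeCall) -> tuple[int, int]:
    m = METRICS.index(call.distance.metric) if call.distance else len(METRICS)
    l = LINKAGES.index(call.linkage.method) if call.linkage else len(LINKAGES)
    return m, l


def select_best_approach(calls: list[SubtypeCall]) -> SubtypeCall:
    """Pick the call whose best cluster has the lowest FDR.

    Ties fall to the smaller optimal k, then to grid order
    (metric-major, linkage-minor).
    """
    if not calls:
        raise ValueError("no subtype calls to select from")
    return min(calls, key=lambda c: (c.best_fdr, c.optimal_k, _grid_rank(c)))
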