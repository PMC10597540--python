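"""Custom gene sets and preranked gene-set enrichment.

Signatures built from one modality's differential expression (e.g. the
miRNAs down in a blood cluster, or the genes up/down in a blood mRNA
cluster) are tested for concentration at the top or bottom of another
modality's fold-change-ranked feature list with the weighted running-sum
(Kolmogorov-Smirnov-style) enrichment statistic, against a gene-label
permutation null. A plain hypergeometric over-representation test against
arbitrary annotation collections is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import DETable, bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    members: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_p: float
    leading_edge: list[str]
    n_perm: int
    seed: int


def build_custom_sets(
    de: DETable, fdr_cut: float = 0.05, prefix: str | None = None
) -> list[GeneSet]:
    """One signature per direction from the FDR-significant DE features."""
    if de.table.empty:
        raise ValueError("DE table is empty")
    prefix = prefix if prefix is not None else f"cluster{de.cluster}_{de.modality}"
    sig = de.significant(fdr_cut)
    sets = []
    for direction, tag in (("up", "UP"), ("down", "DOWN")):
        members = list(sig.index[sig["direction"] == direction])
        if members:
            sets.append(
                GeneSet(
                    name=f"{prefix}_{tag}",
                    members=members,
                    provenance=f"cluster {de.cluster} {de.modality} {direction}, FDR<{fdr_cut}",
                )
            )
        else:
            log.warning("no %s-regulated features at FDR<%s; set omitted", direction, fdr_cut)
    return sets


def _ranked(ranked_stats: pd.Series) -> pd.Series:
    # descending stat, ties broken by feature id for determinism
    s = ranked_stats.loc[sorted(ranked_stats.index)]
    return s.sort_values(ascending=False, kind="mergesort")


def enrichment_score(
    ranked_stats: pd.Series,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score of a set in a ranked list.

    Walking the list in rank order, hits add |stat|^w normalised by the
    total hit weight and misses subtract 1/(N - |set|); the score is the
    running sum's largest excursion from zero, sign retained.
    """
    ranks = _ranked(ranked_stats)
    members = set(gene_set.members) & set(ranks.index)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} shares no feature with the ranked list")
    N = len(ranks)
    if len(members) >= N:
        raise ValueError("gene set must be a strict subset of the ranked universe")
    is_hit = np.array([g in members for g in ranks.index])
    w = np.abs(ranks.to_numpy()) ** weight_exponent
    hit_total = w[is_hit].sum()
    if hit_total == 0:
        raise ValueError("all member statistics are zero; hit weights undefined")
    steps = np.where(is_hit, w / hit_total, -1.0 / (N - len(members)))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _leading_edge(ranks: pd.Series, members: set, running: np.ndarray, es: float) -> list[str]:
    genes = list(ranks.index)
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        return [g for g in genes[: peak + 1] if g in members]
    return [g for g in genes[peak:] if g in members]


def preranked_gsea(
    ranked_stats: pd.Series,
    sets: list[GeneSet],
    n_perm: int = 10000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Permutation GSEA: the null resamples random gene sets of equal size.

    The nominal p-value is the fraction of same-sign null scores at least
    as extreme as the observed one (floored at 1/n_perm); NES divides the
    score by the mean magnitude of the same-sign null scores;
    Benjamini-Hochberg runs across the supplied sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranks = _ranked(ranked_stats)
    rng = np.random.default_rng(seed)
    w_all = np.abs(ranks.to_numpy()) ** weight_exponent
    N = len(ranks)
    results = []
    for gs in sets:
        es, running = enrichment_score(ranks, gs, weight_exponent)
        m = len(set(gs.members) & set(ranks.index))
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(N, size=m, replace=False)
            hit_total = w_all[idx].sum()
            if hit_total == 0:
                null[i] = 0.0
                continue
            steps = np.full(N, -1.0 / (N - m))
            steps[idx] = w_all[idx] / hit_total
            run = np.cumsum(steps)
            null[i] = run[np.argmax(np.abs(run))]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            p = 1.0 / n_perm
            nes = np.nan
        else:
            exceed = int(np.sum(np.abs(same_sign) >= abs(es)))
            p = max(exceed / same_sign.size, 1.0 / n_perm)
            nes = es / np.mean(np.abs(same_sign))
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                es=es,
                nes=float(nes),
                nominal_p=float(p),
                fdr_p=np.nan,
                leading_edge=_leading_edge(ranks, set(gs.members), running, es),
                n_perm=n_perm,
                seed=seed,
            )
        )
    adj = bh_adjust([r.nominal_p for r in results])
    for r, a in zip(results, adj):
        r.fdr_p = float(a)
    return results


def over_representation(
    query, annotations: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of a query set in each
    annotation, BH-adjusted across annotations."""
    U = set(universe)
    if not U:
        raise ValueError("empty universe")
    Q = set(query)
    if not Q <= U:
        raise ValueError("query set must be contained in the universe")
    rows = []
    for name, members in annotations.items():
        A = set(members)
        if not A <= U:
            raise ValueError(f"annotation {name!r} not contained in the universe")
        k = len(Q & A)
        p = float(stats.hypergeom.sf(k - 1, len(U), len(A), len(Q)))
        rows.append({"annotation": name, "n_overlap": k, "n_annotation": len(A), "p": p})
    out = pd.DataFrame(rows).set_index("annotation")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort")
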