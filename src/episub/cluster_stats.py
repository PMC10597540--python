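"""Bootstrap statistics on cluster outcome proportions and cross-modality
cluster overlap tests.

The recurrence proportion inside a flagged cluster gets a percentile
bootstrap confidence interval (1000 resamples by default). Whether two
clusters found in different modalities share more subjects than chance is
assessed with a hypergeometric upper-tail test (one-sided Fisher) over
the set of subjects measured in both modalities, and their overlap is
summarised as a Jaccard percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int
    distribution: np.ndarray | None = None

    def rounded_percent(self) -> tuple[int, int, int]:
        return (
            round(self.point * 100),
            round(self.lower * 100),
            round(self.upper * 100),
        )


@dataclass
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_intersection: int
    p_over: float
    overlap_percent: float

    @property
    def overlap_percent_display(self) -> int:
        return round(self.overlap_percent)


def bootstrap_proportion_ci(
    outcomes,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    keep_distribution: bool = False,
) -> BootstrapCI:
    """Percentile bootstrap CI for the proportion of 1s in a binary vector.

    Bounds are the empirical (1-level)/2 and 1-(1-level)/2 quantiles of the
    resampled proportions (linear-interpolation quantile definition).
    """
    y = np.asarray(outcomes, dtype=float)
    if y.size == 0:
        raise ValueError("outcomes must be nonempty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, y.size, size=(n_boot, y.size))
    props = y[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(props, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        point=float(y.mean()),
        lower=float(lower),
        upper=float(upper),
        n_boot=n_boot,
        seed=seed,
        distribution=props if keep_distribution else None,
    )


def bootstrap_difference_test(
    outcomes_in,
    outcomes_out,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, bool]:
    """t-test between the two bootstrap proportion distributions.

    Returns ``(p, defined)``. The test treats the ``n_boot`` resampled
    proportions of each group as samples, so its p-value shrinks with
    ``n_boot`` — it is anti-conservative by construction and reported as
    such. When either bootstrap distribution has zero variance the p-value
    is undefined and ``defined`` is False.
    """
    a = bootstrap_proportion_ci(outcomes_in, n_boot=n_boot, seed=seed,
                                keep_distribution=True).distribution
    b = bootstrap_proportion_ci(outcomes_out, n_boot=n_boot, seed=seed + 1,
                                keep_distribution=True).distribution
    if np.var(a) == 0 or np.var(b) == 0:
        return float("nan"), False
    _, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p), True


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Hypergeometric over-representation of the intersection of two sets.

    ``p_over`` is the upper-tail probability of drawing at least the
    observed intersection when |B| subjects are sampled without
    replacement from the universe containing |A| marked subjects —
    identical to a one-sided Fisher's exact test on the 2x2 table.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("both sets must be contained in the universe")
    n_int = len(A & B)
    n_union = len(A | B)
    p = float(stats.hypergeom.sf(n_int - 1, len(U), len(A), len(B)))
    pct = 100.0 * n_int / n_union if n_union else 0.0
    return OverlapResult(
        n_universe=len(U),
        n_a=len(A),
        n_b=len(B),
        n_intersection=n_int,
        p_over=p,
        overlap_percent=pct,
    )


def multiway_membership_table(flagged: dict[str, set], universe) -> pd.DataFrame:
    """Membership of each shared-universe subject in every flagged cluster.

    ``flagged`` maps a call name (e.g. a modality) to the member set of its
    flagged cluster. Returns a boolean table over the subjects present in
    the shared universe, with an ``n_memberships`` column; the attached
    ``counts`` attribute tallies how many subjects sit in all / exactly
    two / exactly one / zero flagged clusters.
    """
    U = sorted(universe)
    if not U:
        raise ValueError("empty shared universe")
    tab = pd.DataFrame(
        {name: [s in members for s in U] for name, members in flagged.items()},
        index=U,
    )
    tab["n_memberships"] = tab.sum(axis=1)
    n_calls = len(flagged)
    counts = {
        "all": int((tab["n_memberships"] == n_calls).sum()),
        "zero": int((tab["n_memberships"] == 0).sum()),
    }
    for m in range(1, n_calls):
        counts[f"exactly_{m}"] = int((tab["n_memberships"] == m).sum())
    tab.attrs["counts"] = counts
    return tab
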