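"""Upstream-regulator activation prediction from target expression.

Given a regulator->target network with expected regulation signs (a
miRNA is expected to repress its targets), the direction of each
regulator's differentially expressed targets votes for or against the
regulator being active: a repressed target observed DOWN is consistent
with an active regulator, a repressed target observed UP argues the
regulator is less active. The unweighted activation z-score is
(n_consistent - n_inconsistent) / sqrt(n_total); |z| >= 2 calls the
regulator activated or deactivated. Predictions are then cross-checked
against the regulator's own measured differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DETable

ACTIVATION_THRESHOLD = 2.0


@dataclass
class RegulatorScore:
    regulator: str
    n_targets_de: int
    n_consistent: int
    n_inconsistent: int
    overlap_p: float
    z: float
    predicted_state: str  # activated / deactivated / indeterminate

    @staticmethod
    def state_from_z(z: float, threshold: float = ACTIVATION_THRESHOLD) -> str:
        if z >= threshold:
            return "activated"
        if z <= -threshold:
            return "deactivated"
        return "indeterminate"


def activation_zscore(
    network: pd.DataFrame,
    de: DETable,
    regulator: str,
    fdr_cut: float = 0.05,
    threshold: float = ACTIVATION_THRESHOLD,
) -> RegulatorScore:
    """Score one regulator against the DE table of its targets' modality.

    Raises ``ValueError`` when the regulator has no DE-significant target,
    in which case no score is defined.
    """
    edges = network[network["regulator"] == regulator]
    if edges.empty:
        raise ValueError(f"regulator {regulator!r} absent from the network")
    measured = edges[edges["target"].isin(de.table.index)]
    sig = de.significant(fdr_cut)
    de_targets = measured[measured["target"].isin(sig.index)]
    if de_targets.empty:
        raise ValueError(
            f"regulator {regulator!r} has no differentially expressed target at FDR<{fdr_cut}"
        )
    observed_down = sig["direction"] == "down"
    n_cons = n_incons = 0
    for _, edge in de_targets.iterrows():
        down = bool(observed_down[edge["target"]])
        expects_down = edge["sign"] == "repression"  # target down iff regulator active
        if down == expects_down:
            n_cons += 1
        else:
            n_incons += 1
    total = n_cons + n_incons
    z = (n_cons - n_incons) / np.sqrt(total)
    # enrichment of DE features among this regulator's measured targets
    universe_n = len(de.table)
    overlap_p = float(
        stats.hypergeom.sf(len(de_targets) - 1, universe_n, len(sig), len(measured))
    )
    return RegulatorScore(
        regulator=regulator,
        n_targets_de=total,
        n_consistent=n_cons,
        n_inconsistent=n_incons,
        overlap_p=overlap_p,
        z=float(z),
        predicted_state=RegulatorScore.state_from_z(float(z), threshold),
    )


def score_all_regulators(
    network: pd.DataFrame,
    de: DETable,
    fdr_cut: float = 0.05,
    threshold: float = ACTIVATION_THRESHOLD,
) -> tuple[list[RegulatorScore], dict[str, str]]:
    """Score every network regulator; returns scores and skip reasons."""
    scores, skipped = [], {}
    for reg in sorted(network["regulator"].unique()):
        try:
            scores.append(activation_zscore(network, de, reg, fdr_cut, threshold))
        except ValueError as exc:
            skipped[reg] = str(exc)
    return scores, skipped


def concordance_table(
    scores: list[RegulatorScore],
    mirna_de: DETable,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Compare predicted regulator states with observed regulator DE.

    A prediction is concordant when a deactivated call meets an observed
    significant down-regulation of the regulator itself (or activated
    meets up). Regulators without a measured expression row, without a
    significant change, or with an indeterminate prediction are
    untestable. Summary counts live in ``table.attrs['counts']``.
    """
    rows = []
    for s in scores:
        measured = s.regulator in mirna_de.table.index
        obs_fc = float(mirna_de.table.loc[s.regulator, "log2fc"]) if measured else np.nan
        obs_fdr = float(mirna_de.table.loc[s.regulator, "fdr"]) if measured else np.nan
        if not measured or s.predicted_state == "indeterminate" or obs_fdr >= fdr_cut:
            concordant: bool | None = None
        else:
            concordant = (s.predicted_state == "deactivated" and obs_fc < 0) or (
                s.predicted_state == "activated" and obs_fc > 0
            )
        rows.append(
            {
                "regulator": s.regulator,
                "predicted_state": s.predicted_state,
                "overlap_p": s.overlap_p,
                "z": s.z,
                "observed_log2fc": obs_fc,
                "observed_fdr": obs_fdr,
                "concordant": concordant,
            }
        )
    out = pd.DataFrame(rows).set_index("regulator")
    out.attrs["counts"] = {
        "concordant": int(sum(r["concordant"] is True for r in rows)),
        "discordant": int(sum(r["concordant"] is False for r in rows)),
        "untestable": int(sum(r["concordant"] is None for r in rows)),
    }
    return out
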