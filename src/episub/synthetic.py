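"""Synthetic multimodal cohort generator with planted ground truth.

The generator emulates the statistical structure the subtyping analysis
assumes: a cohort of ~40 subjects measured in up to four modalities with
nested availability (every subject has blood miRNA; a subset adds blood
mRNA; a brain subset overlaps both so that a complete "all four assays"
core exists), per-batch additive offsets, and a planted subtype whose
members carry a coordinated signal — selected miRNAs shifted down and
their planted target genes shifted up — together with an enriched
post-surgical seizure-recurrence rate. The planted memberships, signal
features and regulator network are returned as ground truth for
parameter-recovery tests.

Expression is drawn as a heavy-tailed per-feature baseline (log-normal)
plus a per-batch normal offset and unit normal noise, so the planted
effect size is expressed in within-batch SD units. This is deliberately
simpler than RNA-seq count noise; see the methods note for what that
implies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    MODALITIES,
    PATHOLOGY_LEVELS,
    CohortMetadata,
    ExpressionMatrix,
    ParameterError,
)
from . import io as eio

#: Covariate frequencies of the study cohort the generator emulates.
COVARIATE_FREQS = {
    "female": 0.475,
    "dominant_side": 0.525,
    "pathology": {
        "hippocampal sclerosis": 0.55,
        "malformations of cortical development": 0.10,
        "no lesion": 0.20,
        "other": 0.15,
    },
    "duration_mean": 21.3,
    "duration_sd": 13.5,
}


@dataclass
class SimParams:
    """Generator parameters; defaults are the study-shaped conditions."""

    n_subjects: int = 40
    n_features: dict = field(
        default_factory=lambda: {
            "blood_mirna": 400,
            "blood_mrna": 2000,
            "brain_mirna": 400,
            "brain_mrna": 2000,
        }
    )
    n_batches: int = 2
    subtype_fraction: float = 0.575  # 23 of 40 subjects, the flagged-cluster size
    recurrence_rate_subtype: float = 0.8
    recurrence_rate_background: float = 0.4
    n_signal_features: dict = field(
        default_factory=lambda: {
            "blood_mirna": 100,
            "blood_mrna": 500,
            "brain_mirna": 100,
            "brain_mrna": 500,
        }
    )
    effect_size: float = 1.5
    coupling_fraction: float = 0.5
    network_density: float = 5.0
    decoy_density: float | None = None
    modality_missingness: dict = field(
        default_factory=lambda: {
            "blood_mirna": 0,
            "blood_mrna": 5,
            "brain_mirna": 8,
            "brain_mrna": 8,
        }
    )
    n_complete: int = 30
    batch_sd: float = 0.5
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subtype_fraction", "recurrence_rate_subtype", "recurrence_rate_background",
                     "coupling_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.n_subjects < 4:
            raise ParameterError("n_subjects must be >= 4")
        if round(self.subtype_fraction * self.n_subjects) < 2:
            raise ParameterError("subtype_fraction * n_subjects must be >= 2")
        if self.n_batches < 1:
            raise ParameterError("n_batches must be >= 1")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.network_density <= 0:
            raise ParameterError("network_density must be > 0")
        if self.decoy_density is not None and self.decoy_density < 0:
            raise ParameterError("decoy_density must be >= 0")
        for m in MODALITIES:
            if m not in self.n_features:
                raise ParameterError(f"n_features missing modality {m!r}")
            if self.n_signal_features.get(m, 0) > self.n_features[m]:
                raise ParameterError(f"n_signal_features[{m!r}] exceeds n_features")
            miss = self.modality_missingness.get(m, 0)
            if not 0 <= miss < self.n_subjects:
                raise ParameterError(f"modality_missingness[{m!r}] out of range")
        n_bm = self.n_subjects - self.modality_missingness.get("blood_mrna", 0)
        n_brain = self.n_subjects - self.modality_missingness.get("brain_mrna", 0)
        if self.n_complete > min(n_bm, n_brain):
            raise ParameterError("n_complete exceeds a modality subset size")
        if n_brain - self.n_complete > self.n_subjects - n_bm:
            raise ParameterError(
                "n_complete too small: brain subset cannot avoid the blood-mRNA set that much"
            )


@dataclass
class SimulationTruth:
    subtype_members: list[str]
    signal_features: dict[str, list[str]]
    outcomes: dict[str, int]
    planted_network: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {
            "subtype_members": self.subtype_members,
            "signal_features": self.signal_features,
            "outcomes": self.outcomes,
        }
        if self.planted_network is not None:
            payload["planted_network"] = self.planted_network.to_dict(orient="records")
        return json.dumps(payload, indent=2, sort_keys=True)


def _feature_ids(modality: str, n: int) -> list[str]:
    prefix = "mir" if "mirna" in modality else "GENE"
    return [f"{prefix}-{i:04d}" if prefix == "mir" else f"{prefix}{i:04d}" for i in range(n)]


def _availability(params: SimParams, sample_ids: list[str]) -> dict[str, list[str]]:
    n = params.n_subjects
    n_bmi = n - params.modality_missingness.get("blood_mirna", 0)
    n_bm = n - params.modality_missingness.get("blood_mrna", 0)
    avail = {
        "blood_mirna": sample_ids[:n_bmi],
        "blood_mrna": sample_ids[:n_bm],
    }
    for m in ("brain_mirna", "brain_mrna"):
        n_brain = n - params.modality_missingness.get(m, 0)
        inside = sample_ids[: min(params.n_complete, n_brain)]
        outside = sample_ids[n_bm : n_bm + (n_brain - len(inside))]
        avail[m] = inside + outside
    return avail


def simulate_cohort(params: SimParams):
    """Generate expression matrices, metadata and ground truth.

    Returns ``(matrices, metadata, truth)`` where ``matrices`` maps
    modality to :class:`ExpressionMatrix`. The same seed always yields an
    identical bundle.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    n_sub = round(params.subtype_fraction * n)
    members = sorted(rng.choice(sample_ids, size=n_sub, replace=False).tolist())
    member_set = set(members)

    rates = np.where(
        [s in member_set for s in sample_ids],
        params.recurrence_rate_subtype,
        params.recurrence_rate_background,
    )
    outcome = (rng.random(n) < rates).astype(int)

    sex = (rng.random(n) < COVARIATE_FREQS["female"]).astype(int)
    side = (rng.random(n) < COVARIATE_FREQS["dominant_side"]).astype(int)
    pathology = rng.choice(
        list(COVARIATE_FREQS["pathology"]),
        size=n,
        p=list(COVARIATE_FREQS["pathology"].values()),
    )
    duration = np.clip(
        rng.normal(COVARIATE_FREQS["duration_mean"], COVARIATE_FREQS["duration_sd"], n),
        1.0,
        None,
    ).round(1)
    batch = rng.permuted(np.arange(n) % params.n_batches)

    avail = _availability(params, sample_ids)
    meta_df = pd.DataFrame(
        {
            "outcome": outcome,
            "sex": sex,
            "pathology": pathology,
            "surgical_side": side,
            "epilepsy_duration": duration,
            "batch": [f"b{b + 1}" for b in batch],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for m in MODALITIES:
        meta_df[f"has_{m}"] = meta_df.index.isin(avail[m])
    metadata = CohortMetadata(meta_df)

    # planted signal features, with blood<->brain coupling on shared ids
    signal: dict[str, list[str]] = {}
    for blood_mod, brain_mod in (("blood_mirna", "brain_mirna"), ("blood_mrna", "brain_mrna")):
        universe = _feature_ids(blood_mod, params.n_features[blood_mod])
        k_blood = params.n_signal_features.get(blood_mod, 0)
        blood_sig = sorted(rng.choice(universe, size=k_blood, replace=False).tolist())
        signal[blood_mod] = blood_sig
        brain_universe = _feature_ids(brain_mod, params.n_features[brain_mod])
        k_brain = params.n_signal_features.get(brain_mod, 0)
        shared_pool = sorted(set(blood_sig) & set(brain_universe))
        k_shared = min(round(params.coupling_fraction * k_brain), len(shared_pool))
        shared = sorted(rng.choice(shared_pool, size=k_shared, replace=False).tolist())
        rest_pool = sorted(set(brain_universe) - set(blood_sig))
        own = sorted(
            rng.choice(rest_pool, size=min(k_brain - k_shared, len(rest_pool)),
                       replace=False).tolist()
        )
        signal[brain_mod] = sorted(shared + own)

    matrices: dict[str, ExpressionMatrix] = {}
    for m in MODALITIES:
        fids = _feature_ids(m, params.n_features[m])
        cols = avail[m]
        baseline = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd,
                                 size=params.n_features[m])
        batch_offsets = rng.normal(0.0, params.batch_sd,
                                   size=(params.n_features[m], params.n_batches))
        noise = rng.normal(0.0, 1.0, size=(params.n_features[m], len(cols)))
        col_batch = meta_df.loc[cols, "batch"].str.slice(1).astype(int).to_numpy() - 1
        vals = baseline[:, None] + batch_offsets[:, col_batch] + noise
        sign = -1.0 if "mirna" in m else 1.0  # miRNA signal down, mRNA targets up
        sig_idx = [fids.index(f) for f in signal[m]]
        in_sub = np.array([c in member_set for c in cols])
        if sig_idx and in_sub.any():
            vals[np.ix_(sig_idx, np.where(in_sub)[0])] += sign * params.effect_size
        unit = "cpm" if "mirna" in m else "tpm"
        matrices[m] = ExpressionMatrix(
            pd.DataFrame(vals, index=fids, columns=cols), modality=m, unit=unit
        )

    truth = SimulationTruth(
        subtype_members=members,
        signal_features=signal,
        outcomes={s: int(o) for s, o in zip(sample_ids, outcome)},
    )
    truth.planted_network = simulate_regulator_network(params, truth)
    return matrices, metadata, truth


def simulate_regulator_network(params: SimParams, truth: SimulationTruth) -> pd.DataFrame:
    """Regulator->target edge list: planted repression edges from signal
    miRNAs to signal genes, plus random-sign decoy edges among non-signal
    features."""
    rng = np.random.default_rng(params.seed + 1)
    mirnas = _feature_ids("blood_mirna", params.n_features["blood_mirna"])
    genes = _feature_ids("blood_mrna", params.n_features["blood_mrna"])
    sig_mir = truth.signal_features["blood_mirna"]
    sig_gene = truth.signal_features["blood_mrna"]
    decoy_mir = sorted(set(mirnas) - set(sig_mir))
    decoy_gene = sorted(set(genes) - set(sig_gene))

    rows = []
    for reg in sig_mir:
        k = int(np.clip(rng.poisson(params.network_density), 1, len(sig_gene)))
        for tgt in sorted(rng.choice(sig_gene, size=k, replace=False).tolist()):
            rows.append({"regulator": reg, "target": tgt, "sign": "repression"})
    decoy_density = (
        params.network_density if params.decoy_density is None else params.decoy_density
    )
    if decoy_density > 0 and decoy_gene:
        for reg in decoy_mir:
            k = int(np.clip(rng.poisson(decoy_density), 0, len(decoy_gene)))
            if k == 0:
                continue
            signs = rng.choice(["repression", "activation"], size=k)
            for tgt, s in zip(sorted(rng.choice(decoy_gene, size=k, replace=False).tolist()), signs):
                rows.append({"regulator": reg, "target": tgt, "sign": s})
    return pd.DataFrame(rows, columns=["regulator", "target", "sign"])


def write_fixture_bundle(params: SimParams, dir_path: str) -> dict[str, str]:
    """Simulate a cohort and write the full bundle as plain-text files.

    Writes one matrix TSV per modality, the metadata TSV, the regulator
    network TSV and the ground-truth JSON; returns the path of each
    artifact. Re-running with the same parameters overwrites with
    identical content.
    """
    os.makedirs(dir_path, exist_ok=True)
    matrices, metadata, truth = simulate_cohort(params)
    paths: dict[str, str] = {}
    for m, mat in matrices.items():
        paths[m] = os.path.join(dir_path, f"{m}.tsv")
        eio.write_matrix(mat, paths[m])
    paths["metadata"] = os.path.join(dir_path, "metadata.tsv")
    eio.write_metadata(metadata, paths["metadata"])
    paths["network"] = os.path.join(dir_path, "network.tsv")
    eio.write_network(truth.planted_network, paths["network"])
    paths["truth"] = os.path.join(dir_path, "truth.json")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
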