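"""End-to-end orchestration: preprocess each modality, discover subtypes,
then run bootstrap CIs, cross-modality overlaps, differential expression,
cross-modality enrichment and upstream-regulator scoring, writing every
artifact plus a JSON manifest of seeds and outputs."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as eio
from .cluster_stats import (
    bootstrap_difference_test,
    bootstrap_proportion_ci,
    multiway_membership_table,
    overlap_test,
)
from .containers import MODALITIES, CohortMetadata, ExpressionMatrix
from .de import differential_expression
from .gsea import build_custom_sets, preranked_gsea
from .hierarchy import DEFAULT_GRID_METRICS, LINKAGES
from .preprocess import preprocess_pipeline
from .regulators import concordance_table, score_all_regulators
from .subtypes import select_best_approach, subtype_grid

log = logging.getLogger(__name__)

# fixed per-stage seed offsets so stages are reproducible in isolation
STAGE_SEEDS = {"bootstrap": 11, "gsea": 23}


@dataclass
class PipelineConfig:
    matrix_paths: dict[str, str]
    metadata_path: str
    out_dir: str
    network_path: str | None = None
    sets_path: str | None = None
    metrics: tuple = DEFAULT_GRID_METRICS
    linkages: tuple = LINKAGES
    freq_cut: float = 19.0
    unique_cut: float = 10.0
    max_k: int = 10
    cluster_fdr: float = 0.2
    de_fdr: float = 0.05
    overlap_alpha: float = 0.05
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_fdr", "de_fdr", "overlap_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        unknown = set(self.matrix_paths) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("metrics", "linkages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    Any stage failure aborts with the stage name; artifacts written by
    earlier stages are retained.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {k: config.seed + v for k, v in STAGE_SEEDS.items()},
        "artifacts": {},
    }

    stage = "load"
    try:
        metadata = eio.read_metadata(config.metadata_path)
        raw = {
            m: eio.read_matrix(p, modality=m, unit="cpm" if "mirna" in m else "tpm")
            for m, p in config.matrix_paths.items()
        }

        stage = "preprocess"
        processed: dict[str, ExpressionMatrix] = {}
        for m, mat in raw.items():
            processed[m], removed = preprocess_pipeline(
                mat, metadata, config.freq_cut, config.unique_cut
            )
            path = os.path.join(config.out_dir, f"{m}.scaled.tsv")
            eio.write_matrix(processed[m], path)
            manifest["artifacts"][f"scaled_{m}"] = path
            manifest.setdefault("removed_features", {})[m] = removed

        stage = "subtype"
        calls = {}
        for m, mat in processed.items():
            grid = subtype_grid(
                mat,
                metadata,
                metrics=config.metrics,
                linkages=config.linkages,
                max_k=config.max_k,
                fdr_threshold=config.cluster_fdr,
            )
            if grid:
                call = select_best_approach(grid)
                calls[m] = call
                path = os.path.join(config.out_dir, f"{m}.subtype.json")
                with open(path, "w") as fh:
                    json.dump(call.to_dict(), fh, indent=2)
                manifest["artifacts"][f"subtype_{m}"] = path
            else:
                log.info("no significant cluster for %s", m)
                manifest.setdefault("no_subtype", []).append(m)

        stage = "bootstrap"
        boot_seed = config.seed + STAGE_SEEDS["bootstrap"]
        ci_rows = []
        for m, call in calls.items():
            members = call.flagged_members()
            inside = metadata.outcomes(members).to_numpy()
            rest = metadata.outcomes(
                [s for s in call.assignment.labels if s not in set(members)]
            ).to_numpy()
            ci = bootstrap_proportion_ci(inside, n_boot=config.n_boot, seed=boot_seed)
            p_diff, defined = bootstrap_difference_test(
                inside, rest, n_boot=config.n_boot, seed=boot_seed
            )
            ci_rows.append(
                {
                    "modality": m,
                    "cluster": call.best_cluster,
                    "direction": call.direction,
                    "n": len(inside),
                    "n_recurrence": int(inside.sum()),
                    "proportion": ci.point,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "bootstrap_t_p": p_diff if defined else None,
                }
            )
        if ci_rows:
            path = os.path.join(config.out_dir, "cluster_cis.tsv")
            pd.DataFrame(ci_rows).to_csv(path, sep="\t", index=False)
            manifest["artifacts"]["cluster_cis"] = path

        stage = "overlap"
        overlap_rows = []
        mods = sorted(calls)
        for i, ma in enumerate(mods):
            for mb in mods[i + 1 :]:
                shared = metadata.samples_with(ma, mb)
                if not shared:
                    continue
                a = set(calls[ma].flagged_members()) & set(shared)
                b = set(calls[mb].flagged_members()) & set(shared)
                if not a or not b:
                    continue
                res = overlap_test(a, b, shared)
                overlap_rows.append(
                    {
                        "modality_a": ma,
                        "modality_b": mb,
                        "n_universe": res.n_universe,
                        "n_a": res.n_a,
                        "n_b": res.n_b,
                        "n_intersection": res.n_intersection,
                        "overlap_percent": res.overlap_percent_display,
                        "p": res.p_over,
                        "significant": res.p_over < config.overlap_alpha
                        and calls[ma].direction == calls[mb].direction,
                    }
                )
        if overlap_rows:
            path = os.path.join(config.out_dir, "cluster_overlaps.tsv")
            pd.DataFrame(overlap_rows).to_csv(path, sep="\t", index=False)
            manifest["artifacts"]["cluster_overlaps"] = path
        if len(calls) >= 2:
            shared_all = metadata.samples_with(*mods)
            if shared_all:
                tab = multiway_membership_table(
                    {m: set(calls[m].flagged_members()) for m in mods}, shared_all
                )
                path = os.path.join(config.out_dir, "multiway_membership.tsv")
                tab.to_csv(path, sep="\t")
                manifest["artifacts"]["multiway_membership"] = path
                manifest["multiway_counts"] = tab.attrs["counts"]

        stage = "differential_expression"
        de_tables = {}
        for m, call in calls.items():
            de = differential_expression(processed[m], call.assignment, call.best_cluster)
            de_tables[m] = de
            path = os.path.join(config.out_dir, f"{m}.de.tsv")
            de.table.to_csv(path, sep="\t", index_label="feature")
            manifest["artifacts"][f"de_{m}"] = path
        # project blood calls onto brain matrices for cross-tissue signatures
        cross_de = {}
        for blood_mod, brain_mod in (("blood_mirna", "brain_mirna"), ("blood_mrna", "brain_mrna")):
            if blood_mod in calls and brain_mod in processed:
                call = calls[blood_mod]
                members = set(call.flagged_members()) & set(processed[brain_mod].sample_ids)
                others = set(call.assignment.labels) & set(processed[brain_mod].sample_ids) - members
                if len(members) >= 2 and len(others) >= 2:
                    de = differential_expression(
                        processed[brain_mod], call.assignment, call.best_cluster
                    )
                    cross_de[brain_mod] = de
                    path = os.path.join(config.out_dir, f"{brain_mod}.crossde.tsv")
                    de.table.to_csv(path, sep="\t", index_label="feature")
                    manifest["artifacts"][f"crossde_{brain_mod}"] = path

        stage = "enrichment"
        gsea_seed = config.seed + STAGE_SEEDS["gsea"]
        enrich_rows = []
        for blood_mod, brain_mod in (("blood_mirna", "brain_mirna"), ("blood_mrna", "brain_mrna")):
            if blood_mod not in de_tables or brain_mod not in cross_de:
                continue
            sets = build_custom_sets(de_tables[blood_mod], fdr_cut=config.de_fdr)
            sets = [
                gs for gs in sets
                if set(gs.members) & set(cross_de[brain_mod].table.index)
            ]
            if not sets:
                continue
            gmt_path = os.path.join(config.out_dir, f"{blood_mod}.sets.gmt")
            eio.write_gmt({gs.name: gs.members for gs in sets}, gmt_path)
            manifest["artifacts"][f"sets_{blood_mod}"] = gmt_path
            ranked = cross_de[brain_mod].ranked_stats()
            for res in preranked_gsea(ranked, sets, n_perm=config.n_perm, seed=gsea_seed):
                enrich_rows.append(
                    {
                        "set": res.set_name,
                        "ranked_list": brain_mod,
                        "es": res.es,
                        "nes": res.nes,
                        "p": res.nominal_p,
                        "fdr": res.fdr_p,
                        "n_leading_edge": len(res.leading_edge),
                    }
                )
        if enrich_rows:
            path = os.path.join(config.out_dir, "gsea.tsv")
            pd.DataFrame(enrich_rows).to_csv(path, sep="\t", index=False)
            manifest["artifacts"]["gsea"] = path

        stage = "regulators"
        if config.network_path and "blood_mrna" in de_tables:
            network = eio.read_network(config.network_path)
            scores, skipped = score_all_regulators(
                network, de_tables["blood_mrna"], fdr_cut=config.de_fdr
            )
            if "blood_mirna" in de_tables and scores:
                tab = concordance_table(scores, de_tables["blood_mirna"], fdr_cut=config.de_fdr)
                path = os.path.join(config.out_dir, "regulators.tsv")
                tab.to_csv(path, sep="\t")
                manifest["artifacts"]["regulators"] = path
                manifest["regulator_counts"] = tab.attrs["counts"]
                manifest["regulators_skipped"] = len(skipped)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
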