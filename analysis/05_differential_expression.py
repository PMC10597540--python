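"""Cluster-vs-rest differential expression for each flagged cluster
(pooled-variance t, Benjamini-Hochberg, shifted log2 fold change), plus
the cross-tissue projection: the blood-defined cluster tested on the
brain matrices. Writes DE tables and a volcano plot under results/de/.

Run after 03:  python analysis/05_differential_expression.py
"""

import argparse
import glob
import json
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from episub import differential_expression
from episub import io as eio
from episub.hierarchy import ClusterAssignment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scaled-dir", default="results/preprocessed")
    ap.add_argument("--subtype-dir", default="results/subtypes")
    ap.add_argument("--out-dir", default="results/de")
    args = ap.parse_args()

    os.makedirs(args.out_dir, exist_ok=True)
    pairs = {"blood_mirna": "brain_mirna", "blood_mrna": "brain_mrna"}
    for path in sorted(glob.glob(os.path.join(args.subtype_dir, "*.subtype.json"))):
        modality = os.path.basename(path).split(".")[0]
        call = json.load(open(path))
        assignment = ClusterAssignment(
            {s: int(l) for s, l in call["members"].items()}, call["k"]
        )
        for target in filter(None, [modality, pairs.get(modality)]):
            mat_path = os.path.join(args.scaled_dir, f"{target}.scaled.tsv")
            if not os.path.exists(mat_path):
                continue
            mat = eio.read_matrix(mat_path, target, unit="scaled")
            members = set(assignment.labels) & set(mat.sample_ids)
            in_cluster = [s for s in members if assignment.labels[s] == call["best_cluster"]]
            if len(in_cluster) < 2 or len(members) - len(in_cluster) < 2:
                continue
            de = differential_expression(mat, assignment, call["best_cluster"])
            tag = f"{modality}_cluster{call['best_cluster']}_on_{target}"
            de.table.to_csv(os.path.join(args.out_dir, f"{tag}.de.tsv"),
                            sep="\t", index_label="feature")
            n_sig = int((de.table["fdr"] < 0.05).sum())
            n_down = int(((de.table["fdr"] < 0.05) & (de.table["direction"] == "down")).sum())
            print(f"{tag}: {n_sig} features at FDR<0.05 ({n_down} down, {n_sig - n_down} up)")

            if target == modality:
                fig, axis = plt.subplots(figsize=(5, 4))
                axis.scatter(de.table["log2fc"], -np.log10(de.table["fdr"]),
                             s=6, alpha=0.5,
                             c=np.where(de.table["fdr"] < 0.05, "firebrick", "grey"))
                axis.axhline(-np.log10(0.05), ls=":", c="k", lw=0.8)
                axis.set_xlabel("shifted log2 fold change")
                axis.set_ylabel("-log10 FDR")
                axis.set_title(tag, fontsize=9)
                fig.tight_layout()
                fig.savefig(os.path.join(args.out_dir, f"{tag}.volcano.png"), dpi=120)
                plt.close(fig)


if __name__ == "__main__":
    main()
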