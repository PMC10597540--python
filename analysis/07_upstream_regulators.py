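"""Upstream-regulator analysis: score every network miRNA's predicted
activation from the direction of its differentially expressed mRNA
targets (unweighted z = (consistent - inconsistent)/sqrt(total)), then
cross-check predictions against the miRNAs' own measured differential
expression. Writes the concordance table under results/regulators/.

Run after 05:  python analysis/07_upstream_regulators.py
"""

import argparse
import glob
import os

import pandas as pd

from episub import io as eio
from episub.de import DETable
from episub.regulators import concordance_table, score_all_regulators


def read_de(pattern, modality):
    paths = glob.glob(pattern)
    if not paths:
        return None
    return DETable(table=pd.read_csv(paths[0], sep="\t", index_col=0),
                   cluster=0, modality=modality)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--de-dir", default="results/de")
    ap.add_argument("--out-dir", default="results/regulators")
    args = ap.parse_args()

    os.makedirs(args.out_dir, exist_ok=True)
    network = eio.read_network(os.path.join(args.cohort_dir, "network.tsv"))
    mrna_de = read_de(os.path.join(args.de_dir, "blood_mrna_*_on_blood_mrna.de.tsv"),
                      "blood_mrna")
    mirna_de = read_de(os.path.join(args.de_dir, "blood_mirna_*_on_blood_mirna.de.tsv"),
                       "blood_mirna")
    if mrna_de is None or mirna_de is None:
        print("missing DE tables; run 05 first")
        return

    scores, skipped = score_all_regulators(network, mrna_de)
    tab = concordance_table(scores, mirna_de)
    tab.to_csv(os.path.join(args.out_dir, "regulator_concordance.tsv"), sep="\t")
    counts = tab.attrs["counts"]
    n_deact = int((tab["predicted_state"] == "deactivated").sum())
    print(f"scored {len(scores)} regulators ({len(skipped)} without DE targets): "
          f"{n_deact} predicted deactivated")
    print(f"concordance vs observed miRNA expression: {counts['concordant']} concordant, "
          f"{counts['discordant']} discordant, {counts['untestable']} untestable")
    top = tab[tab["predicted_state"] == "deactivated"].nsmallest(5, "z")
    if not top.empty:
        print(top[["z", "overlap_p", "observed_log2fc", "observed_fdr", "concordant"]]
              .to_string())


if __name__ == "__main__":
    main()
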