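"""Cross-modality enrichment: build custom signatures (UP/DOWN sets) from
the blood DE tables, then test them against the brain fold-change-ranked
lists with preranked GSEA (gene-label permutation null). Writes the GMT
files and enrichment table under results/enrichment/.

Run after 05:  python analysis/06_enrichment.py [--seed 11] [--nperm 2000]
"""

import argparse
import glob
import os

import pandas as pd

from episub import io as eio
from episub.de import DETable
from episub.gsea import GeneSet, build_custom_sets, preranked_gsea


def read_de(path, modality) -> DETable:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return DETable(table=tab, cluster=0, modality=modality)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--de-dir", default="results/de")
    ap.add_argument("--out-dir", default="results/enrichment")
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--nperm", type=int, default=2000)
    args = ap.parse_args()

    os.makedirs(args.out_dir, exist_ok=True)
    rows = []
    for blood_mod, brain_mod in (("blood_mirna", "brain_mirna"), ("blood_mrna", "brain_mrna")):
        blood_paths = glob.glob(os.path.join(args.de_dir, f"{blood_mod}_*_on_{blood_mod}.de.tsv"))
        brain_paths = glob.glob(os.path.join(args.de_dir, f"{blood_mod}_*_on_{brain_mod}.de.tsv"))
        if not blood_paths or not brain_paths:
            continue
        blood_de = read_de(blood_paths[0], blood_mod)
        brain_de = read_de(brain_paths[0], brain_mod)
        sets = build_custom_sets(blood_de, fdr_cut=0.05, prefix=blood_mod)
        sets = [g for g in sets if set(g.members) & set(brain_de.table.index)]
        if not sets:
            print(f"{blood_mod}: no significant signature to test")
            continue
        eio.write_gmt({g.name: g.members for g in sets},
                      os.path.join(args.out_dir, f"{blood_mod}.gmt"))
        ranked = brain_de.table["log2fc"]
        for res in preranked_gsea(ranked, sets, n_perm=args.nperm, seed=args.seed):
            rows.append({"set": res.set_name, "ranked_list": brain_mod, "es": res.es,
                         "nes": res.nes, "p": res.nominal_p, "fdr": res.fdr_p,
                         "leading_edge": len(res.leading_edge)})
            print(f"{res.set_name} in {brain_mod}: ES={res.es:+.3f} NES={res.nes:+.2f} "
                  f"p={res.nominal_p:.3g} FDR={res.fdr_p:.3g}")
    if rows:
        pd.DataFrame(rows).to_csv(os.path.join(args.out_dir, "gsea.tsv"),
                                  sep="\t", index=False)


if __name__ == "__main__":
    main()
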