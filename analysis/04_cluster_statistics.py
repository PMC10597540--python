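"""Bootstrap confidence intervals for the flagged clusters' recurrence
proportions, pairwise cross-modality cluster overlaps (hypergeometric
one-sided test on the shared-sample universe, Jaccard percentage), and
the multiway membership tally. Writes TSVs under results/cluster_stats/.

Run after 03:  python analysis/04_cluster_statistics.py [--seed 11]
"""

import argparse
import glob
import json
import os

import pandas as pd

from episub import (
    bootstrap_difference_test,
    bootstrap_proportion_ci,
    multiway_membership_table,
    overlap_test,
)
from episub import io as eio


def load_calls(subtype_dir):
    calls = {}
    for path in sorted(glob.glob(os.path.join(subtype_dir, "*.subtype.json"))):
        modality = os.path.basename(path).split(".")[0]
        calls[modality] = json.load(open(path))
    return calls


def flagged(call):
    return {s for s, lab in call["members"].items() if lab == call["best_cluster"]}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--subtype-dir", default="results/subtypes")
    ap.add_argument("--out-dir", default="results/cluster_stats")
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()

    os.makedirs(args.out_dir, exist_ok=True)
    meta = eio.read_metadata(os.path.join(args.cohort_dir, "metadata.tsv"))
    calls = load_calls(args.subtype_dir)
    if not calls:
        print("no subtype calls found; run 03 first")
        return

    rows = []
    for m, call in calls.items():
        members = sorted(flagged(call))
        inside = meta.outcomes(members).to_numpy()
        rest_ids = [s for s in call["members"] if s not in set(members)]
        ci = bootstrap_proportion_ci(inside, n_boot=1000, seed=args.seed)
        p_diff, defined = bootstrap_difference_test(
            inside, meta.outcomes(rest_ids).to_numpy(), n_boot=1000, seed=args.seed
        )
        pt, lo, hi = ci.rounded_percent()
        rows.append({"modality": m, "n": len(members), "n_recurrence": int(inside.sum()),
                     "percent": pt, "ci_lower": lo, "ci_upper": hi,
                     "bootstrap_t_p": p_diff if defined else float("nan"),
                     "direction": call["direction"]})
        print(f"{m}: flagged cluster {pt}%, 95% CI ({lo}-{hi}%), "
              f"n={len(members)} ({call['direction']})")
    pd.DataFrame(rows).to_csv(os.path.join(args.out_dir, "bootstrap_cis.tsv"),
                              sep="\t", index=False)

    mods = sorted(calls)
    orows = []
    for i, ma in enumerate(mods):
        for mb in mods[i + 1:]:
            shared = meta.samples_with(ma, mb)
            A = flagged(calls[ma]) & set(shared)
            B = flagged(calls[mb]) & set(shared)
            if not A or not B:
                continue
            res = overlap_test(A, B, shared)
            orows.append({"a": ma, "b": mb, "universe": res.n_universe,
                          "n_a": res.n_a, "n_b": res.n_b, "intersection": res.n_intersection,
                          "overlap_percent": res.overlap_percent_display, "p": res.p_over})
            print(f"{ma} x {mb}: {res.n_intersection} shared of {res.n_a}/{res.n_b} "
                  f"(universe {res.n_universe}) -> {res.overlap_percent_display}% overlap, "
                  f"p={res.p_over:.3g}")
    if orows:
        pd.DataFrame(orows).to_csv(os.path.join(args.out_dir, "overlaps.tsv"),
                                   sep="\t", index=False)

    if len(calls) >= 2:
        shared_all = meta.samples_with(*mods)
        if shared_all:
            tab = multiway_membership_table({m: flagged(calls[m]) for m in mods}, shared_all)
            tab.to_csv(os.path.join(args.out_dir, "multiway_membership.tsv"), sep="\t")
            print("multiway membership counts:", tab.attrs["counts"])


if __name__ == "__main__":
    main()
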