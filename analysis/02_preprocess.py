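"""Batch-wise scale/centre, near-zero-variance filter, and cohort-wide
rescale for every modality of the simulated cohort. Writes the scaled
matrices under results/preprocessed/ and reports how many features the
frequency-ratio/unique-percent rule removed.

Run after 01:  python analysis/02_preprocess.py
"""

import argparse
import os

from episub import io as eio
from episub import preprocess_pipeline
from episub.containers import MODALITIES


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--out-dir", default="results/preprocessed")
    args = ap.parse_args()

    os.makedirs(args.out_dir, exist_ok=True)
    meta = eio.read_metadata(os.path.join(args.cohort_dir, "metadata.tsv"))
    for m in MODALITIES:
        mat = eio.read_matrix(os.path.join(args.cohort_dir, f"{m}.tsv"), m,
                              unit="cpm" if "mirna" in m else "tpm")
        scaled, removed = preprocess_pipeline(mat, meta)
        out = os.path.join(args.out_dir, f"{m}.scaled.tsv")
        eio.write_matrix(scaled, out)
        print(f"{m}: {mat.n_features} features -> {scaled.n_features} "
              f"({len(removed)} removed as near-zero-variance), {mat.n_samples} samples")


if __name__ == "__main__":
    main()
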