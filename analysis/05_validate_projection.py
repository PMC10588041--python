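"""Project an unseen validation cohort onto the fixed training profiles.

Simulates a fresh cohort from the same planted profiles (new weights, new
noise), projects it with H fixed (nonnegative ridge, training D), and
compares the relative-error distribution with the training one.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from fibrenmf import io, nmf, synthetic
from fibrenmf.network import reference_network


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scenario", type=Path, default=Path("results/scenario"))
    ap.add_argument("--fit", type=Path, default=Path("results/fit"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-validation", type=int, default=150)
    ap.add_argument("--out", type=Path, default=Path("results/validation"))
    args = ap.parse_args()

    net = reference_network()
    dec = io.read_decomposition(args.fit / "train")
    H_true = np.loadtxt(args.scenario / "H_true.tsv")

    W_val, md_val = synthetic.make_weights(n=args.n_validation, k=dec.k,
                                           seed=args.seed + 1)
    X_val = synthetic.make_counts(
        W_val, H_true, noise_cv=0.2, seed=args.seed + 2,
        feature_ids=net.aft_ids,
        sample_ids=[f"V{i:04d}" for i in range(len(md_val))],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Wv = nmf.project(X_val, dec.H, dec.alpha, dec.D)
    rel_val = nmf.relative_error(X_val, Wv, dec.H)

    X_train = io.read_matrix(args.scenario / "X_AFT.tsv")
    rel_train = nmf.relative_error(X_train, dec.W, dec.H)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(Wv, index=X_val.sample_ids,
                 columns=[f"profile_{i+1}" for i in range(dec.k)]
                 ).rename_axis("sample_id").to_csv(args.out / "W_validation.tsv",
                                                   sep="\t", float_format=io.FLOAT_FMT)
    pd.DataFrame({
        "cohort": ["train", "validation"],
        "mean_rel_error": [np.nanmean(rel_train), np.nanmean(rel_val)],
        "q95_rel_error": [np.nanquantile(rel_train, 0.95), np.nanquantile(rel_val, 0.95)],
    }).to_csv(args.out / "errors.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
    print(f"train mean rel error {100 * np.nanmean(rel_train):.1f}%, "
          f"validation {100 * np.nanmean(rel_val):.1f}% "
          f"(q95 {100 * np.nanquantile(rel_val, 0.95):.1f}%)")


if __name__ == "__main__":
    main()
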