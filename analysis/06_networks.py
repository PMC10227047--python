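"""Partial-correlation networks over the 11 language-related variables:
EBIC-glasso estimation, four centralities, layout, edge stability."""

from pathlib import Path

import pandas as pd

from speechsyntax.io import write_table
from speechsyntax.network import (
    DEFAULT_NODES,
    bootstrap_edges,
    centralities,
    estimate_ggm,
    fr_layout,
)

OUT = Path(__file__).resolve().parent.parent / "results"
BOOT = 100  # case-resampling draws (1000 for a full run)


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    data = cohort.dropna(subset=list(DEFAULT_NODES))[list(DEFAULT_NODES)]
    model = estimate_ggm(data, gamma=0.25)
    write_table(model.edge_list(), OUT / "network_edges.tsv")
    write_table(model.edge_list(threshold=0.1), OUT / "network_edges_display.tsv")
    cent = centralities(model)
    write_table(cent, OUT / "centralities.csv")
    write_table(fr_layout(model, seed=0), OUT / "network_layout.csv")

    top = cent.sort_values("expected_influence", ascending=False).iloc[0]
    print(f"full-sample network: {model.n_edges} edges at lambda = "
          f"{model.lambda_selected:.3f} (gamma 0.25)")
    print(f"highest expected influence: {top.node} "
          f"(EI = {top.expected_influence:.2f}, strength = {top.strength:.2f})")

    boot = bootstrap_edges(data, B=BOOT, gamma=0.25, seed=0, n_lambda=40)
    write_table(boot, OUT / "edge_stability.csv")
    stable = boot[boot.nonzero_freq > 0.9]
    print(f"{len(stable)} edges appear in >90% of {BOOT} case resamples")


if __name__ == "__main__":
    main()
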