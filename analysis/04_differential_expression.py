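"""Build the disease differential-expression signature.

Median-of-ratios size factors, the trended NB Wald test, BH-FDR, and
direction labels (up: FDR < 0.05 and log2FC >= 1; down: FDR < 0.05 and
log2FC <= -1) on the triplicate knockout-vs-wild-type count matrix.
Sensitivity and the observed false discovery proportion are scored
against the planted truth.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from cystirep import dge
from cystirep import synthdata as sd

OUT = Path("results/analysis")


def main() -> None:
    counts = pd.read_csv(OUT / "counts.tsv", sep="\t", comment="#").set_index("gene")
    n = counts.shape[1] // 2
    groups = ["wild_type"] * n + ["knockout"] * n

    factors = dge.size_factors(counts)
    print(f"size factors: {factors.round(3).to_dict()}")

    table = dge.nb_wald_test(counts, groups, reference="wild_type", factors=factors)
    table = dge.label_degs(table)
    sd.write_table(table, OUT / "deg_table.tsv", schema="deg-table")
    summary = dge.deg_summary(table)
    print(f"DEGs: {summary['total_significant']} significant at FDR < 0.05 "
          f"({summary['up']} up, {summary['down']} down, "
          f"{summary['significant_below_fold_cut']} below the fold cut)")

    truth = pd.read_csv(OUT / "counts_truth.tsv", sep="\t", comment="#")
    truth["true_direction"] = np.where(
        truth["log2_effect"] >= 1, "up", np.where(truth["log2_effect"] <= -1, "down", "ns")
    )
    merged = table.merge(truth, on="gene")
    planted = merged["true_direction"] != "ns"
    called = merged["direction"] != "ns"
    tp = int((planted & (merged["direction"] == merged["true_direction"])).sum())
    fp = int((called & ~planted).sum())
    print(f"recovery: sensitivity {tp / int(planted.sum()):.2f}, "
          f"observed FDR {fp / max(int(called.sum()), 1):.3f} "
          f"({int(planted.sum())} planted)")


if __name__ == "__main__":
    main()
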