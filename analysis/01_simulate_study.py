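"""Generate the seeded synthetic study and write every pipeline input.

The study mirrors the screen design under analysis: a 1200-compound
library on 48-well cystine plates (24 planted depleters at 80% true
depletion) and 384-well caspase plates in triplicate (27 planted
protectors at 60% true protection, 6 compounds shared with the
depleters), plus a 10,000-gene triplicate count matrix with 200
planted differentially expressed genes.  Ground-truth tables are
written next to each input so later steps can score their recovery.

Run from the repository root:  python analysis/01_simulate_study.py
"""

from pathlib import Path

from cystirep import synthdata as sd
from cystirep.pipeline import default_study

SEED = 7
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_study(SEED)

    plates, truth = sd.simulate_screen(spec.screen_cfg)
    sd.write_table(plates, OUT / "cystine_plates.csv", sep=",", schema="plate-table")
    sd.write_table(truth, OUT / "cystine_truth.tsv", schema="truth-table")
    print(f"cystine screen: {len(plates)} wells on {plates['plate_id'].nunique()} plates, "
          f"{int((truth['true_effect'] > 0).sum())} planted depleters")

    plates, truth = sd.simulate_apoptosis_screen(spec.apoptosis_cfg)
    sd.write_table(plates, OUT / "apoptosis_plates.csv", sep=",", schema="plate-table")
    sd.write_table(truth, OUT / "apoptosis_truth.tsv", schema="truth-table")
    print(f"apoptosis screen: {len(plates)} wells on {plates['plate_id'].nunique()} plates "
          f"(3 replicates), {int((truth['true_effect'] > 0).sum())} planted protectors")

    counts, truth = sd.simulate_counts(spec.counts_cfg)
    sd.write_table(counts.reset_index(), OUT / "counts.tsv", schema="count-matrix")
    sd.write_table(truth, OUT / "counts_truth.tsv", schema="truth-table")
    n_deg = int((truth["log2_effect"] != 0).sum())
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples, {n_deg} planted DEGs")


if __name__ == "__main__":
    main()
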