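"""QC both screens, call hits on each phenotype, and cross the hit sets.

Reads the plate tables written by 01_simulate_study.py.  Each plate is
scored with the Z-factor (replicate-adjusted for the triplicate
imaging screen); compounds are called hits at >= 50% cystine reduction
and >= 40% apoptosis reduction; the intersection of the two hit sets
gives the lead candidates.  Hit calls are scored against the planted
truth tables.
"""

import pandas as pd

from cystirep import apoptosis as apo
from cystirep import cystine as cys
from cystirep import integrate, screenqc
from cystirep import synthdata as sd
from pathlib import Path

OUT = Path("results/analysis")


def read(name: str, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(OUT / name, sep=sep, comment="#")


def main() -> None:
    cys_plates = read("cystine_plates.csv", sep=",")
    cys_plates["normalized"] = cys_plates["cystine_nmol"] / cys_plates["protein_mg"]
    qc = screenqc.qc_all_plates(cys_plates, "normalized", pos_role="positive", neg_role="vehicle")
    screenqc.write_qc_reports(qc, OUT / "cystine_qc.tsv")
    hts = screenqc.z_factor(screenqc.ControlSummary.from_values(
        cys_plates.loc[cys_plates.role == "positive", "normalized"],
        cys_plates.loc[cys_plates.role == "vehicle", "normalized"]))
    print(f"cystine QC: {sum(r.passed for r in qc)}/{len(qc)} plates with Z >= 0.5; "
          f"assay-level Z = {hts:.2f}")

    apo_plates = read("apoptosis_plates.csv", sep=",")
    apo_plates["fraction"] = apo_plates["positive_nuclei"] / apo_plates["total_nuclei"]
    qc = screenqc.qc_all_plates(apo_plates, "fraction", pos_role="non_induced",
                                neg_role="induced", r=3, adjusted=True)
    screenqc.write_qc_reports(qc, OUT / "apoptosis_qc.tsv")
    print(f"apoptosis QC: {sum(r.passed for r in qc)}/{len(qc)} plates (replicate-adjusted Z)")

    cystine_hits = cys.call_cystine_hits(cys.compound_activities(cys_plates))
    cys.write_screen_results(cystine_hits, OUT / "cystine_results.tsv")
    apoptosis_hits = apo.call_apoptosis_hits(apo.compound_apoptosis(apo_plates))
    cys.write_screen_results(apoptosis_hits, OUT / "apoptosis_results.tsv")

    a = set(cystine_hits.loc[cystine_hits.hit, "compound_id"])
    b = set(apoptosis_hits.loc[apoptosis_hits.hit, "compound_id"])
    crossed = integrate.cross_screens(a, b)
    (OUT / "crossed_hits.txt").write_text("\n".join(sorted(crossed)) + "\n")

    truth_a = set(read("cystine_truth.tsv").query("true_effect > 0")["compound_id"])
    truth_b = set(read("apoptosis_truth.tsv").query("true_effect > 0")["compound_id"])
    print(f"cystine hits: {len(a)} (planted {len(truth_a)}, exact: {a == truth_a})")
    print(f"apoptosis hits: {len(b)} (planted {len(truth_b)}, exact: {b == truth_b})")
    print(f"crossed: {len(crossed)} compounds active in both screens "
          f"(expected {len(truth_a & truth_b)})")


if __name__ == "__main__":
    main()
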