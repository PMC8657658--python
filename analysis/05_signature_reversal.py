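"""Vote the disease signature against the lead compounds' ranked lists.

Each lead's prototype ranked list (PRL) is reduced to 250-gene up and
down tails; a disease-up gene is a reversal candidate when >= 4 of the
5 leads place it in their down tail, and vice versa.  The PRLs carry
planted consensus reversers (23 disease-up, 16 disease-down at support
>= 4, plus support-3 decoys), so the selection is scored exactly.
"""

import pandas as pd
from pathlib import Path

from cystirep import reversal
from cystirep import synthdata as sd
from cystirep.pipeline import _planted_reversers, default_study

SEED = 7
OUT = Path("results/analysis")
TAIL = 250
K = 4


def main() -> None:
    spec = default_study(SEED)
    deg = pd.read_csv(OUT / "deg_table.tsv", sep="\t", comment="#")
    leads = sorted(set((OUT / "crossed_hits.txt").read_text().split()) - {spec.toxic_lead})

    prl_cfg = sd.PRLSimConfig(
        genome=tuple(deg["gene"]),
        n_compounds=len(leads),
        planted_reversers=_planted_reversers(spec),
        tail_size=TAIL,
        seed=spec.prl_seed,
    )
    prls, truth = sd.simulate_prls(prl_cfg, compound_names=leads)
    for rl in prls:
        reversal.write_ranked_list(rl, OUT / f"prl_{rl.compound_id}.txt")
    sd.write_table(truth, OUT / "prl_truth.tsv", schema="truth-table")

    signatures = [reversal.tails_to_signature(rl, TAIL) for rl in prls]
    candidates, summary = reversal.vote_reversal(deg, signatures, k=K)
    sd.write_table(candidates, OUT / "reversal_candidates.tsv", schema="reversal-candidates")

    expected = set(truth.loc[truth["support"] >= K, "gene"])
    print(f"voting (k={K} of {len(leads)}): "
          f"{summary['disease_up_drug_down']} disease-up genes pushed down by the drugs, "
          f"{summary['disease_down_drug_up']} disease-down genes pushed up")
    print(f"planted >= {K}-support reversers recovered exactly: "
          f"{set(candidates['gene']) == expected}")


if __name__ == "__main__":
    main()
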