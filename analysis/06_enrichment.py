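"""Over-representation analysis of the reversal candidates.

The voted reversal genes are tested against a synthetic GMT collection
(random modules plus one module seeded with the candidates) with the
upper-tail hypergeometric test over the full gene universe, BH
correction, and greedy Jaccard clustering of the significant terms.
"""

import pandas as pd
from pathlib import Path

from cystirep import enrich
from cystirep import synthdata as sd
from cystirep.pipeline import default_study

SEED = 7
OUT = Path("results/analysis")


def main() -> None:
    spec = default_study(SEED)
    deg = pd.read_csv(OUT / "deg_table.tsv", sep="\t", comment="#")
    query = list(pd.read_csv(OUT / "reversal_candidates.tsv", sep="\t", comment="#")["gene"])

    collection = sd.simulate_gene_sets(list(deg["gene"]), focus_genes=query,
                                       seed=spec.geneset_seed)
    enrich.write_gmt(collection, OUT / "gene_sets.gmt")

    results = enrich.hypergeom_enrich(query, collection)
    sd.write_table(results, OUT / "enrichment.tsv", schema="enrichment")
    clustered = enrich.summarize_clusters(results, collection)

    n_sig = int((results["fdr"] < 0.05).sum())
    print(f"{len(results)} gene sets tested over a universe of "
          f"{results['universe_size'].iloc[0]} genes; {n_sig} significant at FDR < 0.05")
    top = results.iloc[0]
    print(f"top term: {top['set_id']} ({top['name']}), overlap {top['overlap']}/{top['set_size']}, "
          f"p = {top['p']:.2e}")
    if not clustered.empty:
        print(f"{clustered['cluster'].nunique()} cluster(s) after Jaccard grouping")


if __name__ == "__main__":
    main()
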