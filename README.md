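# cystirep

An integrative drug-repurposing pipeline for nephropathic cystinosis —
and, more generally, for any rare-disease programme that combines a
dual-phenotype compound screen with a transcriptome reversal analysis.

Nephropathic cystinosis is a lysosomal storage disease: loss of the
cystinosin transporter (*CTNS*) causes lysosomal cystine accumulation,
proximal tubular dysfunction, and heightened sensitivity to apoptosis.
The repurposing strategy implemented here screens an off-patent
compound library for two cellular phenotypes, crosses the hits, and
asks — connectivity-map style — which disease expression changes the
lead compounds are predicted to push back toward normal:

1. **Screen QC** — per-plate Z-factor,
   `Z = 1 − 3(σ_p + σ_n)/|μ_p − μ_n|`, with a replicate-adjusted
   variant for triplicate imaging screens.
2. **Hit calling** — cystine per mg protein as percent of each plate's
   vehicle mean (hit: reduction ≥ 50%); caspase-3/7-positive nuclei
   over total nuclei as percent of each plate's induced-untreated mean
   (hit: reduction ≥ 40%); leads = the intersection, confirmed by
   four-parameter logistic dose-response fits and one-way ANOVA with
   Bonferroni posttests.
3. **Disease signature** — median-of-ratios normalization, a trended
   negative-binomial Wald test, BH-FDR, and direction labels
   (FDR < 0.05, |log2FC| ≥ 1).
4. **Signature reversal** — each lead's prototype ranked list (PRL) is
   reduced to 250-gene up/down tails; a disease-up gene is a reversal
   candidate when ≥ 4 of the 5 leads rank it in their *down* tail, and
   vice versa.
5. **Enrichment** — upper-tail hypergeometric ORA of the reversal genes
   against GMT gene sets, with greedy Jaccard grouping of redundant
   terms.

A synthetic-data module generates every input with planted ground
truth (screens, counts, PRLs, gene sets), so the full chain is testable
offline.  See `docs/methods.md` for models, defaults, and limitations.

## Worked example

The numbered drivers under `analysis/` run the default seeded study and
narrate what they find (outputs land in `results/analysis/`):

```text
$ python analysis/01_simulate_study.py
cystine screen: 1440 wells on 30 plates, 24 planted depleters
apoptosis screen: 4368 wells on 12 plates (3 replicates), 27 planted protectors
counts: 10000 genes x 6 samples, 200 planted DEGs

$ python analysis/02_screen_qc_and_hits.py
cystine QC: 30/30 plates with Z >= 0.5; assay-level Z = 0.74
apoptosis QC: 12/12 plates (replicate-adjusted Z)
cystine hits: 24 (planted 24, exact: True)
apoptosis hits: 27 (planted 27, exact: True)
crossed: 6 compounds active in both screens (expected 6)

$ python analysis/04_differential_expression.py
DEGs: 201 significant at FDR < 0.05 (92 up, 97 down, 12 below the fold cut)
recovery: sensitivity 0.94, observed FDR 0.000 (200 planted)

$ python analysis/05_signature_reversal.py
voting (k=4 of 5): 23 disease-up genes pushed down by the drugs,
16 disease-down genes pushed up
planted >= 4-support reversers recovered exactly: True
```

Reading the numbers: every plate clears the Z ≥ 0.5 quality band, the
50%/40% reduction thresholds recover exactly the planted actives, the
crossed set contains the 6 dual-phenotype compounds (one is then
excluded as toxic, leaving 5 leads), the NB test finds the planted
expression changes at the nominal error rate, and the k-of-n vote
selects exactly the genes whose disease-direction change ≥ 4 leads
oppose — while rejecting the planted support-3 decoys.

The same stages are available as a CLI (`cystirep simulate | qc |
screen-cystine | screen-apoptosis | cross | fit-dr | dge | reversal |
enrich | run-all`) for use on real plate tables, count matrices, PRL
files, and GMT collections.

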