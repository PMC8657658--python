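# Methods

`cystirep` re-implements, as a tested pipeline, an integrative
drug-repurposing analysis for nephropathic cystinosis: a dual-phenotype
compound screen (lysosomal cystine depletion and protection from
apoptosis) whose crossed hits are confirmed by dose-response modelling,
combined with a disease transcriptome signature through
opposite-direction voting against per-compound ranked gene lists, and
finished with gene-set over-representation analysis.  This note records
the models, the tunable parameters, and the design decisions taken where
the underlying analysis left the choice open.

## Screen quality control

The Z-factor compares control separation to control spread,

    Z = 1 − 3(σ_p + σ_n) / |μ_p − μ_n|,

with sample SDs (n−1 denominator, standard for assay QC).  For screens
whose per-compound readout is the mean of r replicate wells on
different plates, the replicate-adjusted variant divides the *spread
term* by √r:

    Z_r = 1 − [3(σ_p + σ_n) / |μ_p − μ_n|] / √r.

The alternative reading — dividing the whole expression by √r — is
selectable (`mode="whole"`) but not the default, because it caps a
perfect assay at 1/√r < 1, which contradicts the interpretation of
values near 0.55 as good for replicated high-content assays.  The
default reporting band is Z ≥ 0.5 (the conventional "excellent assay"
bound).  Because no per-plate exclusion cutoff is standard, plates are
*reported* against 0.5 but *excluded* from analysis only below a
separate `z_exclude_threshold` (default 0, i.e. only assays with
overlapping control bands are dropped); both are configurable.

## Hit calling

Cystine readouts (nmol) are normalized to per-well protein (mg) and
expressed as percent of the same plate's vehicle (DMSO) mean; apoptosis
is the fraction of caspase-3/7-positive nuclei over total nuclei,
normalized to the same plate's induced-untreated mean.  Normalization
is always plate-wise, because controls live on every plate and
plate-to-plate level shifts would otherwise leak into the activity
scale.  Replicate wells are combined on the percent scale after
normalization; the default policy is the mean (a min/max policy is
available for more/less permissive calling).  Hits are thresholded on
percent reduction — ≥ 50 for cystine, ≥ 40 for apoptosis, both
boundary-inclusive — and the two hit sets are crossed by plain
intersection.  Non-induced vehicle wells are carried as a reference
series and feed the Z-factor, but never enter hit calling.

## Dose-response confirmation

Lead compounds are fit with the four-parameter logistic

    y(x) = d + (a − d) / (1 + (x/c)^b),

by least squares (Levenberg–Marquardt on (a, d, log c, b); the log-EC50
parameterization keeps c positive without bounds).  Initialization:
a and d from the responses at the extreme doses, c from the log-middle
of the dose grid, b = 1; on failure up to five perturbed restarts over
both slope signs.  Near-constant responses (range below 1e−8 of the
response scale, or fitted |a − d| below 1e−6 of the data span) are
declared degenerate — the EC50 is unidentifiable — and reported with
`converged = False`, parameters withheld.  Confirmation statistics are
one-way ANOVA across dose groups with, when the overall p < 0.05,
pairwise t tests on the pooled within-group mean square, Bonferroni-
multiplied and capped at 1 (the classical multiple-comparison
posttest).  Toxicity-based exclusion of a crossed hit is an explicit
user-supplied list, not an automated rule, because no viability readout
is part of the data model.

## Differential expression

The disease signature is built from a gene × sample integer count
matrix with two groups (wild-type, knockout), at least two samples
each.  Normalization is median-of-ratios: each sample's factor is the
median, over genes positive in every sample, of its ratio to the
per-gene geometric mean.  The two-group test assumes a negative
binomial law, Var(K) = μ + αμ².  Gene-wise dispersion is estimated by
method of moments within each group (on normalized counts, with the
size-factor correction of the Poisson term) and pooled.  At 2–3
replicates per group the raw moment estimate is far too noisy to use
directly, so it is shrunk toward a mean-dependent trend — the median
raw dispersion within 20 quantile bins of mean expression — with the
gene's own n₁+n₂−2 degrees of freedom weighed against a `prior_df`
pseudo-count (default 20) on the trend.  The Wald statistic contrasts
the log normalized group means (pseudo-count 0.5 on each mean, so
all-zero groups are defined), with a t reference on n₁+n₂−2+`prior_df`
degrees of freedom; genes with zero counts everywhere get p = 1 and
log2FC = 0.  Multiplicity is handled by Benjamini–Hochberg.  Direction
labels use FDR < 0.05 (strict) and |log2FC| ≥ 1 (inclusive).  There is
no dispersion-trend fitting beyond the binned median, no shrinkage of
fold changes, no outlier replacement, and no independent filtering;
these simplifications are intentional and visible, and mean that DEG
counts from real data will not exactly match a full DESeq2-style
analysis of the same matrix.

Null calibration is checked empirically: on 10,000 simulated null
genes at triplicate sample size the fraction of p < 0.05 must sit
within one percentage point of 0.05 (the acceptance suite recomputes
this).

## Signature reversal

Each compound contributes a prototype ranked list (PRL): a total order
over the genome, most-upregulated first.  Tied ranks are rejected
rather than silently broken.  The top and bottom `tail_size` genes
(default 250, common connectivity-map practice; the underlying
consensus criterion is not published, so the default is an explicit
stand-in) form the compound's up/down signature; when explicit
up/down gene-list files are supplied they are used verbatim and tail
extraction is skipped.  Replicate rankings can be merged by mean-rank
(Borda) aggregation with lexicographic tie-break.  Voting: a
disease-up gene is selected iff ≥ k of the n compound signatures place
it in their *down* tail (default k = 4 of n = 5), and symmetrically
for disease-down genes; ns genes never qualify.  The selection is
monotone in k and in tail size, and invariant to compound order.

## Over-representation analysis

The voted genes are tested against GMT gene-set collections with the
one-sided upper-tail hypergeometric test, P(X ≥ x) for overlap x, set
size K, query size n, universe M, BH-corrected across sets.  The
universe defaults to the genes of the DEG table (configurable to the
union of collection members) — the background materially changes p and
must be explicit.  Query and set members outside the universe are
dropped with a logged count.  Redundant significant terms are grouped
greedily by Jaccard similarity of their gene membership (cut 0.3,
visiting terms by ascending p, representative = the group's lowest-p
term); this is a deliberately simple stand-in for kappa-based term
clustering.

## Synthetic study

The generator module produces every pipeline input with planted ground
truth; its defaults are the study conditions used by the tests and the
acceptance script:

* **Cystine screen** — 1200 compounds on 48-well plates, 4 vehicle + 4
  cysteamine-like positive controls per plate, 24 planted depleters at
  true effect 0.8, per-well gaussian noise of SD 0.05 × vehicle mean.
  Baseline constants (6 nmol cystine/mg protein in untreated
  cystinotic cells, 2% residual after cysteamine, 0.02 mg protein per
  well) are round numbers in the physiologically plausible range for
  proximal-tubule cell lysates.  Protein carries its own jitter; it
  cancels in percent-of-vehicle, so planted effects are exact at zero
  noise.
* **Apoptosis screen** — 384-well plates with 32 induced-untreated and
  32 non-induced control wells, triplicate plate sets, 27 planted
  protectors at effect 0.6 with 6 compounds shared with the depleters.
  Induced caspase-positive fraction 0.40, non-induced 0.04, 1200
  nuclei per well; positive-nucleus counts are rounded from the noisy
  fraction (quantization ≤ 0.05%, irrelevant at the 40% threshold).
* **Counts** — 10,000 genes × 3 + 3 samples, NB with common baseline
  mean 100 and dispersion 0.02 (typical of technical-replicate cell
  lines), 200 planted DEGs.  The 39 reversal-designated genes (23 up,
  16 down) and 6 decoys carry |log2 effect| = 3 so their detection is
  essentially certain and the voting stage is tested in isolation from
  DEG power; the remaining planted genes draw |effect| from U(1, 2.5)
  and deliberately straddle the detection boundary.
* **PRLs** — five lists over the same genome; each planted reverser is
  placed uniformly inside the relevant 250-gene tail of exactly its
  supporting compounds' lists and strictly outside both tails
  elsewhere.  True reversers get support 4 or 5; decoys get support 3,
  one short of the quorum, so a correct voter must reject them.
* **Dose-response** — per-lead 4PL truth (top 100, bottom U(10, 30),
  EC50 log-uniform over the 1–10 µM dose grid, Hill U(0.8, 2)) with
  triplicate gaussian noise of SD 2 percentage points.

What the generator does **not** emulate: spatial plate effects (edge
wells, gradients), compound fluorescence interference, batch effects
or library-size imbalance in the counts, correlated genes, and
realistic rank correlation between compounds' PRLs.  Passing the
planted-truth tests therefore demonstrates correctness of the
computations and thresholds, not robustness to those real-data
artifacts.

All generators take explicit integer seeds; there is no hidden global
random state, and identical seeds give byte-identical output tables.

## Problem sizes

The default synthetic study (1200 compounds, ~5800 screen wells,
10,000 genes × 6 samples, five 10,000-gene PRLs) runs end-to-end in
well under a minute on one CPU; the calibration simulations (10,000
null genes; 10,000 null ANOVA datasets; 200 noisy dose-response
refits) were sized to make Monte-Carlo error small relative to the
tolerances they are checked against (binomial SE ≈ 0.2 percentage
points at 10,000 draws).

## Known limitations

* The DE test is a transparent simplification; exact DEG counts from a
  full shrinkage-based analysis of real data are out of scope.
* The PRL tail size is a convention, not an inference; results at
  other tail sizes follow the documented monotonicity.
* ORA p-values depend strongly on the chosen universe; the default is
  the DEG table's gene set and should be changed consciously.
* EC50s fitted on the 4-dose grid alone (no anchors outside the grid)
  are poorly identified when the true EC50 lies near or beyond the
  grid edge; the fit reports convergence honestly but the estimate can
  be off severalfold there.
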