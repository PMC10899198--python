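# Methods

## Assay model

An MPRA element is a 230 bp oligo: a 200 bp genomic window with the assayed
variant base inside it, flanked by fixed 15 bp synthesis adapters
(`ACTGGCCGCTTGACG` … `CACTGCGGCTCCTGC`).  Centering an even-length window is
ambiguous by one base; we fix 99 bases upstream and 100 downstream (0-based
offset 99 within the insert) so element sequences are byte-reproducible.
Only single-nucleotide substitutions are supported — indels change the insert
length and are rejected — and elements are always built on the forward strand
of the supplied genome.  Ref and alt elements of a variant therefore differ
at exactly one position, an invariant the tests enforce.

Every element is coupled to many random 20 bp barcodes.  Activity of element
*e* in replicate *r* is

    a_er = log2( ((rna_er + 1) / N_rna,r) / ((dna_er + 1) / N_dna,r) )

where counts are sums over the element's contributing barcodes and `N` are
per-replicate assay totals over retained elements (total-count
normalisation).  The +1 pseudocount keeps activities finite at zero counts;
its distortion is < 0.01 log2 units for counts ≥ 1000.  Pooled activity
`A_e` applies the same formula to counts summed over replicates.

## Read processing

All sequence matching is exact: adapter trimming requires the association
5' adapter (`GGCCTAACTGGCCGCTTGACG`) as a literal prefix, element matching
requires the trimmed read to be a zero-mismatch, zero-indel prefix of exactly
one element's post-adapter reference, and barcodes are accepted only between
exact guide-sequence matches at exactly 20 bp spacing with no Ns.  This
mirrors the stringency of the original processing: errors discard reads
instead of risking misassignment, trading recall for exact precision (a
property the simulation tests verify directly).

Read-pair roles in association sequencing: read 1 carries adapter + oligo,
read 2 the guide-flanked barcode; if the guides are not found on read 2
as-is, its reverse complement is searched.  A barcode observed with more than
one element is assigned to the majority element when it holds ≥ 90% of the
barcode's support (configurable `dominance`), otherwise dropped as ambiguous.
Raising the dominance threshold can only shrink the mapped set (tested as a
property).

For DNA/RNA count sequencing, the forward read is searched with the assay's
forward-orientation guide pair and the reverse read with the
reverse-orientation pair (hits reverse-complemented to canonical
orientation); a pair whose two reads yield different barcodes is dropped as
inconsistent.  The DNA reverse-orientation pair is
`TCGCCGTGTAATAATTCTAGA` / `AGATCGGAAGAGCG`.

## Aggregation filters

A barcode contributes to its element iff its **DNA** count is ≥ 1 in every
replicate.  DNA witnesses plasmid delivery; an RNA zero for a delivered
barcode is a meaningful expression observation, so RNA presence is not
required by default (`require_rna=True` extends the rule to both assays —
the choice is surfaced prominently because either reading is defensible).
Elements with fewer than 5 contributing barcodes are dropped and logged.
Ref and alt elements are filtered independently, so a variant can lose one
allele and then be skipped (and logged) by the allelic test.

## Enhancer calling

**General enhancers.**  Pooled activities are standardised over all retained
elements (sample sd, controls included in the background) and elements with
z ≥ 3 are called.  Calling is one-sided by default — the target class is
enhancers, not silencers — with a two-sided option (`|z| ≥ 3`).  Negative
outliers are reported but not called.  If sd = 0 all z are defined as 0 and
nothing is called.  Whether standardisation should operate on log ratios or
raw ratios was an open choice; we use the log2 ratio, consistent with the
activity definition above.

**Allele-specific enhancers.**  With replicate as the block, the balanced
two-allele common-replicate design admits an exact paired formulation of the
correlated-groups mixed model: per replicate difference
`d_r = a_alt,r − a_ref,r`, effect `β̂ = mean(d_r)`, sample variance
`s²_g = var(d_r)` on `d_g = R − 1` df, unscaled variance `v_g = 1/R`.  Any
additive per-replicate effect shared by both alleles cancels in `d_r`
exactly (scale-equivariance, tested).  The equivalence holds only for
complete pairs with a common replicate set; unbalanced variants are skipped,
not modelled.

Variances are shrunk toward a scaled inverse-chi-square prior fitted by the
standard method of moments on log variances: with
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`,

    ψ'(d0/2) = max(0, var(e)·n/(n−1) − mean(ψ'(d_g/2)))
    s0² = exp(mean(e) + ψ(d0/2) − log(d0/2))

solved for `d0` by monotone root bracketing on the trigamma (bisection
bracket [1e-4, 1e6], tolerance 1e-8); a non-positive right-hand side gives
`d0 = ∞` with `s0² = exp(mean(e))` and a normal reference distribution.
The moderated statistic is `t = β̂ / (s̃·√v_g)` with
`s̃² = (d0·s0² + d_g·s²_g)/(d0 + d_g)` on `d0 + d_g` df; at `d0 = 0` this
reduces to the ordinary paired t-test (verified against an independent
implementation to 1e-8).  P-values are Benjamini–Hochberg adjusted (own
step-up implementation, cross-checked against statsmodels) and tiered:
active (adj_p < 0.05), suggestive (0.05 ≤ adj_p < 0.1), ns.

The optional B statistic (log-odds of differential activity, prior
proportion 0.01) uses the standard two-component scale-mixture form; the
effect-variance hyperparameter is set by moment matching on the upper tail
of the t statistics rather than a full mixture fit.  B is off by default and
intended for ranking only.

## Annotation arithmetic

* **Depletion rank**: 500 bp windows at 50 bp step, 0-based half-open; a
  variant at 1-based position p is covered by windows with
  `start ∈ (p−1−500, p−1]` (~10 windows on a complete tile) and inherits
  their mean score; NA off-track.  Malformed (non-500 bp) windows are
  rejected.
* **TFBS delta scores**: keep `|score| ≥ 0.8` (inclusive boundary — the
  published cut-off states no strictness); negative = disrupt, positive =
  create; a variant is flagged when any prediction survives.
* **Interval overlap**: the element footprint of a variant is
  `[pos−1−flank, pos+flank)` (flank 100 by default, i.e. the assayed
  window), intersected against 0-based half-open BED intervals.
* **Proportion tests**: Pearson chi-square on the k×2 table; Yates
  continuity correction iff k = 2, which is the default behaviour of the
  classical proportion test and reproduces both published p-value families
  (three-group uncorrected, merged two-group corrected) on the packaged
  overlap counts.  Percentages are rounded half-up to 2 decimals for report
  parity; half-up vs banker's rounding is unknowable from the published
  table, so half-up is fixed here.

The packaged overlap-count table uses a background group of 5094 elements:
this is the unique size consistent with all four published percentage cells
and both published p-value rows.  The packaged TFBS table carries the
published variant IDs, positions, TF names and FDR bins, but synthetic
placeholder score magnitudes (±0.8 boundary for published high-confidence
hits, −0.3 for variants published without hits) because the signed scores
themselves were not released; it supports the filtering arithmetic, not
effect-size reanalysis.

## Synthetic data

The generator's defaults mirror the study conditions: 3 replicates, ~449
barcodes per element truncated to 1–9333 (log-normal with σ = 1 on the log
scale, tuned so the mean matches), a ~3% enhancer minority
(α ~ Normal(2, 0.5) log2 units, shared by both alleles), a ~0.5% allelic
minority (β ~ ±Normal(1.5, 0.3)), and per-barcode log-normal abundance
weights.  DNA counts are multinomial over barcode weights at the configured
depth; RNA expectations are `w_b·2^(α + β·[alt] + u_r)` with a replicate
effect u_r (sd 0.1) shared across alleles — deliberately, so the paired
model's invariance is exercised — and counts are gamma-Poisson
(negative-binomial, dispersion 0.05) around the scaled expectations,
collapsing to multinomial at dispersion 0 for exact round-trip tests.
Sequencing errors are uniform substitutions at 0.1% per base.  The DNA/RNA
sequencing depth per replicate is not published; the default 20 M reads per
assay/replicate is a realistic share of a high-output flow cell.  One master
seed drives an independent stream per stage (library / association reads /
counts / count FASTQ), so outputs are byte-identical under a fixed seed and
stages can be regenerated independently.

What the generator does **not** emulate: PCR chimeras and duplicates, index
hopping, GC and position-dependent coverage bias, barcode-level
overdispersion heterogeneity, and real linkage structure among variants.
Passing tests therefore demonstrate the pipeline's correctness under its own
model assumptions and its exactness guarantees (precision-1 matching,
round-trip identity), not robustness to every artefact of real sequencing.

## Problem sizes and numerical choices

The shipped test and acceptance runs use desk-scale conditions chosen to
exercise every code path with stable statistics: the `tiny` preset (200
variants, ~30 barcodes/element, 300 k reads per assay/replicate) for round
trips; 20 × 120 variants at shallow depth for null calibration; 300 variants
with 5% planted β = ±2 for power/bias; 2000 draws for prior recovery.  The
`paper-scale` preset reproduces the full study geometry (5254 allele pairs)
for users who want it.

Degenerate inputs are handled explicitly: zero-variance ensembles and
all-zero variance vectors raise; a zero-spread activity vector yields z = 0
everywhere and no calls; empty p-value vectors pass through BH unchanged;
zero-total-count replicates raise rather than silently producing infinities.
Ties in BH are preserved by a stable sort.  Barcode-map resolution breaks
exact support ties deterministically (lexicographically largest element id
wins only when strictly greater support is absent — such barcodes are below
the dominance threshold and dropped anyway unless one element dominates).

## Known limitations

* Only SNVs; no strand-aware or indel-tolerant matching; no barcode error
  correction (a Hamming-neighbour collapse would raise recall at some
  precision cost).
* Barcode-level modelling with precision weights (rather than aggregated
  counts) is out of scope; total-count is the only normalisation mode.
* The B statistic's hyperparameter uses a tail-moment approximation, not the
  full mixture estimator.
* The allelic model requires a complete, balanced ref/alt pair; variants
  with one underrepresented allele are excluded rather than modelled — the
  same behaviour the published screen reports for loci that lost an allele
  to barcode filters.
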