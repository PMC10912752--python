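# Methods

`tmztk` reimplements, as a tested library, the statistical core of a
glioblastoma (GBM) temozolomide (TMZ) response analysis: dropout
statistics for a DNA-damage-response (DDR)-focused pooled CRISPR screen,
a somatic-variant filter chain feeding 96-channel mutational-signature
refitting with a hypermutation classifier, and a patient-cohort model
linking proliferation-adjusted RAD18 expression to hypermutation.  A
synthetic-data module generates every input with retained ground truth,
so the whole pipeline runs and is tested without any external data.

## Screen statistics (`screen_quant`, `screen_stats`)

Reads from sequenced sgRNA cassettes are counted by exact spacer matching
between universal flanks (`count_guides`); a read increments exactly one
guide, and mapped + unmapped always equals the input total.  Exact
matching (rather than fuzzy alignment) keeps the counting contract
testable; a one-mismatch search and reverse-complement search exist
behind flags but are off by default.  Counts are normalized per sample to
a fixed total (counts-per-10-million by default).  Every downstream
statistic is invariant to this constant by construction, which is the
protection against the unknown normalization dialect of upstream
counting tools.

Per-guide log2 fold changes r = log2((n_PD20 + c)/(n_PD0 + c)) compare 20
population doublings of selection against the baseline, with pseudocount
c = 1 guarding dropout zeros.  Gene ranking uses SigmaFC (SUMLFC): the
sum over a gene's guides of the replicate-mean LFC.  SigmaFC scales with
guide count; it is compared only against resampled null gene scores of
the same size.

Significance against non-targeting controls is an empirical two-sided
permutation test: B = 10,000 draws of m control guides without
replacement, each scored by SigmaFC, and
p = (1 + #{|null| >= |observed|})/(B + 1), so p is bounded below by
1/(B + 1) and never zero.  All genes with the same guide count share one
null sample.

Drug-vs-vehicle gene statistics use a two-sample Z:
Z_g = X_g / S_g with X_g the difference in mean guide LFC (TMZ − DMSO)
and S_g the standard error of that difference in the Welch form
sqrt(s²_T/n_T + s²_D/n_D).  The standard-error reading (rather than a
pooled standard deviation) is the only one under which the pathway
combination

    Z_P = (Σ_{g∈P} X_g) / sqrt(Σ_{g∈P} S_g²)

is standard normal under the null, which is the property the pathway
test relies on.  **Observation units:** each guide contributes its
replicate-mean LFC (n = guides per condition), not raw guide × replicate
values.  Guides carry a shared efficacy component across replicates, so
raw pooling treats correlated values as independent and underestimates
S_g — in null simulations it inflates the Z_P standard deviation to
≈ 1.12 and the 5% type-I error to ≈ 0.09, while replicate-mean units are
exchangeable across guides and calibrate correctly.  Raw pooling remains
available via `collapse_replicates=False`.  Pathway membership is
many-to-many: a gene listed under several DDR pathways contributes to
each.

Pathway dropout summaries (for heatmap/radar-style displays) are the
paired t-test on log10(PD20 + c) vs log10(PD0 + c) over guide × replicate
pairs, and the pooled log2 fold change log2(Σ PD20 / Σ PD0) over the
pathway's guides.  Degenerate conventions: all paired differences exactly
zero gives p = 1; zero variance with non-zero mean gives p = 0 with a
warning.

## Variant filtering and mutation catalogs (`variants`)

Variant records (from VCF with DP/AD FORMAT fields; multi-allelic sites
split to biallelic rows) pass a conjunction of post-calling filters, all
inclusive at the printed boundary: mutant allele frequency ≥ 10%,
coverage ≥ 10×, alt-supporting reads ≥ 3; indels strictly longer than
10 bp are removed; exact (chrom, pos, ref, alt) matches to known
polymorphisms are removed; and variants must start inside a captured
exon region (BED, 0-based half-open, VCF positions 1-based).  Records
carrying an upstream caller verdict are restricted to PASS by default.
Because the filters are a conjunction, order affects only the per-filter
removal tally, never the surviving set; the chain is idempotent and
monotone.

Passing SNVs are binned into 96 trinucleotide channels in the pyrimidine
convention (purine-reference records are reverse-complemented together
with their context), ordered as in the COSMIC v2 layout.  Contexts come
either attached to the records or from a FASTA lookup; the two paths
produce identical catalogs and are tested against each other.  The six
substitution classes split into Pattern I (C>T, attributed to
O6-methylguanine mispairing with thymine) and Pattern II (the remaining
five classes, attributed to N3-methyladenine/N7-methylguanine processing);
the two patterns always sum to the total SNV count.

## Signature refitting and group comparison (`signatures`)

Exposures solve min ‖m − S·e‖₂ subject to e ≥ 0 per sample
(non-negative least squares, Lawson–Hanson active set — deterministic and
KKT-exact), reported in mutation counts so the alkylation-signature count
can be thresholded directly: strictly more than 500 attributed mutations
classifies a sample as hypermutant.  Tests validate NNLS against an
exhaustive simplex × scale grid search for K ≤ 3 and check homogeneity
and nested-model residual monotonicity.

Group comparisons of per-clone exposures are pairwise two-sided t tests
with Tukey HSD adjustment: pooled within-group variance with N − k error
degrees of freedom and the studentized-range tail probability with k
groups.  For k = 2 this reduces exactly to the pooled two-sample t test
(q = |t|·√2), which is the closed-form check in the tests, alongside a
Monte-Carlo confirmation that the family-wise error rate stays near
nominal for k = 3.

## Cohort model (`cohort`)

The proliferation score is the mean of within-cohort z-scored expression
over a cell-cycle gene set — a deliberate simplification of kernel-based
single-sample enrichment scoring.  The downstream analysis needs only a
monotone proliferation proxy, and the score may alternatively be supplied
precomputed.  RAD18 expression is adjusted by OLS on the proliferation
score; the residual (orthogonal to the score, zero-sum to 1e-9) is the
adjusted expression, which is stratified into tertiles at the empirical
1/3 and 2/3 quantiles (linear interpolation; ties share a label; if the
cuts coincide every sample is labelled medium with a warning).

Hypermutation is modelled as
logit P(hyper) = β₀ + β₁·RAD18_adj + β₂·MGMT_low with MGMT entering as a
binary low/high indicator.  The fit is iteratively reweighted least
squares (max 100 iterations, relative log-likelihood tolerance 1e-10,
step-halving so the log-likelihood never decreases) with Wald standard
errors from the inverse observed information; exact or quasi-complete
separation raises an error naming the covariate.  POLE-mutant samples
are excluded by a boolean column filter before modelling.  All samples
enter the model with continuous adjusted expression; the tertile labels
are display stratification only.

## Synthetic data (`simulate`)

The generator produces the study conditions the pipeline is tested
under; its defaults are fixed, not tuning knobs.

* **Library**: 504 DDR genes × 10 guides + 1,000 non-targeting controls,
  20-nt unique spacers, genes assigned to 12 DDR pathway labels
  (many-to-many for every ninth gene).
* **Screen counts**: PD0 guide abundances log-normal (sd 0.25 decades)
  around uniform, mimicking library skew and stressing normalization.
  PD20 expectation multiplies in 2^(gene coefficient + per-guide
  efficacy noise, sd 0.15); the efficacy draw is shared across
  replicates, reproducing the within-guide correlation of real screens.
  Counts are negative binomial with Var = μ + αμ², α = 0.05, at an
  expected 1.5 million reads per sample; control guides always carry
  coefficient 0.  Neither PD0 skew nor depth is reported for the
  original screen beyond a >250-fold guide representation, so these are
  package choices.
* **Lesion spectrum**: primary TMZ lesions are drawn as 70%
  N7-methylguanine, 25% N3-methyladenine, 5% O6-methylguanine.
* **Clone catalogs**: per-clone SNV totals are negative binomial
  (α = 0.05) around arm means calibrated to the reported contrasts —
  basal 150 (RAD18+/+ MLH1+/+), 280 (RAD18−/− MLH1+/+), 1,200/1,500 for
  the MMR-deficient lines, and TMZ-induced increments of 396 and 378 in
  the MMR-proficient RAD18+/+ and RAD18−/− lines, ≈ 500 in RAD18+/+
  MLH1−/− and 0 in the double knockout.  Channels are drawn from per-arm
  mixtures over a bundled synthetic 5-signature matrix whose alkylation
  component concentrates C>T at non-CpG contexts; TMZ arms of the
  RAD18−/− MMR-proficient line put ~2× more of their total into that
  component, emulating the reported Signature-11 excess.  Variant
  records carry depth/VAF/alt-read values that pass the default filter
  chain, randomized strand representation to exercise canonicalization,
  and loci on a tiny synthetic reference containing every trinucleotide.
* **Cohort**: RAD18 = ρ·proliferation + √(1−ρ²)·noise with ρ = 0.75 and
  standard-normal components; hypermutation is Bernoulli under the
  logistic model (defaults β₀ = −1, β_RAD18 = −1.5, β_MGMT = +1.5 on
  MGMT-low); signature counts are drawn so hypermutants strictly exceed
  500 and non-hypermutants never do.  The default size of 200 samples is
  in the range of a multi-institute recurrent-GBM cohort.

What the generator does **not** emulate: PCR duplicates, non-uniform
sequencing error, clonal phylogenies, subclonal VAF structure, copy
number, germline contamination, or expression batch effects.  Passing
tests therefore demonstrate the statistics are implemented and
calibrated correctly under these idealized conditions, not that the
pipeline is robust to every artifact of real sequencing data.

## Numerical choices and problem sizes

Determinism: every generator takes an integer seed; identical
(design, seed) gives byte-identical outputs.  The permutation floor
1/(B+1) is attained, never 0.  Zero-variance degenerate cases are
defined explicitly (Z_g = 0 when X_g = 0 and S_g = 0; errors otherwise).

Test problem sizes are chosen to finish in minutes on one core while
leaving Monte-Carlo error well inside the asserted tolerances: the null
calibration of Z_P uses 56 independent 504-gene screens partitioned into
2,000 disjoint 14-gene pathways (disjointness keeps the Kolmogorov–
Smirnov test valid); permutation calibration uses one 504 × 10 screen
with 1,000 controls and B = 10,000; catalog calibration uses 200–400
clones per arm; regression recovery uses n = 5,000 cohort samples.

## Known limitations

* Exact spacer matching undercounts at high sequencing error rates by
  design; fuzzy matching is out of scope.
* The six-class pathway heatmap statistics reproduce the analysis
  contract, not the figure rendering.
* NNLS exposures carry no uncertainty estimates (no bootstrap), and de
  novo signature extraction is not provided.
* The MGMT-low cutoff and the proliferation gene set are configuration,
  not inferred quantities.
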