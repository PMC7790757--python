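# Methods

## The statistic and the junction taxonomy

The pipeline quantifies cryptic 3′-splice-site usage with the splicing index
SI = a/(a + c), where a and c are the unique split-read counts of an
aberrant junction and of its canonical partner in one sample. SI is left
missing when a + c = 0 (the locus is unobserved, not quantifiably normal);
everywhere an analysis needs a number, missing SI is imputed as 0 — an
unexpressed aberrant form — and this convention is applied uniformly across
the rank tests, PCA and maxima.

Aberrant junctions are classified against the annotation by which splice
site they share with an annotated intron. A junction sharing its donor and
presenting a novel acceptor within 100 nt is a proximal 3′ aberration (the
hallmark category for this phenotype); the mirror case is proximal 5′;
offsets beyond 100 nt are "distant"; junctions joining two annotated splice
sites of the same gene without being annotated themselves are aberrant-exon
events; junctions with two novel ends or connecting two genes are discarded.
Distances are signed in transcript orientation (negative = upstream of the
canonical site), so the cryptic-acceptor hallmark appears as offsets in
[−30, −10] on both strands. When several annotated partners share the
matched end, the nearest one is used, with ties broken toward the partner
with the higher cohort count when counts are supplied (else the lower
coordinate — a deterministic fallback).

Expression gating uses per-sample quantiles: the CQ (AQ) of a junction's
count is the right-continuous empirical-CDF value of that count within the
sample's observed canonical-junction counts. Ties count as ≤ x, a query of
0 maps to 0, and a query above all canonical counts maps to 1. Defining
both quantile types against the canonical-count distribution makes the gate
comparable across libraries of different depth. Junction selection keeps a
junction when at least one sample satisfies SI ≥ SI_min, AQ ≥ AQ_min and
CQ ≥ CQ_min (defaults 0.15/0.4/0.5, the pan-cohort setting); optional rules
add ubiquitous canonical expression (CQ ≥ 0.3 in ≥ 95% of samples) and a
control-group exclusion for experimental designs (drop junctions whose
canonical partner is unexpressed in controls — median control CQ below the
threshold — or whose aberrant form is already well expressed there — any
control AQ above the threshold). Selection is monotone: raising any
threshold never adds junctions.

## Probe-burden screening

For every aberrant junction the probe is the 40-mer centered on the spliced
joint (20 exonic nt either side) on the mRNA sense strand; identical
sequences from distinct junctions are deduplicated with all source ids
retained. A sample's burden score counts the probes found at least once in
its reads within a Hamming distance of 2 (substitutions only, no indels;
both strands searched since libraries may be unstranded). The default
engine partitions each probe into `max_mismatch + 1` exact seeds; by the
pigeonhole principle any occurrence within the budget contains one exact
seed, so the prefilter cannot miss, and every seed hit is verified by a
full Hamming comparison. A brute-force sliding scan is provided as the
independent oracle; the two are asserted equal in the test suite.

Scores grow with depth, so an OLS fit of score on a coverage proxy (read
count in the synthetic runs; any monotone surrogate such as BAM size works
the same) is computed on the samples strictly below the 99th percentile of
raw scores — boundary ties excluded — and residuals are taken for all
samples as the adjusted burden. If the exclusion leaves fewer than three
samples (a degenerate score distribution) the fit falls back to all
samples. Flagging is inclusive: residual ≥ cutoff, where the cutoff may be
a number or the residual of a named anchor sample (the anchor then flags
itself).

## Phenotype calling

PCA is applied to the column-centered SI matrix of the selected junctions.
Junctions are not scaled to unit variance: SI values already share the
[0, 1] scale, and scaling would inflate the influence of barely-expressed
junctions. The PC1 sign is arbitrary, so it is oriented to correlate
positively with per-sample mean SI (phenotype-positive samples appear at
high PC1). The call threshold is median + 3·MAD of the PC1 scores with the
MAD scaled by 1.4826, the normal-consistency factor and the default of R's
`mad()`. The package deliberately uses the scaled MAD: with the raw MAD the
threshold sits at ≈ 2.0 standard deviations under a normal score null, so
even a perfectly behaved null cohort would have > 2% of samples flagged,
and with realistic coverage heterogeneity (a scale mixture across samples)
we measured ≈ 5%; the scaled MAD puts the threshold at ≈ 3 sigma and the
measured null flag rate at 1–2%. A constant SI matrix makes the
decomposition degenerate: a warning is emitted and no calls are made.

Genotype–phenotype association is a one-sided Fisher's exact test
(enrichment direction) on the 2×2 table of phenotype call × genotype
status, Bonferroni-adjusted by the number of genes screened. Neither the
exact table construction nor the gene-set size is canonical, so both are
caller parameters; the default table counts genotype carriers among
phenotype-positive, mutation-wild-type samples, and the acceptance run
adjusts by a deliberately conservative 10,000-gene factor.

## Two-group similarity protocol

Whether two alteration groups share a splice-aberration pattern relative to
controls is tested per aberration category:

1. **Rank tests.** Per-junction two-sided Wilcoxon rank-sum tests (group A
   vs controls, B vs controls, A vs B). The exact null distribution is used
   when the smaller group has ≤ 10 samples and the pooled values are
   tie-free; otherwise the normal approximation with tie correction. A
   Fisher test compares the observed count of p < 0.05 against the uniform
   expectation (round(0.05·N)), one-sided toward enrichment.
2. **Supervised PCA.** Candidates are the junctions with p < 0.05 against
   controls, deliberately uncorrected — the next step does the filtering.
   Among principal components explaining > 5% of the variance, a component
   is group-associated when its scores separate the altered group from
   controls; "separate" is operationalized as complete rank separation
   (AUC = 1), the strictest reading, because with 5–6 samples per group
   anything weaker is satisfied by chance too easily (the AUC threshold is
   a parameter). Junctions with |Pearson r| > 0.2 against an associated
   component's scores, or |loading| > 0.05 on it, are the group's
   differential junctions. Note that null junctions passing the candidate
   filter by chance genuinely correlate with the associated component, so
   the null selection rate is bounded by, and close to, the 5% candidate
   alpha — this is a property of the protocol, not an implementation
   artifact.
3. **Overlap.** The observed overlap of the two groups' junction sets is
   compared with the random expectation |A|·|B|/U over the universe of all
   tested junctions in the category, via resampling (empirical p with the
   add-one correction, (1 + hits)/(n + 1)) and the closed-form
   hypergeometric upper tail.
4. **Shared/specific classification.** Over the union of selected
   junctions, each group's maximal SI is compared with the control
   quantiles Q95 and Q75 (linear-interpolation empirical quantiles over
   control samples; at least 20 controls required, configurable): shared if
   both maxima exceed Q95; group-specific if one exceeds Q95 while the
   other stays strictly below Q75; not determined otherwise, and excluded
   from shared-fraction summaries.

The classification rule has a structural sensitivity limit worth stating:
when the non-responding group's SI at a junction is exchangeable with the
controls' (the biologically expected situation for a truly group-specific
site — background is background), the probability that the maximum of k
such samples falls below the control upper quartile is ≈ 0.75^k, about 24%
at k = 5. Group-specific calls by this rule are therefore highly specific
but insensitive for small groups, and most genuinely specific junctions
land in "not determined". The synthetic-recovery tests exhibit exactly
this ceiling; shared junctions, whose maxima sit far above Q95 in both
groups, are recovered essentially completely.

Experimental-model helpers follow the same conventions: ΔSI_max =
(max SI_exp − max SI_ctl)/max SI_ctl, undefined (NaN) when the control
maximum is 0; distance histograms over a ±50 nt window with an overflow
bin and a summary fraction in [−30, −10]; out-of-frame classification as
|offset| mod 3 ≠ 0 (uniform offsets on 10–30 nt give 14/21 = 2/3 out of
frame); and replicate-group differential junctions by Welch's t on SI plus
|log2(mean SI ratio)| ≥ 1, with either raw-p (≤ 0.05) or
Benjamini–Hochberg FDR (≤ 0.01) gating.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
real transcriptomes. Genes (default 120, 2–4 exons of 80–200 nt, introns
150–400 nt, both strands) are laid on one contig with 200-nt spacers. Every
canonical intron carries donor/acceptor dinucleotides and a planted cryptic
AG acceptor at an offset drawn uniformly from 10–30 nt upstream of the
canonical acceptor, strand-aware (on the minus strand the acceptor
dinucleotide appears as CT on the reference). The cohort layout defaults to
400 controls plus altered groups of 6 and 5 samples; 90 junctions are
"sensitive", 50 responding in both groups and 20 in each single group.

Counts: canonical-junction totals are negative binomial with mean
(per-junction base expression, lognormal with median 150 and log-sd 0.6) ×
(per-sample library multiplier, uniform on 0.5–2) and dispersion 0.15
(variance μ + 0.15μ²) — the standard overdispersed RNA-seq model; the
aberrant count is a binomial thinning of the total with success probability
equal to the target SI (0.3 in a sensitive junction's responding groups,
0.01 background elsewhere), so the expected SI is exact by construction.
Read-level runs of the burden screen use a background of 0.001 instead:
the probe screen is a presence/absence statistic, and at the default depth
a 1% SI background would make most probes present in every control
library, contradicting the screen's premise that probe sites are
essentially unused in unaltered samples. Reads are junction-spanning
100-mers centered on the splice joint (so each junction's 40-mer probe is
contained verbatim at zero error rate; conservation: one read per counted
split read), plus optional uniform genomic background reads and uniform
per-base substitution errors. One integer seed drives every stage through
named `SeedSequence` substreams, giving byte-identical FASTA/FASTQ/SJ
outputs per seed.

What the generator does not model — and what passing tests therefore do
not show about real data: transcript isoform structure and alternative
splicing beyond single planted acceptors, NMD (which in real tumors
depletes out-of-frame junctions well below the 2/3 expectation),
positional sequencing-error profiles, alignment artifacts, multi-mapping
reads, and inter-gene expression correlation (tissue heterogeneity). The
similarity protocol's robustness to these is inherited from its rank and
quantile constructions, not demonstrated by the synthetic runs.

## Problem sizes and numerical conventions

The test-suite and acceptance runs use the default cohort (411 samples,
~250 junction pairs) for the protocol recovery and null-calibration
checks, three seed-replicates of the control group (1,200 samples) for the
null flag rate, a 40-gene/21-sample cohort for the read-level burden
screen (~70 probes, ~10⁴ reads per sample), 10⁵ resamples for the overlap
test, and 2,000 junctions / 500 replicates for the calibration checks.
Quantiles are linear-interpolation (numpy default) except the CQ/AQ eCDF,
which is right-continuous by definition. PCA is exact (full SVD on the
centered matrix); equality with a direct eigendecomposition is asserted to
1e-8. Fisher and hypergeometric tails are computed by scipy; both are
cross-checked against exhaustive enumeration for small margins.
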