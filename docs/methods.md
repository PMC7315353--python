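# Methods

## The problem being modelled

A feeding knockdown experiment produces small-RNA libraries in which three
read populations coexist: primary siRNAs cut from the fed dsRNA fragment
(often a large fraction of the library), siRNAs from endogenous
siRNA-producing loci, and a large stable remainder of the mapped pool
(degradation products, other sRNA classes, unannotated sources). The
scientific questions are (i) whether endo-siRNA loci lose reads genome-wide
under feeding, (ii) whether phased loci — Dicer-spaced siRNA producers —
lose more when the Dicer gene itself is the target, (iii) whether the
construct has sequence off-targets, and (iv) how the mRNA transcriptome
responds. Every quantity the package reports is defined relative to this
three-population structure.

## Quantification

Reads are filtered to 21–25 nt (inclusive), the siRNA size range; 23 nt is
the dominant endogenous length. An alignment increments a locus when it
overlaps it by at least one base. Multi-mapping is handled by counting each
(read, locus) pair at most once: a read with several alignments inside one
locus contributes one count there, while a read mapping into two loci
legitimately counts in both. The library total *T* is the number of
distinct genome-mapped filtered reads, not alignments, and the
feeding-associated count *K* is the number of distinct reads overlapping
the feeding fragment interval by ≥1 bp. Region strings such as
`scaffold:137857-138267` are parsed as 1-based inclusive and held
internally as 0-based half-open. Spliced or gapped alignments are rejected
with a warning — contiguous alignment is part of what makes a read an
siRNA candidate. Only the fragment interval itself contributes to *K*;
secondary siRNAs flanking the fragment are left in the library (a caller
can widen the interval if they prefer the other reading).

## Normalization

Total count scaling (TCS), `R′ = R·M/T`, rescales every library to the
largest one. In a feeding library this is systematically wrong for
endogenous questions: if a fraction *f* of reads derives from the fragment,
every endogenous count is deflated by (1−f) before scaling, so a true locus
fold change φ is estimated as φ·(1−f). Knockdown-corrected scaling (KDCS)
subtracts the feeding reads from the library size first,
`R′ = R·M/(T−K)` with `M = max(Tᵢ−Kᵢ)`, and recovers φ. Both formulas are
implemented exactly as stated; libraries are normalized within a batch,
by default one serotype's libraries, because the two serotypes are
analysed separately throughout. TCS remains the right tool for exactly one
job — displaying the abundance of the feeding-associated reads themselves —
and the pipeline uses it only there.

## The synthetic generator

The generator's defaults are the study conditions: two serotypes, wild
type plus *ND169* and *DCR1* feeding, expected depth 2×10⁶ mapped 21–25 nt
reads per library, feeding-read fraction f = 0.4 (the real fraction is not
tabulated anywhere; 0.4 is a free parameter chosen once), background share
b = 0.8 of the non-feeding pool, locus depletion 0.5 in feeding
conditions, an extra 0.5 for phased loci under *DCR1* feeding, NB
dispersion 0.05, and mRNA knockdown fold change 0.02.

Per feeding library, `K ~ Binomial(depth, f)`; the remaining
`N = depth − K` reads are split between the background pool and the endo
loci. Locus *i* draws `NB((1−b)·wᵢ·φᵢ·N, α)` with lognormal relative
abundances `wᵢ` (σ = 0.8) shared across libraries. Two deliberate choices
matter:

* **The background absorbs freed capacity.** The background pool's expected
  count is `N·(1 − (1−b)·Σwᵢφᵢ)`, not `b·N`: sequencing fills a fixed
  number of reads, so capacity lost by depleted loci flows into the
  dominant stable pool, and the expected corrected library size T−K is
  condition-stable. This is precisely the regime in which KDCS is unbiased
  (estimates φ) and TCS biased by (1−f); under the alternative
  renormalized-composition model KDCS would estimate φ/(b+(1−b)φ) instead.
* **The background is Poisson, not NB.** It stands in for the aggregate of
  thousands of independent sources, whose sum has negligible
  overdispersion. Modelling it as a few NB loci would give library totals
  a spurious ±6% jitter and destabilize every share-based estimate.

An optional `locus_depletion_sigma` puts a lognormal spread on each locus's
response (shared between the two feeding conditions), emulating
heterogeneous locus sensitivity; it defaults to 0 so the reference
conditions stay exactly as stated, and the bundled analysis study uses 0.5.

mRNA counts are NB around lognormal gene means; in a feeding condition all
genes are scaled by a mild global factor (0.9) and the condition's target
gene additionally by the knockdown fold change. Target-gene counts are
further thinned by the fraction of the gene outside the padded feeding
region, emulating the removal of feeding-associated reads before
quantification; the effective-length TPM correction (below) undoes exactly
this thinning, so the observed fold change estimates the biological one.
The thinning can be disabled (`mrna_region_filtered=False`) to model
unfiltered counts.

Alignment emission materializes every counted read as an error-free
alignment of length uniform in {21…25}, placed uniformly inside its
feature, strand uniform, written as plain SAM. Counting those alignments
returns the simulated matrix, *T* and *K* exactly; this inverse property is
tested and is the package's main end-to-end consistency check. One PRNG
stream per purpose (genome, weights, counts, mRNA, reads), each seeded as
`(seed, fixed offset)`, keeps outputs byte-identical under a seed and
insensitive to unrelated config changes.

What the generator does not emulate — sequencing error, adapter artifacts,
ligation bias, genuine multi-mapping ambiguity from repeated sequence,
isoform structure, autogamy states — bounds what passing tests show: the
statistical machinery is correct under the stated model, not that the model
captures every artifact of real libraries.

## Differential expression

DE runs on raw counts. Size factors are median-of-ratios over features
expressed everywhere; because a genome-wide depletion of *all* tested loci
is exactly what median-of-ratios normalizes away, the pipeline anchors
size-factor estimation on the stable background loci (and, for mRNA, drops
the knocked-down targets from estimation) — the DE-side mirror of the KDCS
rationale. Per feature, a two-group NB log-linear model with known
dispersion is fitted by Newton iteration on the group log-means
(score `Σ(y−m)/(1+αm)`, information `Σm/(1+αm)`); the Wald statistic is the
difference of group coefficients over its standard error from the inverse
information. The fit agrees with an independent GLM implementation of the
same likelihood to three decimals.

Dispersion is where small-sample honesty lives. The plain
method-of-moments estimate `α = max(0, (var−mean)/mean²)` on scaled counts
is exposed as its own operation; used across all libraries it absorbs any
real between-group difference (conservative, caps the attainable |z|),
while used per group at 2–3 replicates its truncation noise makes
normal-reference tests wildly anti-conservative (measured: every one of
100 null datasets produced a BH discovery). The run-level procedure
therefore uses a moderated estimate — a df-weighted average of each
group's raw (untruncated) MoM values, floored at the across-feature
median, so no feature looks quieter than the experiment's typical
dispersion — and refers the Wald statistic to a t distribution with the
residual degrees of freedom. Measured on the reference design: 0/100
global-null datasets with any BH discovery, full power at 4-fold
depletion, and ~45% locus-level yield under heterogeneous 2-fold
depletion. No dispersion trend fitting, shrinkage, Cook's filtering or
independent filtering is attempted, so locus counts from replicate-rich
published analyses are not comparison targets. BH adjustment is the
standard step-up, NaN (untested) features excluded from m. Two contrast
modes exist: all replicates of a condition vs all wild-type replicates
(default), and each knockdown library separately vs the wild-type
replicates, since single-replicate contrasts are statistically fragile but
mirror per-library set-intersection figures.

## Off-target scanning

All `L−k+1` windows (k = 23) of the fragment plus their reverse
complements, deduplicated, are searched for exact, full-length, ungapped
occurrences on the forward genome strand — reverse complements in the
query set make strandedness implicit. "Rest of the genome" means
occurrences overlapping the fragment's own interval are discarded;
excluding the whole host gene is available behind the caller's choice of
excluded intervals. A k-mer occurring exactly once outside the exclusion
is a unique match, and genes overlapping a unique match by ≥1 bp are the
off-target candidates (the permissive "any exact match" reading is a
flag). The scanner is a sliding-window set-membership scan, checked for
exact hit-set equality against a naive per-k-mer substring search on
random genomes with planted copies. The seed-match mode searches positions
2–16 (1-based) of each k-mer, the slicing-competent core of an
Argonaute-loaded small RNA; its hit set always contains the full-length
one. Odd k guarantees no k-mer is its own reverse complement.

## Expression statistics

Gene-level TPM: `rate = count/efflen`, `TPM = rate/Σrate·10⁶`. For a
knocked-down gene in its own feeding condition the padded feeding span
(±100 bp, clipped to the transcript) is excluded and the effective length
floors at 1. Knockdown efficiency is the TPM ratio knockdown/wild-type on
replicate means (undefined when the wild-type TPM is 0). All rank
comparisons are unpaired two-sided Wilcoxon rank-sum tests — exact
enumeration when the pooled sample is ≤25 without ties, normal
approximation with tie correction otherwise, p = 1 for constant pooled
data. "Replicates were merged" is interpreted as averaging normalized
values per condition before comparison. Fold changes of sparse loci use
log2((x+c)/(y+c)) with pseudocount c = 1 normalized unit (configurable).
Library clustering is complete-linkage on Euclidean distances between
library columns, columns sorted lexicographically first for determinism;
merge heights are monotone by construction and the tree is exported as
Newick.

## Problem sizes

The bundled analysis study uses 150 loci, 30 background loci, 18 libraries
at 2×10⁵ reads — rich enough for every statistic to be in its asymptotic
regime while the whole chain reruns in about a minute. The statistical
benchmarks (null calibration, power, clustering recovery) use the
reference 500-locus, 2×10⁶-read design with 3v3 libraries; they run on
count matrices directly and finish in seconds. Test fixtures are smaller
still (24–60 loci, 10⁴–10⁵ reads) since they exercise logic, not
asymptotics.

## Known limitations

Single-isoform gene models only (adequate for organisms with effectively
single-isoform annotation); no weighting scheme for genuinely ambiguous
multi-mappers beyond the once-per-locus rule; the NB Wald test without
shrinkage loses power relative to DESeq2-style moderation at 2 replicates;
phasing labels are consumed, never computed; off-target scanning is exact
full-length matching, not thermodynamic or mismatch-tolerant prediction;
GO enrichment is out of scope.
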