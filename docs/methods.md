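# Methods

This note documents the statistical models behind each pansvkit stage,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the numerical conventions.

## Cohort model

Analyses assume a cohort of unrelated diploid individuals partitioned
into groups (default wild = 20, native = 70, commercial = 41; the
commercial count matches the 41 commercial meat-breed birds of the
motivating design, and the 90 remaining samples are split 20/70 as a
simulation choice). SV genotypes are biallelic dosages in {0, 1, 2} with
missing calls excluded — never imputed — from all allele counts, so a
site's allele number varies with its call rate. The "derived" allele is
identified with the ALT (non-reference) allele throughout: true
polarization would need an outgroup the pipeline does not model. θ̂ and
|ΔAF| are invariant to this choice; only the increased/decreased labels
depend on it, and they should be read as "ALT-frequency increased".

## PAV calling and pan-genome modeling

Presence rule: a gene is present in a sample iff
(Σ exonic bases with depth ≥ 2) / (Σ exonic lengths) > 0.05, pooled over
exons. The inequalities at 5% (and at the 99%/1% class boundaries) are
strict; boundary cases fall to the lower class. The pooled-bases
interpretation of "5% of all exons" is the default because it is robust
to unequal exon lengths; a per-exon-count mode (> 5% of exons touched)
is available via `mode="per_exon"`.

Occupancy classes partition genes by presence frequency f: core (f = 1),
softcore (0.99 < f < 1), shell (0.01 ≤ f ≤ 0.99), cloud (f < 0.01).
Pan/core trajectories average the union/intersection gene counts of the
first x genomes over n_orders = 100 random orderings (the mean curve is
seed-invariant to < 0.5% per point at n_orders = 500). Curves are fitted
by bounded multi-start least squares — A free in sign, B ∈ [−5, 5],
C ≥ 0, a deterministic grid of starts, best residual sum of squares wins
— for the pan power law y = A·x^B + C and the core exponential
y = A·e^{Bx} + C. The power law is the standard pan-genome growth model;
B < 0 flags a closed pan-genome with C the estimated total gene count.
An exclusion-list parameter supports dropping sex-chromosome genes from
the modeling.

## Selection scan

Each SV is tested for frequency differentiation between the two groups
of a contrast with a two-sided Fisher exact test on the 2×2 allele-count
table (derived vs other × group). Two-sidedness is by hypergeometric
probability mass — every table with the same margins whose probability
does not exceed the observed table's contributes — computed in exact
integer arithmetic, which agrees with brute-force enumeration to the
last bit and avoids the floating tie tolerances of library
implementations. Allele counts (not genotype counts) are the default
table, treating the two alleles of an individual as independent, as
implied by comparing allele frequencies; a carrier/non-carrier genotype
table is available.

Multiplicity is controlled with Benjamini–Hochberg at FDR 0.001 (the
procedure behind a bare "FDR" requirement). In parallel, per-SV
Weir–Cockerham (1984) θ̂ = a/(a+b+c) is computed from per-group called
sample counts, ALT frequencies and observed heterozygote frequencies;
monomorphic sites (a+b+c = 0) and sites with < 2 called samples in a
group are undefined and excluded. An SV is *selected* iff q ≤ 0.001 AND
θ̂ reaches the empirical 99th percentile of the contrast's defined θ̂
values (the "top 1%" rule, computed per contrast). Note the estimator's
finite-sample behaviour: for two identical Hardy–Weinberg groups of n
samples θ̂ = −1/(2(n−1)), not 0; it is exactly 0 when the observed
heterozygosity equals 4p(1−p) (e.g. two identical all-heterozygote
groups), and exactly 1 at an opposite fixed difference.

|ΔAF| ranking takes a declared region, computes |AF_hi − AF_lo| per
variant and sorts descending with ties broken by ascending position, so
output is deterministic.

## TE–SV association

Per-SV overlap statistics use the merged union of TE spans, making the
coverage fraction invariant to annotation fragmentation. Classes:
partial (> 0 overlap), high (fraction ≥ 0.5, "at least half of the
sequence"), and intact-derived. Overlap-class summaries are reported for
SVs > 100 bp; insertions have no reference footprint and are excluded.
Intact-derived matching requires reciprocal overlap strictly > 0.95 with
a single intact element — both overlap/len_SV and overlap/len_TE — since
"derived from" an element implies near-coincident spans, and a one-sided
rule would mis-call small SVs inside long elements (a one-sided mode
exists behind a flag).

Co-occurrence: each chromosome is tiled into non-overlapping windows of
2/5/10 kb (last partial window kept); a window holds a feature at ≥ 1 bp
overlap; the 2×2 occupancy table is tested with Pearson's χ² without
continuity correction (window counts are in the thousands; a Yates
option exists). Odds ratios use a 0.5 Haldane correction when a cell is
zero; a zero margin leaves the test flagged undefined.

Context assignment is strand-aware: gene_body if the SV overlaps a
gene's exon-spanning extent, else upstream5k if within 5 kb 5′ of a TSS
on that gene's strand, else intergenic; gene_body takes precedence.
Nearest genes are chosen by minimal edge-to-edge distance (0 on
overlap), ties to the lower gene start.

## LTR insertion dating

The two LTRs of a retroelement are identical at insertion; their
divergence dates it as T = K/(2r), r = 1.91×10⁻⁹ per site per year by
default. Pairs are globally aligned (match +1, mismatch −1, gap −2);
columns containing a gap or N are excluded from numerator and
denominator; at least 50 ungapped columns are required. K is
JC69-corrected by default, K = −(3/4)·ln(1 − 4p/3), undefined at
p ≥ 0.75; raw-p and Kimura two-parameter models are selectable and the
model is recorded in the output. JC69 is the simplest model consistent
with dating by LTR sequence homology; on 10 kb simulated pairs the
estimate lands within 3 binomial standard errors of the true K in
≥ 95% of replicates across K ∈ {0.001, 0.005, 0.02}.

## Sweep statistics and single-marker association

π is the per-site unbiased heterozygosity 2p̂(1−p̂)·n/(n−1) summed over a
window's segregating sites and divided by window length (a site-count
denominator is available; whether to normalise by physical length or
callable sites is a genuinely open convention). Tajima's D follows the
1989 normalization D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1)) and is undefined at
S = 0. Diploid genotypes are used as 2n unphased alleles for both
statistics — valid for frequency-based quantities, an approximation for
k̄ under linkage. Windowed F_ST is the ratio of sums Σa / Σ(a+b+c) of
per-site Weir–Cockerham components, the standard windowed estimator; it
reduces to the single-locus θ̂ for a one-site window. Window presets:
20 kb / 20 kb step for π and F_ST (non-overlapping, last partial window
kept), 10 kb / 5 kb for Tajima's D (full windows only).

The association model is ordinary least squares y = μ + β_sex·sex +
β_g·g with the marker coded additively 0/1/2 (a 2-df genotype-class
model is optional); the marker's p-value is the F-test against the
sex-only model and marker R² = (RSS_reduced − RSS_full)/TSS, the marker
sum of squares after all other terms over the total sum of squares.

## Synthetic cohorts: what they emulate, and what they do not

All generators draw from one integer seed through named SeedSequence
substreams; outputs are byte-identical given the seed.

- **Genotypes.** Null SVs share one Beta(0.5, 0.5) allele frequency
  across groups (a U-shaped frequency spectrum, so the MAF ≥ 0.01 filter
  does real work); planted SVs carry explicit per-group triples, the
  defaults mirroring near-fixed improvement loci (native 0.89 vs
  commercial 0.012; 0.93 vs 0) and two domestication shifts. Dosages are
  Binomial(2, AF) per sample: Hardy–Weinberg within groups, no linkage
  disequilibrium between sites — the simplest null consistent with
  per-SV tests. Real cohorts have LD, relatedness and genotyping error,
  so passing tests show correctness of the statistics, not robustness to
  those artefacts.
- **TE landscape.** TEs are placed uniformly (lognormal lengths,
  class labels with vertebrate-like weights; 15% of long LTR elements
  flagged intact with 250 bp terminal repeats). An SV start falls inside
  a random TE-occupied 2 kb window with probability ρ (default 0.5,
  a positive association of the strength the analysis is meant to
  detect), else uniformly; ρ = 0 gives exact independence, which is what
  the χ² calibration tests exploit. A fraction (default 5%) of SVs copy
  an intact element's span with ≤ 1% per-edge jitter, guaranteeing
  > 95% reciprocal overlap.
- **Coverage.** Present genes are covered at the sample's depth
  (mean 45×, mild lognormal sample variation); per-exon counts of bases
  at depth ≥ 2 are Binomial at the Poisson tail probability. Absent
  genes receive background mis-mapped coverage over a small fraction
  (default 3%) of exonic bases rather than a uniform thinned Poisson: at
  45×, a uniform background of 5% of the depth would put ~66% of bases
  above 2 reads and make every absent gene look present, whereas real
  mis-mapping is patchy — concentrated in short homologous segments.
  The 3% patch fraction sits deliberately near the 5% calling threshold
  so the rule is actually exercised.
- **Gene classes.** 97.67% of genes are core (always present);
  dispensable genes are softcore (presence probability 0.995) or shell
  (uniform 0.05–0.95) in roughly the 26/74 split of dispensable genes
  seen in closed avian pan-genomes.
- **LTR pairs.** Each copy of a 1 kb seed sequence receives independent
  substitutions at per-site probability K/2 (random target base), so the
  expected pairwise divergence is K − K²/3 ≈ K; default K values 0.002292
  and 0.014823 correspond to insertion ages of 0.6 and 3.88 Myr at the
  default rate. K > 0.75 is rejected (outside JC69 validity).
- **F2 phenotypes.** Marker genotypes segregate ¼:½:¼; with Var(y)
  scaled to 1 the additive effect is a = √(2v) (marker variance a²/2 = v,
  default v = 0.2761), sex explains 10%, and the residual takes the
  remainder. The fitted marker R² recovers v in expectation.
- **Window haplotypes.** Segregating sites draw derived-allele counts
  ∝ 1/i (the neutral frequency spectrum) at distinct uniform positions —
  no coalescent tree, so site frequencies are exchangeable and D has no
  linkage-induced variance structure.

## Problem sizes and numerical choices

The packaged demo runs 1000 SVs × 131 samples on a 2 × 5 Mb genome with
400 genes, 500 TEs and 6 LTR pairs; replicated checks use 20 null
cohorts, 200 co-occurrence replicates per condition, 100 LTR replicates
per K and 20 F2 cohorts. These sizes were chosen so the complete
analysis reruns from scratch in about a minute on one CPU while leaving
every statistic's sampling error well inside its decision margin.
Fisher p-values and the curve fits are deterministic; all simulation
randomness flows from explicit seeds; quantile thresholds use numpy's
default linear interpolation; ties in rankings are broken by genomic
position. Degenerate inputs (monomorphic sites, empty windows, zero
margins, saturated divergence) are reported as missing/flagged rather
than silently dropped, and strict thresholds never reclassify boundary
cases upward.

## Known limitations

No LD-aware statistics (haplotype scans such as XP-EHH are out of
scope); no kinship or structure correction in the association model; no
multi-allelic SVs (the reader rejects them with a warning rather than
guessing semantics); insertions are excluded from reference-coordinate
overlap statistics; LTR dating assumes a strict molecular clock and
ignores gene conversion between LTRs, which compresses apparent ages of
old elements in real data.
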