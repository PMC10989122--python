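# pansvkit

Population-genomic analysis of structural variation (SV) against a
pan-genome reference, for cohorts of resequenced individuals stratified
into wild, native (landrace) and commercial groups — the setting of duck
domestication studies, where transposable-element (TE) derived SVs near
genes such as *IGF2BP1* and *MITF* drive bodyweight and plumage traits.

The package implements the full analytical stack downstream of read
alignment and SV calling:

- **Gene presence/absence (PAV) and pan-genome modeling** — a gene is
  present in a sample when > 5% of its exonic bases carry ≥ 2 reads;
  presence frequencies classify genes as core (f = 1), softcore
  (0.99 < f < 1), shell (0.01 ≤ f ≤ 0.99) or cloud (f < 0.01); pan and
  core growth curves over random genome orderings are fitted with
  y = A·x^B + C (power law) and y = A·e^{Bx} + C, with C the estimated
  pan-genome size when B < 0 (a closed pan-genome).
- **SV selection scans** — per-SV two-sided Fisher exact tests on derived
  (ALT) allele counts between groups, Benjamini–Hochberg FDR at 0.001,
  intersected with the top 1% of Weir–Cockerham (1984) single-locus
  F_ST (θ̂ = a/(a+b+c)); directions label frequency increase/decrease
  along the wild → native (domestication) and native → commercial
  (improvement) contrasts. |ΔAF| ranking identifies the top candidate
  variant in a region.
- **TE–SV association** — χ² tests of TE/SV co-occupancy of 2/5/10 kb
  genomic windows; per-SV TE-overlap classes against the merged TE track
  (≥ 50% overlap = "high"); intact-TE-derived SVs matched by reciprocal
  overlap > 95%; genomic context (gene body / 5 kb upstream of the TSS /
  intergenic) and nearest-gene assignment.
- **LTR insertion dating** — divergence K between the two terminal
  repeats of an intact LTR element (global alignment, JC69 correction)
  dates the insertion as T = K/(2r) with r = 1.91×10⁻⁹
  substitutions/site/year.
- **Sweep statistics and association** — windowed nucleotide diversity π,
  Tajima's D (10 kb / 5 kb), and ratio-of-sums windowed F_ST
  (20 kb / 20 kb); single-marker general linear model y ~ sex + marker
  with marker R² = marker sum of squares after all other terms divided by
  the total sum of squares.
- **Synthetic cohorts** — `pansvkit.simulate` generates every input with
  known ground truth (planted allele-frequency triples, TE co-placement
  strength ρ, intact-derived SV copies, LTR pairs at known K, ~45×
  coverage with gene dropout, an F2 phenotype with known marker variance
  fraction), so every stage is testable without any data download.

Inputs are standard formats: VCF 4.x (SVTYPE/SVLEN/END + GT), BED, GFF3,
FASTA, TSV tables. Internally all coordinates are 0-based half-open.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated 131-duck cohort (20 wild, 70 native, 41 commercial; 1000 SVs
with four planted selection signals):

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_selection_scan.py
```

prints

```
1000 SVs, 875 after MAF >= 0.01
domestication (wild -> native): 2 selected SVs (1 increased, 1 decreased); planted recovered: ['SV00600', 'SV00938']
improvement (native -> commercial): 2 selected SVs (0 increased, 2 decreased); planted recovered: ['SV00143', 'SV00474']
dAF in chr2:3286317-3306558: 3 variants; top |dAF| = 0.921 at SV00143 (planted: True)
```

i.e. exactly the four planted frequency shifts are called selected, in the
contrast where they were planted, and the near-fixed native-vs-commercial
deletion tops the |ΔAF| ranking of its region — the analytical signature
of a large-effect domestication/improvement locus. The remaining drivers
report PAV classes and the pan-genome asymptote (`02`), TE–SV
co-occurrence χ² and intact-derived matching (`04`), LTR ages for the two
planted divergence classes, ~0.6 and ~3.9 Myr (`05`), the windowed F_ST
peak over the planted locus (`06`), and the F2 marker association,
R² ≈ 28% of phenotypic variance (`07`).

Library use mirrors the drivers:

```python
from pansvkit import io, selection

matrix = io.read_sv_vcf("svs.vcf")
meta = io.read_sample_metadata("groups.tsv")
res = selection.scan_selection(selection.maf_filter(matrix), meta,
                               ("native", "commercial"))
print(res[res.selected])
```

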