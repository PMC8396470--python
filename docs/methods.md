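# Methods

This note documents the models implemented in `bulkmap`, the defaults and the
reasoning behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## The cross and phenotype model

Both parents are doubled haploids, hence fully homozygous; they differ at
genome-wide marker SNPs, at mutagenesis-induced variants private to the
mutant parent, and at one planted causal SNP. Every F1 is heterozygous at
every segregating site; F2 gametes are produced under the Haldane model —
crossover count per chromosome ~ Poisson(genetic length in Morgans), uniform
crossover placement, no interference. The default genetic map is 2 cM/Mb
uniform, a typical average recombination rate for a crop genome; none is
dictated by the study system itself.

Plant height follows a one-locus semi-dominant mixture: height ~
Normal(μ_g, σ_g) with g the causal genotype. Defaults (cm):

| genotype       | mean  | SD   | provenance                                   |
|----------------|-------|------|----------------------------------------------|
| dwarf homozygote | 86.8  | 4.9  | observed mutant line                         |
| heterozygote     | 152.1 | 12.0 | observed F1 mean; SD = (range 121–167)/4     |
| tall homozygote  | 198.7 | 15.9 | observed background line                     |

The heterozygote SD is unreported anywhere, so the range/4 heuristic on the
observed F1 range is used. The ordering μ_dwarf ≤ μ_het ≤ μ_tall is enforced;
equality is allowed deliberately — a flat phenotype model makes the bulks
uninformative of genotype and is how the null-calibration experiments remove
the causal signal without changing any other machinery.

Bulks are chosen by rank, not threshold: the `bulk_size` shortest plants form
the dwarf bulk and the tallest the wild-type bulk, ties broken by plant id.
This guarantees the design's bulk size (30 of 300 by default) even under
unlucky phenotype draws. Parental pools are clonal (20 plants each), so their
allele frequencies are exactly 0 or 1 before sequencing noise.

## Sequencing model

Per site and pool, depth ~ Poisson(λ, default 50) and alt reads ~
Binomial(depth, f(1−e) + (1−f)e) with f the pool allele frequency and e a
per-read miscall rate (default 10⁻³). These are ordinary resequencing values;
both are configurable. Zero-depth sites are emitted as (0, 0) and become
missing downstream.

The reference sequence is defined as the wild-type parent genome, so the alt
allele of every segregating variant is the mutant-parent allele and
Δ(SNP-index) is positively polarized at the causal locus. Residual parental
heterozygosity is emulated by "artifact" sites sequenced at frequency 1/2 in
the affected parent pool and 1/4 in both bulks; these exist to exercise the
heterozygosity/consistency exclusion rules, which would otherwise be
vacuous under the doubled-haploid assumption.

## Synthetic genome and the planted causal SNP

Each chromosome (3 × 10 Mb by default) carries equally spaced genes (12 per
chromosome) with a fixed architecture: 120 bp 5′UTR, CDS exons of
150 + 300 + 750 bp separated by two 250 bp introns (GT…AG), 150 bp 3′UTR;
strands alternate. CDSs are stop-free random codons with ATG/TAA ends. The
causal gene carries the degron codon block GGA-TGG-CCA-CCA-GTC (GWPPV)
starting at codon 84, and the causal SNP is a G→A substitution at the middle
base of that Gly codon — GGA>GAA, Gly→Glu, amino-acid change G84E, motif
GWPPV → EWPPV. Codon 84 sits in the second CDS exon, consistent with the
gene structure the analysis is meant to recover.

What the generator does **not** emulate: read-level FASTQ data, alignment and
base-quality artifacts, structural variants, polyploid homeolog
cross-mapping, segregation distortion, and non-uniform recombination maps.
Passing tests therefore demonstrate correctness of the statistics and the
isolation logic under the stated sampling model, not robustness to alignment
or calling artifacts in real pooled sequencing.

## Segregation testing

Heights are classified tall (≥ 170 cm), semi-dwarf, dwarf (≤ 110 cm);
boundary values belong to the extreme classes so the classes are mutually
exclusive; the cut-offs are exposed as parameters. The χ² goodness-of-fit
statistic is uncorrected (no Yates continuity correction — the published
statistics are only reproduced without it); classes with zero expected ratio
are dropped from the statistic and the degrees of freedom, and observed
counts in such a class are a qualitatively different "ratio violated"
outcome rather than a large statistic. Expected counts may be derived from a
stated population size larger than the classified total (`total=`), because
a scored population can contain plants that fit no height class; the F2 of
this study system is such a case (566 classified of 576 scored).

Model selection evaluates the candidate ratios {1:0:0, 0:1:0, 0:0:1, 1:2:1,
1:1:0, 0:1:1, 3:0:1, 1:0:3} at α = 0.05; the verdict "single semi-dominant
gene" requires the F2 to be consistent with 1:2:1 and each supplied
backcross with its 1:1 expectation. Both backcross directions are labelled
explicitly as (F1 × wild-type) and (F1 × mutant) because published labels
for backcross families are easy to transpose.

## Δ(SNP-index) scan and the null band

Per-site indices are alt/(ref+alt), undefined at zero depth. Sites below a
minimum depth (default 8 in either bulk) are excluded from windows. Windows
are 1 Mb sliding by 100 kb (QTL-seq practice scaled to the synthetic
genome), half-open, with at least 5 usable sites; sparser windows propagate
a missing mean and can never be significant.

The 95% band is an empirical Monte-Carlo null: each bulk draws `bulk_size`
unselected F2 genotypes i.i.d. 1:2:1 (equivalently, a pooled allele count ~
Binomial(2·bulk, ½)), forms the pool allele frequency, and is re-sequenced
as Binomial(depth, f); the band is the (2.5%, 97.5%) quantile pair of the
resulting Δ over 10⁴ replicates, tabulated per integer depth and linearly
interpolated. A backcross design flag switches the genotype probabilities to
1:1. Windows are judged at their median site depth, where a site's depth is
the harmonic mean of its two pool depths — the harmonic mean matches the
read-noise variance of the equal-depth null exactly.

Peak regions are runs of ≥ 3 same-direction significant windows, allowing
gaps of ≤ 1 window; bounds are the union of member windows; output BED is
0-based half-open.

A calibration caveat: the band is a marginal, per-site 95% statement. Its
empirical check (5% ± 1% of null sites outside the band) requires
effectively unlinked sites; physically linked sites share one bulk-genotype
draw, so the realized outlier fraction of a single cross fluctuates far
beyond ±1% without any miscalibration. The calibration experiments therefore
stretch the genetic map until adjacent sites are > 1 Morgan apart.

## Effect annotation

Region precedence on overlap: splicing > exonic (CDS) > UTR5/UTR3 >
intronic > upstream/downstream > intergenic. "Splicing" means within 2 bp of
an intron boundary, or spanning an exon–intron junction; flanks default to
2 kb. These mirror common annotator defaults; the precedence order is this
package's own, as is the convention that "exonic" denotes CDS overlap (UTRs
are reported separately). Coding consequences translate the spliced,
strand-oriented CDS with the standard nuclear code; indels are frameshift
unless the length change is a multiple of 3; a REF allele that contradicts
the reference sequence is a hard data-integrity error. The degron screen
reports the GWPPV motif as intact, altered (with the mutant motif string) or
absent.

## Candidate isolation

Genotypes are called from pooled depths: missing below depth 8, hom-ref at
alt fraction ≤ 0.1, hom-alt at ≥ 0.9, het otherwise (all configurable —
the isolation strategy is stated on genotype states, and pooled calling is
necessarily a thresholding decision). The four exclusion rules, applied in
fixed order with all violations reported:

* R1 — wild-type parent **or** tall bulk heterozygous ("or" is the stricter
  reading of an ambiguous conjunction; a "both" mode is provided);
* R2 — wild-type parent and tall bulk inconsistent (inequality of
  categorical calls, the simplest faithful reading);
* R3 — the two bulks identical;
* R4 — mutant parent heterozygous.

A variant with any missing call is excluded with a distinct reason code
(conservative). The kept/excluded outcome is a pure function of the four
states, so rule order can never change the verdict.

Shortlisting restricts kept variants to peak regions and ranks
protein-changing variants (missense, nonsense, frameshift, in-frame indel)
ahead of splice-region and regulatory-region variants — the isolation
strategy targets mutations that directly affect the protein — and within a
class by |windowed Δ| at the variant (rounded to 0.01 to merge local noise),
then per-site |Δ|, then position. Windowed Δ at a position is interpolated
between window centers.

The expression screen keeps genes with FDR < 0.05 (strict) and |log2FC| ≥ 3
(inclusive); the fold-change threshold corresponds to an 8-fold linear
change.

## AS-PCR marker design

The allele-specific primer ends exactly on the SNP (3′-terminal base = the
targeted allele) and carries one artificial mismatch at the third base from
the 3′ end, substituted by a fixed strong-destabilizing transversion map
A↔C, G↔T (the map is a design choice and overridable; the SNP base counts
as position 1). The common primer's 5′ end is placed so the amplicon length
equals the request exactly (product length = distance between primer 5′
ends + 1). Primer lengths are adjusted within 18–30 nt to meet a Wallace-rule
(2AT + 4GC) melting temperature of 55–65 °C; homopolymer runs ≥ 6 under a
primer reject the design. The in-silico annealing model requires the
3′-terminal base to match exactly and tolerates at most one mismatch within
the terminal three bases — so the targeted allele extends past its single
engineered mismatch while the wrong allele, carrying two terminal
mismatches, fails. This is a deliberate simplification standing in for
nearest-neighbor thermodynamics; it reproduces the qualitative behaviour of
AS-PCR (mutant-only amplification of the designed product).

## Problem sizes and determinism

Default experiments use 3 × 10 Mb chromosomes, 600 marker SNPs, 60 induced
mutations, 30 artifact sites, an F2 of 300 with bulks of 30, and ~50×
pooled depth; one end-to-end run takes well under a second after warm-up,
and the multi-seed recovery experiments (50 crosses) about half a minute.
All randomness flows through a single `numpy` Generator seeded from the
configuration, so every result in the documentation and tests is exactly
reproducible.

## Known limitations

* The null band models bulks as i.i.d. draws from the F2 genotype
  distribution; the real bulks are drawn without replacement from one finite
  population, which shrinks the genotype variance slightly (the empirical
  outlier rate sits a few tenths of a percent below 5%).
* Candidate ranking can tie when a linked non-causal variant lands in the
  same window with an equally extreme Δ; a marker-derived missense within
  the peak can then out-rank the causal variant (observed in roughly one of
  fifty simulated crosses). Real studies resolve such ties with biological
  evidence, as the degron-status column is meant to support.
* The annotator handles one transcript per gene and the standard nuclear
  code only; it classifies but does not score regulatory variants.
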