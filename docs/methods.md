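# Methods

This note documents the models, procedures and numerical choices behind
`dsnchip`: what each stage computes, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely open.

## Data model and conventions

Variants are biallelic (multiallelic VCF sites are excluded on input, with a
count). Coordinates are 1-based inclusive, matching VCF; any BED output is
converted to 0-based half-open at the writer. Indel alleles are trimmed to
minimal representation on input (shared suffix first, then shared prefix);
full left-alignment across repeat tracts would need the reference sequence,
which the pipeline does not carry — distances between variants are
differences of (trimmed) start positions.

Allele frequencies are alternative-allele frequencies (AAF). Missing
genotypes are excluded from both numerator and denominator — the standard
population-genetics convention. A breed with no observed genotypes at a
variant has an *undefined* AAF (`nan`), deliberately distinct from 0: the
breed-uniqueness rule needs "observed absent" versus "never observed", and an
undefined AAF is never silently coerced to 0. A comparison breed with an
undefined AAF does not veto uniqueness; a variant with no defined comparison
AAF at all is conservatively not called unique.

## Technical-suitability filters

Run in a fixed order, each producing an accounting record
(`n_out = n_in − n_removed` by construction):

1. **Neighbourhood**: a variant is removed when another variant (surviving
   or not) lies within its probe window. The default window removes at
   distance ≤ 35 bp (36 bp survives); variants headed for the high-value
   categories (GWAS, impact, breed-unique) use a stricter 20 bp window that
   *tolerates* a neighbour at exactly 20 bp (removal only below 20 bp). The
   asymmetric boundary follows the two rules' phrasing: "within 35 bp …
   removed" versus "allowing an interfering variant located 20 bp up- or
   downstream".
2. **Depth**: total read depth across animals must reach 10 × the expected
   carrier count — all animals on autosomes/X (or an absolute override such
   as 3000), males only on Y, since only males carry Y reads. Missing depth
   fails.
3. **AAF with rescue**: keep when AAF_focal ≥ 0.05, or when
   AAF_focal > 0.01 and the variant is either focal-unique or common
   (AAF > 0.05) in a configured rescue breed. Y and mitochondrial variants
   are exempt: their selection categories take every detected variant, so
   frequency-filtering them would empty categories whose point is
   completeness.
4. **p-convert**: the better strand must score ≥ 0.6 (boundary inclusive);
   variants without scores fail.

## Two-locus LD and haplotype blocks

Haplotype frequencies for a pair of biallelic loci are estimated from
unphased genotypes by EM over the two-locus multinomial likelihood. Only the
double-heterozygote class is phase-ambiguous; allele counts are fully
observed, so the frequency margins stay at the sample allele frequencies and
EM moves a single degree of freedom (the coupling-haplotype frequency).
Convergence: max-abs change < 1e-8 or 1000 iterations; three starts (double
hets split 5/50/95 % toward coupling) guard against boundary stagnation,
with the best log-likelihood kept.

D′ uses the absolute-value convention, |D|/D_max ∈ [0, 1];
r² = D²/(p_A(1−p_A)p_B(1−p_B)). The 90 % confidence interval on |D′|
follows the Gabriel/Haploview construction: the likelihood is evaluated on a
101-point grid over [0, 1] (step 0.01, configurable), with allele
frequencies held at sample estimates and the sign of D fixed at the point
estimate's; the normalised likelihood is treated as a distribution and the
5th/95th percentiles reported. A pair is undefined when either locus is
monomorphic among shared non-missing animals — the scalar API raises
`LDUndefinedError`, the batched API returns a `defined` mask, and callers
never propagate NaN.

**Blocks** (Gabriel criterion): within 200 kb windows, a candidate span is a
block when ≥ 95 % of its informative pairs show strong LD (CI lower bound
≥ 0.60 and upper bound ≥ 0.85). Informative pairs are those classified
strong LD or strong recombination (CI upper bound < 0.90); pairs with fewer
than 5 shared informative animals are non-informative. The thresholds 0.60
and 0.85 are the design's working values; the recombination bound, the 0.95
fraction and the 5-animal floor are the published Gabriel/Haploview
defaults, since the block definition leaves them open — all are fields of
`BlockConfig`. Overlapping candidate spans are resolved longest-span-first,
leftmost on ties, so output blocks never share a variant; spans with zero
informative pairs are never blocks.

Implementation note: the batched path deduplicates identical 3×3 genotype
count tables (block-structured data repeats them heavily) and solves each
distinct table once in a compiled kernel; the scalar numpy path implements
the same mathematics independently and the test suite asserts the two agree
to 1e-9.

## Category selection

Ten categories in fixed order; a variant selected by an earlier category
still counts in a later category's *total* but its *unique* attribution
stays with the earlier category, so unique counts sum exactly to the chip
size. Details that the ordered list leaves open:

* **Complete-LD pruning** (categories 3 and 4): "complete LD" is r² = 1
  within 1e-9 on EM haplotype frequencies (a D′ = 1 alternative is a config
  switch). Groups are connected components of the complete-LD graph among
  one block's members; at most two survive per group, counting members
  already selected by earlier categories toward the cap, survivors chosen in
  genomic order. Pruned variants leave these categories but remain available
  as gap fillers. Pruning can never strip a block's sole representative,
  because singleton groups are untouched and larger groups always keep two.
* **Category 9 (block tagging)** considers blocks not yet covered by any
  selected variant, restricted to spans > 5 kb, or > 1 kb when within
  100 kb of a coding gene (gene annotation optional; without it only the
  5 kb clause applies). One variant per block, by lexicographic priority:
  empirical-evidence flag, better-strand p-convert, MAF > 0.05 indicator,
  |AAF_focal − AAF_reference|; ties broken by position then id. The
  category's *total* additionally counts one representative per eligible
  block already covered by earlier categories, so the total reads as "blocks
  covered by the chip".
* **Category 10 (gap filling)** is greedy: repeatedly take the longest
  remaining inter-variant gap > 250 kb that contains a surviving candidate,
  insert the candidate closest to the gap midpoint, re-split, and stop when
  every remaining over-limit gap is empty of candidates. Afterwards, any
  residual gap > 250 kb provably contains no technically suitable candidate
  (asserted by scan in the tests).
* **Probesets**: one per variant; two for A/T and C/G SNPs (invisible to a
  two-dye system with a single probeset); variants unique to category 2 and
  not derived from imputed data have their probesets doubled (the replicate
  factor is configurable — the source design reports only that such
  oligonucleotides were "added multiple times", so its printed probeset
  total is not exactly reconstructable). The default capacity of 210,000
  represents a 200k-class array's loose probeset ceiling; exceeding it
  raises an error with the overflow count.

Everything is deterministically ordered (position, then id), so identical
inputs and configuration reproduce byte-identical designs.

## Evaluation

Call confidence is 1 − genotype-cluster probability (0 best). QC masks
calls with confidence > 0.05 *before* computing the per-variant call rate,
which must strictly exceed 0.95 ("had to exceed"; an inclusive switch
exists). "Called in at least one breed" runs QC per breed — each breed's
own animals as denominator — and takes the union. Segregating variants are
successfully called with MAF strictly > 0.01 in the target population,
computed from masked calls. Concordance compares hard genotype codes over
positions non-missing in both members of a pair; pairs with zero comparable
calls are reported undefined and excluded from the mean; the summary SD uses
n−1 by default (a config switch selects n). Percentages in accounting
tables are rounded half-up to two decimals, and empty strata report None
rather than 0 %. The failing-variant LD summary pairs each failed assay with
the nearest successfully called variant in its haplotype block (fallback:
nearest on the chromosome) and reports mean ± SD of D′ and r² computed from
the sequencing genotypes. MAF histograms use 0.05 bins with the lowest bin
starting at 0.01.

## Synthetic cohort generator

The generator reproduces the structure the pipeline assumes, at desk scale.
Defaults: two breeds (focal + one close comparison) × 100 animals, one 5 Mb
chromosome at 1 variant/kb (~5000 variants), LD segments with
gamma-distributed lengths (shape 2, mean 10 kb), 10 % indels, 10 % of
variants private to the focal breed, fold coverage Normal(18.72, 2.44²)
truncated at 1 drawn once per animal with per-variant Poisson depths,
impact-class proportions 97.17/2.19/0.60/0.04 %, and p-convert as a mixture
(80 % Beta(24, 3), concentrated near 0.9; 20 % uniform on [0.3, 0.8]).

Within each LD segment, every animal's two haplotypes are drawn from a pool
of 2–4 founder haplotypes (founder alleles Bernoulli at a Beta(0.5, 1.5)
target frequency, forced polymorphic within the pool), with breed-specific
Dirichlet pool weights; segments recombine freely. This haplotype-pool
construction was chosen over coalescent simulation because it is
dependency-free and gives direct control of block boundaries for oracle
tests. The Beta AAF spectrum is a generator parameter, not a claim about any
real population's site-frequency spectrum.

Two small corrections keep the designated-unique set exactly equal to the
uniqueness-classification truth: designated-unique variants receive enough
focal carriers to clear the presence threshold (alt count such that
AAF > 0.01), and non-unique variants whose alt allele drifted to zero in a
comparison breed while present in the focal breed get one planted carrier
there. Without the second rule, random drift would create accidental
"unique" variants and the generator's truth labels would be wrong.

The chip-run simulator draws variant-level failure with probability
base + slope·max(0, 0.7 − p-convert) + penalty·max(0, 1 − MAF/0.05) —
failures enriched just above the 0.6 score floor and at rare alleles, whose
small unsharp genotype clusters are the hard case for cluster-based calling.
Failed variants emit no calls (confidence 1). Per-call corruption replaces a
genotype with one of the other two codes uniformly (default rate 0.002, with
the same rare-allele penalty as a multiplier), so sequencing-vs-chip
concordance has expectation exactly 1 − rate. Confidences are Beta(1, 200)
for clean calls (essentially never masked) and diffuse Beta(2, 6) for
corrupted ones. Replicated animals receive independent corruption and
confidence draws in separate batches.

What the generator does **not** emulate: read-level errors (no FASTQ, no
sequencing-error model), pedigree structure, genuine coalescent LD decay
within segments, chromosome-specific variant density, X/Y dosage in
genotypes (sex chromosomes are simulated like autosomes when requested), or
batch effects beyond independent replicate draws. Passing tests therefore
demonstrate the pipeline's correctness and internal consistency on
block-structured data, not calibrated performance on real sequencing
cohorts.

## Problem sizes in the test and acceptance runs

The acceptance suite exercises the design engine on twenty seeded cohorts at
the default scale (2 × 100 animals, 5 Mb, ~5000 variants), the LD oracles on
pairs of ≤ 30 animals and exhaustive block enumeration on 8-SNP instances
over 50 seeds, block-boundary recovery on 1 Mb cohorts with two founder
haplotypes per segment (the high-LD regime the recovery claim is about), and
the AAF-spectrum recovery as a two-sample KS test at α = 0.01 over 10 seeds
against an independent re-derivation of the generative arithmetic. These
sizes were chosen so the whole cycle runs comfortably on a laptop while
keeping every estimate's sampling error far below the tested tolerances.

## Known limitations

* The AAF filter's rescue clause and the uniqueness rule both read per-breed
  AAFs from the variant records; when those come from hard genotype calls
  (the only mode implemented), dosage-based frequencies from external
  cohorts are not representable.
* Gabriel auxiliaries beyond the CI thresholds are assumptions (published
  defaults), configurable but untested against the original tool's output.
* The gap filler is greedy and not guaranteed minimal in probeset cost;
  optimality was not a design goal.
* `category_table` percentages use each category's *unique* count as
  denominator; strata defined on totals would need the caller to recompute.
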