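# Methods

## The mapping model

The package assumes a fully penetrant autosomal-recessive lesion segregating
in a single-generation backcross: a carrier sire mated to its own daughters,
so that affected offspring are autozygous (two copies identical by descent)
for the sire haplotype carrying the lesion. Three consequences drive the
pipeline's logic:

- every affected individual is homozygous for the *same* alleles across the
  lesion-bearing segment;
- every dam of an affected individual is an obligate carrier and therefore
  cannot be homozygous for the case haplotype;
- no unaffected individual may be homozygous for the case haplotype.

The workflow localizes the lesion by intersecting case runs of homozygosity
(ROH), removes intervals contradicted by relatives, triages the carrier's
small variants against a control cohort, and — when the candidate interval
is clean — falls back to read-depth evidence for a structural variant. All
coordinates are 1-based, fully closed; BED/bedGraph conversion happens only
at file boundaries.

## Synthetic family generator

The generator emulates the study conditions end to end with known truth.

**Marker panel.** Two 80-Mb chromosomes with 1,500 SNPs each, uniformly
placed (one SNP per ~53 kb — the density of a ~50k bovine array), reference
allele frequencies Uniform(0.05, 0.5).

**Transmission.** Crossovers per meiosis per chromosome are
Poisson(length × rate) with rate 1e-8/bp (1 cM/Mb), positions uniform, no
interference — adequate for single-generation IBD structure. The sire
carries the deletion on one haplotype; a gamete carries it when the active
haplotype at the deletion midpoint is the carrier one.

**Default family.** Five daughters of the sire, of which exactly three carry
the deletion (carrier status forced by per-daughter rejection sampling, so
the gamete distribution is correct conditional on carrier state); 24
offspring split 5/5/5/5/4; the offspring generation is redrawn until at
least three affected calves exist, since a family without multiple cases
cannot be mapped and would not have been studied. Three cases, nine
unaffected calves, the five dams and the sire are genotyped. Genotyping
noise: symmetric call flips with probability 0.002 and independent
missingness 0.01 (conventional chip rates; the chip error model is a design
choice, not data-derived).

**Sequencing evidence.** Windowed depth is negative-binomial with mean
`mean_depth × copy_number/2` inside the deletion and `mean_depth` outside;
variance μ + 0.1μ² (dispersion 0.1, configurable). A floor of 2% of
`mean_depth` inside the deletion mimics mismapped reads, which is also why a
homozygous deletion reads ~0.02× rather than zero. Per-base Poisson tracks
cover each breakpoint (±16 kb in the pipeline, so that window-resolution
segment edges always leave the refinement search window covered).
Deletion-spanning read pairs are drawn with fragment length
Normal(400, 30) bp and 100-bp reads; their apparent reference insert is the
fragment length plus the net deleted length. The control cohort is a site
table at reduced scale (100 samples, 2 × 10⁻⁵ sites/bp) guaranteed disjoint
from designated private sites. The sire's private small variants are placed
off the mapped chromosome so that the candidate region is clean and the
structural-variant escalation branch is exercised deterministically.

**What the generator does not emulate:** linkage disequilibrium beyond
pedigree transmission, batch or GC coverage biases, read-level artifacts
(the depth and pair summaries are drawn directly), hemizygous genotype-call
behaviour of chip probes inside a deletion, and genotyping chemistry
differences between arrays. Passing tests therefore demonstrate the logic
and calibration of the pipeline under idealized-but-noisy conditions, not
performance on real intensity data.

## Stage-by-stage choices

**QC.** A SNP is removed when call rate < 0.90 *or* MAF < 0.01 (strict
inequalities: a SNP exactly at a threshold is retained). MAF is computed
over all genotyped samples pooled. A SNP failing both criteria is counted
once, under call rate.

**ROH detection.** Exact greedy scan rather than a sliding-window heuristic:
from each uncovered homozygous SNP the run extends right while interior
budgets hold (≤ 2 missing, 0 heterozygous by default), ends on a homozygous
SNP (tolerated calls never at run ends), and qualifies with ≥ 30 SNPs or a
span > 100 kb. The output is deterministic, non-overlapping and sorted, and
is checked against an independent quadratic enumeration in the tests.

**Shared regions.** Qualifying ROH are interval-intersected across cases;
within each intersection, any heterozygous call or homozygous mismatch
splits the region; SNPs where some cases are missing are tolerated (the
consensus comes from the called cases). Sub-regions are re-checked against
the qualification rule and trimmed to SNPs with a defined consensus.

**Pedigree filter.** A region is excluded when an obligate-carrier dam or an
unaffected sibling matches the case haplotype at every region SNP *where
that relative has a call*. A single discordant call rescues the region from
that relative; a missing call does not, because a no-call carries no
evidence of a haplotype difference. (Letting missing calls rescue exclusion
would, at 1% missingness over 100-SNP regions, halve the filter's power and
let large chance-IBD blocks through.)

**Region post-processing.** Two explicit steps follow the filter. Merging
(gap ≤ 1 Mb) heals the fragmentation caused by isolated genotyping errors
and missing-budget exhaustion inside one true IBD region. A support floor
(≥ 30 SNPs per final region, reusing the ROH SNP criterion) removes chance
identity islands: at ~50-kb marker spacing, any 2–3 adjacent SNPs identical
homozygous by chance span > 100 kb and would otherwise qualify via the
length rule. Backcross families genuinely produce occasional additional
shared IBD blocks; across 20 simulated families the pipeline reports exactly
one candidate region containing the implanted deletion in 19, and the
remaining family is an honest mapping miss in which the shared block splits
at the deletion itself.

**Variant triage.** Pure row filters that commute: heterozygous selection,
cohort subtraction keyed on (chrom, pos, ref, alt) site presence (no
frequency threshold — the logic is "uniquely present in the carrier"), and
closed-interval restriction with merging of overlapping intervals.
Multi-allelic records must be pre-split.

**Depth caller.** The segment scan thresholds a running median of the window
counts (width 15 windows) at 0.75× a two-pass baseline median (re-estimated
after provisionally masking low windows, so a deletion occupying a large
share of the profile cannot drag its own detection threshold down). Segment
edges are re-localized at raw window resolution with a two-segment
least-squares step fit, and a detected segment must itself average below the
threshold. These numerical safeguards exist because at dispersion 0.1 the
per-window coefficient of variation exceeds 30%, which fragments a naive
contiguous-threshold scan. Flank tests are two-sided Welch t-tests on raw
window counts (defaults: ~100 kb upstream, ~50 kb downstream); no
multiple-testing correction is applied across the three planned comparisons,
and p-values are reported raw. Breakpoint refinement minimizes the
two-segment SSE per edge independently over per-base counts, ties broken to
the leftmost base, requiring ≥ 5% relative SSE improvement with the correct
step sign — otherwise "breakpoint not resolvable". Depth genotyping uses
ratio thresholds 0.25/0.75, the midpoints between copy-number expectations
0, 0.5 and 1. Pairs are discordant when the apparent insert exceeds the
nominal by > 4 SD; clusters form by interval overlap, and the largest
cluster's median implied span and member count corroborate the call. The
inserted sequence of a delins is not discoverable from depth; it enters the
call only from ground truth or user input, as in practice it comes from
Sanger sequencing across the junction.

**PCR model.** Coordinate arithmetic is primary: a primer pair amplifies an
allele iff neither footprint overlaps a deleted interval, the product is the
5′-to-5′ reference span adjusted by enclosed edits, and products above 5 kb
(standard polymerase practicality) are called no-product. The printed
5′-start of a reverse primer is interpreted as its *rightmost* reference
base — the unique convention under which the wild-type assay's coordinates
(forward 56,450,454; reverse 56,451,423) give the printed 970-bp product;
this check locks the convention. Under the same arithmetic the
deletion-specific pair yields 575 + 6 + 161 = 742 bp, which follows from the
printed primer positions and breakpoints; a smaller published figure for
that product cannot be reconciled with those coordinates, and the
coordinates are followed. An exact sequence-scan mode (verbatim primer
matching on an explicit allele sequence) exists for FASTA-based checks.

**Segregation statistics.** Co-segregation is perfect iff every affected is
−/−, no unaffected is −/−, and every genotyped parent of an affected
carries ≥ 1 deletion allele. The segregation-ratio test is an exact
two-sided binomial test (minimum-likelihood two-sided definition: sum of
outcome probabilities ≤ that of the observed count) of the affected count
among carrier-dam offspring at p₀ = 0.25; an affected offspring of a
non-carrier dam is impossible under the null and raises.

**Annotation.** Coding impact is the closed-interval overlap of the deletion
with CDS intervals; amino acids lost = deleted CDS/3 (floored, with an
out-of-frame flag when not a codon multiple); the protein fraction is
reported to one decimal. Exon numbering follows transcript (strand) order
while coordinates stay reference-forward. The bundled gene fixture is
synthetic: a six-exon gene with a 729-bp CDS of which three internal exons
(522 bp, 174 aa, 71.6% of the protein) fall inside the default deletion —
real exon coordinates are not shipped. Protein-domain tables may be supplied
by the user; none ship with the package.

## Problem sizes

The test suite and examples run at desk scale by design: two 80-Mb
chromosomes (1,500 SNPs each), 24-offspring families, 200-kb depth profiles
at 1-kb windows, 100-sample control cohorts, and 20–100 seed replicates for
the stochastic calibration checks. These sizes preserve the marker density,
depth, family structure and noise rates of the real setting while keeping
every check reproducible in minutes on one CPU.

## Known limitations

- The ROH scanner's greedy left-to-right selection reports non-overlapping
  runs; when tolerated-call budgets force a choice between overlapping
  maximal runs, SNPs after the selected run's end may go unreported.
- Candidate-region boundaries are SNP positions, not recombination
  breakpoints; the true lesion may sit between the last shared SNP and the
  first discordant one.
- The depth caller targets a single large deletion per profile; it does not
  segment multi-state copy-number landscapes, inversions, duplications or
  translocations.
- Cohort subtraction is presence/absence at site level; a causal variant
  segregating at low frequency in the cohort would be (correctly, per the
  design) discarded.
- The in-silico PCR model ignores primer thermodynamics, mismatch tolerance
  and amplification efficiency; a band is predicted wherever coordinates
  allow one.
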