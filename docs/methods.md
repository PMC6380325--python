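# Methods

## The pseudoheterozygosity model

A haploid genome sequenced with short reads and mapped to a single-copy
reference shows apparent heterozygosity wherever two diverged duplicate
copies collapse onto one reference locus. At such a site the reads sample
the two copies roughly 1:1, so a genuine pseudoheterozygous site (PHS)
looks like a balanced biallelic column, while sequencing errors are
low-frequency, often low-quality and concentrated near read ends, and
mapping artefacts cluster in repeats, homopolymers and around indels. The
PHS filter operationalizes this contrast:

- only observations with base quality ≥ Q25 count as allele support;
- each allele needs ≥ 5 supporting reads whose site position is ≥ 15 bp
  from both read ends (each allele independently — the stricter reading,
  symmetric in the two copies);
- total read depth must be strictly greater than 8 (all reads, not only
  Q25+ reads — the more permissive of the two readings of the depth rule);
- the site must fall outside homopolymer runs of ≥ 6 bases (the run
  itself, no flank), outside positions whose 30-mer is non-unique in the
  reference, and ≥ 5 bp away from indels supported by genotype quality
  > 30 and > 5 reads.

Triallelic columns are discarded entirely: a PHS is a two-copy signature,
and a third allele signals error or copy number beyond the model.
Repeat detection uses exact 30-mer multiplicity rather than re-running an
aligner; it is deterministic and testable, and on the random synthetic
references it coincides with what unique-mapping would mask.

## From PHS to duplications

Linked PHS within 400 bp in the same genome are chained (single linkage)
into one PHS duplication. The span between the first and last PHS, minimum
1 bp, is the call's length — the breakpoints of interspersed duplications
are unobservable from the collapsed pileup, so no breakpoint refinement is
attempted. Calls overlapping user-supplied excluded regions are dropped,
and spans above 28 kb are flagged for review as large clustered
duplication regions rather than silently removed.

Independent evidence is collected per genome and pooled across the sample
for classification, since a region duplicated in any sampled genome is
duplication evidence for the population catalog:

- **Split reads.** Tandem breakpoint clusters pass when
  S1 = (n⁺ + 1)(n⁻ + 1) > 15, which demands either balanced strand support
  or very deep one-strand support.
- **Read depth.** Depth in 200-bp windows is normalized by the genome-wide
  mean; high-copy regions are maximal runs of windows strictly above
  1.25× containing at least one window strictly above 2×. Two numerical
  choices matter here. First, the normalizing mean is computed iteratively
  excluding windows above 1.5× the current mean (besides repeat-masked
  windows): without this, duplicated windows inflate the mean and a true
  2-copy region sits just *below* the strict 2× threshold in expectation,
  with failure probability → 1 as depth grows. Second, the pipeline
  evaluates windows at a 100-bp step (sliding) rather than a disjoint
  tiling: with a fixed grid, a 2-copy event of 200–400 bp that straddles a
  window boundary never fully covers any window, so no window can exceed
  2× in expectation at any depth and the event is undetectable in
  principle. Sliding windows are the convention of read-depth CNV
  estimators; `DepthProfile` still defaults to non-overlapping tiling for
  API users who want it.
- **qPCR.** ΔCt is the mean target Ct minus the mean single-copy-fragment
  Ct per strain; ΔΔCt = ΔCt(calibrator) − ΔCt(test); copy number 2^ΔΔCt;
  amplicons strictly above 2^0.5 ≈ 1.41 are flagged as duplicated. The
  z-normalization of ΔΔCt across amplicons is reported alongside the raw
  fold changes, and the 1.41 threshold is applied to the raw values; a
  switch (`z_before_exponentiation`) implements the alternative reading.

A call is classified high-copy (or tandem) when strictly more than 50% of
its length overlaps the pooled high-copy regions (or tandem intervals);
the 50% rule is stated for high-copy evidence and extended to tandem
evidence for uniformity. Calls in different genomes sharing at least one
PHS position collapse into one population event (the most conservative
identity; span-overlap identity is available behind a flag), and an
event's frequency is its carrier count.

## Frequency-spectrum statistics

Under the standard neutral model the expected number of variants at
sample frequency *i* of *n* genomes is proportional to 1/*i*; with *S*
events the expected count in class *i* is *S*/(*a·i*), *a* = Σ₁^{n−1} 1/i,
and the classes sum to *S* exactly. The singleton-excess test is a 1-df
χ² (no continuity correction) of the observed singleton/nonsingleton
split against (S/a, S − S/a). Proportion contrasts use the two-sided
Fisher exact test. The false-positive estimator treats in-silico validated
calls as true positives and converts the singleton-proportion excess of
the undetermined set into a fraction of the total catalog:
N_und (s_und/N_und − s_val/N_val) / N_total, truncated at zero and
reported as a half-up-rounded percentage, matching the convention of
printed tables. π and θ_W = S/(aL) are computed per site over a
caller-supplied L.

## Interval enrichment and age trends

The permutation null for functional-element overlap samples, per draw, one
length-matched fragment per observed call uniformly over positions where
the fragment fits, and counts fragments overlapping the track by ≥ 1 bp.
Empirical p uses the add-one formula (1 + #{null ≥ obs})/(N + 1) — never
zero, two-sided by doubling the smaller tail — making it a valid,
slightly conservative p-value. Region assignment resolves overlapping
transcripts by coding priority (CDS > 5′UTR > 3′UTR > intron >
intergenic), and regional χ² expectations are proportional to region
length, without a mappability correction. Age-group trends compute
observed/expected ratios per group × track, a sign test per group across
tracks (one- and two-sided reported, since the sidedness convention is a
judgment call), a Friedman test across groups with tracks as blocks, and
pairwise Wilcoxon signed-rank tests with Bonferroni correction.

## Paralog dN/dS

The two copies of a duplication are reconstructed by assigning allele 1
of every PHS to copy A and allele 2 to copy B; phase is unknowable from
collapsed pileups but immaterial for counting methods, which are symmetric
in the two sequences. dN/dS uses Nei–Gojobori (1986) counting rather than
codon-model maximum likelihood: PHS counts per duplication are small, and
in the few-substitution regime counting and ML agree closely while
removing an external dependency. Conventions: synonymous site count per
codon = (synonymous one-step changes)/3 with stop-codon neighbours counted
as nonsynonymous (N + S = 3 per codon exactly); multi-hit codons average
over all minimal mutational paths with equal weights; proportions are
Jukes–Cantor corrected, raising an error at saturation (p ≥ 3/4); pairs
with dS = 0 and dN > 0 are flagged (`undefined_ratio`) and excluded from
ratio-based sign tests as their own category. Cross-species homology
status requires identity > 90% and alignment length > 50% of the query:
0 qualifying hits → no homolog, 1 → single copy, ≥ 2 non-overlapping →
duplicated in the subject.

## The synthetic-data generator

The generator emulates a haploid-embryo resequencing panel directly at the
level of observation tracks — pileup columns, split-read clusters, binned
depth — rather than FASTQ, isolating the package's decision rules from
external aligners. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_genomes | 29 | panel size of the emulated design |
| read_length | 73 bp | effective read length after splitting |
| mean_depth | 30× | typical haploid-embryo coverage |
| size distribution | log-normal, μ=5.175, σ=1.073 (log scale) | calibrated analytically so P(L < 500 bp) = 0.834 |
| divergence_rate | 0.01 /bp | recent but detectably diverged copies; uniform per-site substitution is a modeling choice, not an inference |
| tandem_fraction | 0.3 | interspersed duplications outnumber tandem ones |
| frequency model | neutral (1/i) or singleton_excess(w) mixture | enables calibration and power tests |
| base quality | uniform Q25–Q40 | exercises the Q25 filter |
| base_error_rate | 0.001 | Illumina-scale per-base error |
| genome_length / n_events | 2 Mb / 200 | scaled-down genome with non-overlapping source intervals |

Carried duplications double the expected depth over their source interval;
each divergent site yields a pileup column drawing reads 1:1 from the two
copies with Poisson depth, uniform read offsets and optional base errors;
carried tandem events emit one split-read cluster with Poisson(depth/2)
spanning reads split binomially between strands. Depth is simulated in
100-bp bins so that overlapping windows constructed downstream share their
sampling noise instead of getting optimistic independent draws.

What the generator does **not** model — and what passing tests therefore do
not establish about real data: mapping ambiguity and soft-clipping, GC and
library-preparation bias in depth, correlated error profiles along reads,
copy numbers above 2, indel divergence between copies, gene conversion
between paralogs, and linked selection or demography in the frequency
spectrum. Recovery rates on synthetic data are an upper bound on real-data
sensitivity.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.Generator`; identical seeds give bit-identical truth sets,
tracks and reports. The end-to-end recovery analysis runs on the 2-Mb /
29-genome / 200-event scenario (a few seconds); statistical calibrations
use 2,000 neutral frequency-spectrum draws and a few hundred permutation
datasets. Oracle-equivalence checks (merge partition, high-copy scan,
NG86 path enumeration, hypergeometric enumeration) run on 50–1,000 random
instances each against independently coded brute-force implementations.

## Known limitations

- The 30-mer uniqueness mask is an exact-match stand-in for remapping;
  diverged repeats that an aligner would multi-map are not masked.
- High-copy detection quantizes to window boundaries; events below ~200 bp
  rarely acquire depth evidence and rely on split reads or remain
  undetermined, mirroring the behaviour of the real pipeline where roughly
  a third of duplication calls stayed undetermined.
- The mpileup text converter cannot recover per-read end offsets (the
  format does not carry them); positional filtering requires the richer
  pileup TSV.
- Copy-number genotyping per event and breakpoint refinement for
  interspersed duplications are out of scope.
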