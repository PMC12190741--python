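# Methods

## The question this package models

Standard short-read pipelines treat the human sex chromosomes like
autosomes: reads are aligned to a reference carrying both a full X and a
full Y, genotypes are called diploid everywhere, and filter thresholds are
tuned to diploid chromosomes. Three structural facts break those
assumptions. The pseudoautosomal regions (PAR1, PAR2) still recombine and
are effectively identical between X and Y, so every PAR read has two equally
good homes. The X-transposed region (XTR) is ~98.78% identical between the
chromosomes, so XTR reads have one good home and one nearly-as-good decoy.
And outside the PARs, X and Y are haploid in XY individuals, carrying half
the depth and half the allele copies of a diploid chromosome.

This package is a closed-world simulation laboratory for those effects:
every component — genome, reads, mapper, caller, filters — is explicit and
seeded, and every call is scored against the generating truth, so the
consequences of each pipeline decision can be measured exactly rather than
argued about.

## Synthetic genome and cohorts

`genome_sim` builds a toy genome whose default desk-scale layout is a 200 kb
X (PAR1 10 kb, non-PAR 70 kb, XTR 30 kb, ampliconic 10 kb, non-PAR 75 kb,
PAR2 5 kb), a 100 kb Y with the same homologous-class lengths, and a 100 kb
diploid autosome as baseline. Lengths are two to four orders of magnitude
below the real chromosomes; the mapping and calling phenomena of interest
are driven by sequence-identity fractions and per-base densities, which are
preserved. Y PARs are exact copies of the X PARs (`s_par = 1`, exposed as a
parameter); the Y XTR is a copy of the X XTR with exactly
`floor((1 - s_xtr) * L)` uniformly placed substitutions (`s_xtr = 0.9878`);
ampliconic and non-PAR sequence is independently drawn, hence ~75% divergent
— a deliberate simplification that makes non-homologous mapping
unambiguous. Ampliconic regions are tracked as a region class but have no
internal repeat structure; results for that class only measure "unrelated
sequence labelled AMP".

Cohort truth sets place SNPs per haplotype as a Bernoulli process at
density θ = 0.001 per bp (a human-like per-haplotype heterozygosity), alt
alleles uniform over the three non-reference bases, no indels. Variants are
independent across samples; there is no shared-polymorphism or
allele-frequency structure (see "What the generator does not emulate").
XY samples carry one full X, a second X-anchored copy of the PARs (PAR
variation is represented on X coordinates only, diploid in everyone), and
the Y non-PARs; XX samples carry two full X copies and never any Y
sequence. When the two copies at one position both mutate, the second draw
adopts the first alt allele so golden sites stay biallelic.

## Read simulation

Paired 150 bp reads are drawn per chromosome copy at 10x per copy, so
diploid regions see 20x and haploid regions 10x. Fragment lengths are
Normal(350, 40) clipped to [read length, template length]; mate 1 is the
fragment 5' end, mate 2 the reverse-complemented 3' end. Base qualities are
Q25 with an expected ~10% of bases demoted to Q12 in runs at read ends
(each end independently affected with probability 0.3, geometric run length
with mean 25), giving the trimmer realistic work. Per-base error
probability is `10**(-Q/10)`; errors substitute a uniform different base.
Setting a constant error rate ε instead is supported for controlled
experiments (ε = 0 yields error-free reads).

Fragments are drawn within ploidy-class segments: PAR1, the non-PAR span,
and PAR2 are separate templates with their own coverage, so no fragment
spans a PAR/non-PAR junction. This mirrors region-by-region read simulation
with region-specific coverage settings (the PARs are simulated diploid and
X-anchored while the non-PARs of an XY sample are haploid, which forces
separate simulation runs per region) and it makes the PAR observables
clean: without it, junction-spanning reads would give the PARs a thin
uniquely-mappable fringe whose width is set by the read length, an artifact
of simulating boundaries rather than a property of the strategies under
test. The cost is a slight coverage droop at template edges (fragment-length
scale), visible as mildly elevated false negatives near region boundaries.

Trimming follows the classic end-quality recipe: maximal runs of bases with
Q < 20 are removed from both read ends, reads shorter than 75 bp after
trimming are discarded, reads with mean Phred below 20 are discarded, and
mates are dropped jointly if either fails. The mean-quality gate uses the
arithmetic mean of Phred scores of the post-trim read. Trimming is
idempotent (property-tested).

## Mapper

`mapsim` is a fully specified ungapped mapper, not an emulation of any
production aligner. Candidate placements come from an exact k-mer index
(k = 11); splitting a read of length L into `L // k` non-overlapping seeds
guarantees by pigeonhole that every placement with fewer than `L // k`
mismatches is evaluated, which on these genomes makes the seeded mapper
equivalent to an exhaustive Hamming scan (property-tested on a 32 kb
genome, placement sets and MAPQ both). Placements are scored by mismatch
count over the full read on both strands; reference `N` counts as a
mismatch, so a hard-masked homolog can never out-compete an unmasked true
locus. Ties collapse MAPQ to 0 and one placement is reported, chosen by a
deterministic per-read tie hash derived from the run seed — like a
production aligner's tie-breaking, the same read picks the same home
whenever its candidate set is unchanged, so strategy contrasts (default vs
complement-matched references) are not blurred by placement noise;
otherwise `MAPQ = min(60, 6 * (second_best - best) + 20)`,
a declared surrogate whose two regimes that matter downstream are 0
(multi-mapper, excluded from calling) and >= 40 (survives the MQ hard
filter). Reads whose best placement exceeds 25% mismatches are unaligned.
Mates are aligned independently; pairing constraints and pair rescue are
deliberately out of scope — with identical PAR copies, pair rescue would
only re-anchor ambiguous mates without changing which regions are
confidently mappable.

Under this model: PAR reads tie between X and Y under the default reference
(MAPQ 0); XTR reads map home with a margin of the few divergent sites in
the read, landing mostly in MAPQ 26–38, and tie (MAPQ 0) when the read
covers no divergent site (~16% of 150 bp reads at 98.78% identity); reads
from a masked Y XTR re-route to the X copy with MAPQ 60 (no surviving
competitor).

## Caller

Genotype likelihoods use the standard per-read substitution model: a read
base b with error probability e supports allele a with `1 - e` if `b == a`,
else `e / 3`; haploid likelihoods multiply per-read terms, diploid
likelihoods use the half-half allele mixture. Error probabilities are
floored at 1e-4 so high-quality bases cannot produce zero likelihoods.
Reads with MAPQ < 20 — and always MAPQ 0 — are excluded before likelihoods;
this is the mechanism that empties the PARs under the default reference.
Genotype priors put 1e-3 on each heterozygous genotype and 5e-4 on
homozygous/hemizygous alt (a GATK-like heterozygosity prior, configurable).

Joint genotyping scans candidate sites (any sample showing >= 2 reads of
one non-reference base, a computational trigger two alt reads always
satisfy), picks the cohort-wide most frequent non-reference base as the alt
(highest count kept at multi-allelic columns, with a warning), assigns each
sample its MAP genotype at its own ploidy — mixed ploidy across samples at
one site is the point — and emits sites with at least one called alt allele
and QUAL > 0, where QUAL is the phred-scaled posterior probability that
every sample is homozygous/hemizygous reference (independence across
samples). There is no local reassembly, no GVCF intermediate, and no
multi-site genotype refinement.

Annotations follow GATK conventions: DP (calling-usable depth summed over
samples), AN (ploidy-weighted genotyped allele copies), AC, QD
(QUAL / depth over samples carrying an alt), FS (phred-scaled two-sided
Fisher exact p on the ref/alt x strand table), SOR (symmetric strand odds
ratio with +1 pseudocounts), and MQRankSum / ReadPosRankSum (rank-sum
z-scores of alt vs ref read MAPQs and distances from the read end, omitted
when either allele has no reads). MQ is the RMS mapping quality over the
raw pileup including multi-mappers, so regions whose reads are ambiguously
placed carry low MQ even when a few confident reads exist; this is what
lets the MQ < 40 filter act as the ambiguity backstop.

## Filters

The hard-filter set is the standard autosomal recommendation — QD < 2,
QUAL < 30, SOR > 3, FS > 60, MQ < 40, MQRankSum < -12.5,
ReadPosRankSum < -8 — applied with strict comparisons exactly as written;
a missing annotation never fails its filter, and filter labels are
conjunctive and order-independent. The DP band filter retains sites whose
depth lies within 50–150% of a mean DP that is either autosome-derived
("diploid-based") or derived from X/Y non-PAR sites of XY samples
("haploid-based"); both bounds are inclusive. The AN filter retains sites
with at least k genotyped allele copies (retaining high AN, since AN counts
successful genotyping); with n haploid-called samples AN cannot exceed n,
so any k > n empties haploid regions analytically. Threshold sweeps over
QD {1, 1.5, 2, 12, 16, 20, 28} and AN {20, 15, 10, 5, 4, 3, 2, 1} report
retained TP/FP per region class. DP and AN act site-wise on the joint call
set (INFO-level, not per-genotype).

## Benchmarking

A true positive is a site both called and simulated with matching ref and
alt; a false positive is called but not simulated; a false negative is
simulated but not called. A called site whose alt mismatches the simulated
alt counts as one FP plus one FN — the definitions do not cover this case,
so the convention is declared and such rows are flagged `alt_mismatch` for
audit. Genotypes (het vs hom) are not compared. The joint call set is
exploded to per-sample sets (a sample carries a site iff its genotype
contains an alt allele) before classification, and per-sample, per-region
conservation TP + FN = simulated is asserted on every run. Stratification
merges PAR1/PAR2 into "PAR" and reports XTR, AMP and the non-PAR remainder
separately, with proportions over per-sample simulated totals (undefined
for empty classes). Window tracks use 0-anchored fixed windows (50 kb
default, truncated final window included).

`run_experiment` executes the factorial {default, SCC, SCC + Y-XTR masked
(XY only)} x {matched ploidy, forced diploid} from one seed, reusing each
sample's reads across reference kinds, and reports per-cell tables, window
difference tracks, and summary metrics. All randomness descends from the
single seed through tagged child seeds (CRC-based, process-independent), so
identical config + seed reproduce every table and output file byte for
byte.

### The XTR over-call ratio

The headline metric for the masked-XTR strategy is the number of
joint-called sites in the X XTR divided by the number of distinct simulated
X-XTR sites per sample (mean across samples). The per-sample denominator is
deliberate: with independent per-sample variants, the cohort-union of
simulated sites grows linearly with cohort size (n·θ per bp, ~10x the
segregating-site density of a real cohort of this size, where allele
sharing keeps the union near θ per bp), which would deflate the ratio by
exactly that factor and measure the generator's lack of allele sharing
rather than the masking artifact. Against the per-sample denominator the
mechanism is scale-free: masking the Y XTR converts every X–Y divergent
position (density 1 - s_xtr ≈ 0.0122/bp) into a called site, an order of
magnitude above the simulated density θ = 0.001/bp. The cohort-union
variant is reported alongside for transparency.

## What the generator does and does not emulate

Emulated: the region architecture and identity structure of X and Y,
ploidy-correct coverage and genotypes, quality-dependent sequencing error,
multi-mapping ambiguity, and golden-truth scoring. Not emulated: real
coordinates and region sizes; allele sharing and frequency spectra across
samples (variants are i.i.d. per haplotype); empirical error/GC profiles
and machine-specific quality models; indels and structural variation;
ampliconic internal repeats; gapped alignment and pair rescue; local
haplotype reassembly. Passing tests therefore demonstrate the mechanisms —
multi-mapper collapse, divergence-driven over-calling, ploidy-mismatched
genotype and filter behavior — at desk scale; absolute counts do not
transfer to real genomes, and regions whose real-world difficulty comes
from repeat structure (ampliconic) are under-modelled here.

## Numerical and design choices

Coordinates are 0-based half-open internally, 1-based in VCF. Likelihood
arithmetic is log10 with a 1e-300 clip; genotype posteriors are normalized
per sample; QUAL and GQ are rounded to 2 decimals / capped at 99.
Substitution counts for reference similarity use `floor((1 - s) * L)` with
a 1e-9 tolerance against float representation (0.0122 * 30000 must be 366,
not 365). Mapper ties are broken by a per-read hash of the run seed;
correctness downstream is defined by the truth table, never the placement.
Degenerate inputs: empty pileup columns yield uniform likelihoods and no
call; sites whose reference base is N are never candidates; empty region
classes report zero counts with undefined proportions; intervals shorter
than a read are skipped with a warning at simulation time.

Problem sizes in the shipped configurations (200 kb X at 10–20x, ten
samples per cohort; 30–40 kb chromosomes in the test suite) were chosen so
each observable rests on hundreds of informative sites while a full
factorial stays comfortably runnable on a laptop; all of them are
parameters, not constants.

## Known limitations

The mapper's MAPQ surrogate is linear in the mismatch margin and
intentionally simple; only its tie and >= 40 regimes are consumed
downstream. Because XTR reads carry a 1–3 mismatch margin, XTR site MQ
hovers near the 40 cutoff and the MQ filter removes most unmasked-XTR
calls at desk scale — the strategy contrasts (masked vs unmasked, default
vs SCC) are preserved, but absolute XTR recovery is pessimistic relative
to a production aligner whose MAPQ saturates faster. Forced-diploid false
positives at 10x arise mostly from paired sequencing errors and are small
in absolute number; their ordering against haploid calling is the robust
signal. The AN wipeout and PAR collapse results are analytic consequences
of the model and should be read as such.
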