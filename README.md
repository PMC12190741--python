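# sexchrom-varbench

A simulation laboratory for measuring how alignment, variant-calling and
filtering strategies behave on the human sex chromosomes — for people who
build or evaluate short-read germline pipelines and need ground truth to
score them against.

The X and Y chromosomes violate the assumptions autosomal pipelines are
tuned for. The pseudoautosomal regions (PAR1, PAR2) are effectively
identical between X and Y, so under a reference carrying both copies every
PAR read multi-maps with MAPQ 0 and vanishes from calling. The X-transposed
region (XTR) is ~98.78% identical between the chromosomes, so masking one
copy re-routes its reads onto the other, where every X–Y divergent site
becomes a spurious variant. And X/Y non-PARs are haploid in XY individuals:
diploid genotype models invent heterozygotes from error piles, and
diploid-derived depth (DP) and allele-number (AN) thresholds are twice too
stringent.

This package builds the entire experiment from scratch — a toy X/Y/autosome
genome with the real identity structure, ploidy-aware paired-end reads, the
four reference variants (default; sex-chromosome-complement for XX and XY;
XY with the Y XTR additionally masked), a fully specified mapper, a
haploid/diploid joint genotyper with GATK-convention annotations
(QD, MQ, FS, SOR, rank sums), the standard hard filters plus DP/AN/QD
sweeps, and a golden-truth benchmark that scores TP/FP/FN per sample,
region class and window. Everything is seeded and deterministic.

## Model sketch

Per read base `b` with error probability `e` (from its quality), allele
support is `P(b|a) = 1 - e` if `b = a`, else `e/3`. Haploid:
`L(a) = prod_reads P(b|a)`; diploid:
`L(a1,a2) = prod_reads [P(b|a1) + P(b|a2)] / 2`. Joint genotyping assigns
each sample its MAP genotype at its region ploidy (X PAR diploid; X/Y
non-PAR haploid in XY; mixed ploidy across a cohort at one site), with site
`QUAL = -10 log10 P(all samples hom-ref | data)` and
`AN = sum of ploidies of genotyped samples` — the quantity that makes a
diploid-based `AN >= 20` filter analytically lethal to ten haploid-called
samples. The mapper scores ungapped placements by mismatch count; ties give
MAPQ 0 (excluded from calling), otherwise
`MAPQ = min(60, 6 * (second_best - best) + 20)`, with reference `N`
counting as a mismatch so hard-masked homologs never compete.

## Worked example

`examples/` contains one narrative script per capability. The mapping
mechanism in thirty seconds (`examples/02_reference_masking_and_mapq.py`):

```
default                masked bases: {'X': 0, 'Y': 0, 'A': 0}
xx_scc                 masked bases: {'X': 0, 'Y': 100000, 'A': 0}
xy_scc                 masked bases: {'X': 0, 'Y': 15000, 'A': 0}
xy_scc_yxtr_masked     masked bases: {'X': 0, 'Y': 45000, 'A': 0}

150 bp read from X PAR1:
  default : 2 co-optimal placement(s) [('X', 2000), ('Y', 2000)] -> MAPQ 0
  xy_scc  : 1 co-optimal placement(s) [('X', 2000)] -> MAPQ 60
```

The PAR read has two perfect homes under the default reference and is
useless to the caller; masking the Y PARs gives it a unique home. Calling
ploidy (`examples/03_haploid_vs_diploid_calling.py`, three XY samples,
complement-matched alignment, same pileups genotyped both ways):

```
mode            X/Y non-PAR FP   X/Y non-PAR FN
matched                      0               14
force-diploid               40               14
```

Diploid calling of haploid chromosomes inflates false positives and buys
nothing on false negatives. Ploidy-informed filtering
(`examples/04_filter_thresholds.py`, ten haploid-called XY samples):

```
allele-number thresholds (10 haploid-called samples):
  AN >=  1:  2569 X/Y non-PAR TPs
  AN >= 10:  2539 X/Y non-PAR TPs
  AN >= 20:     0 X/Y non-PAR TPs

mean DP: autosome-derived 171.6, X/Y-non-PAR-derived 83.3
  DP in [85.8, 257.5] (diploid-based):  1202 X/Y non-PAR TPs
  DP in [41.7, 125.0] (haploid-based):  2520 X/Y non-PAR TPs
```

Ten haploid samples can never reach AN 20, and the diploid depth band sits
above the haploid depth mode, discarding half the true positives the
haploid band keeps. `examples/05_full_benchmark.py` runs the complete
strategy factorial and prints the per-region TP/FP/FN table.

## Layout

```
src/sexchrom_varbench/   genome_sim, read_sim, refprep, mapsim,
                         caller, filters, bench (+ dna helpers)
tests/                   pytest suite, property tests, oracle checks
examples/                one runnable narrative script per capability
docs/methods.md          model assumptions, parameters, limitations
scripts/acceptance.py    end-to-end recomputation of headline metrics
```
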