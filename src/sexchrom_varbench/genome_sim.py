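"""Toy X/Y genome architecture, reference simulation, and golden truth sets.

The simulated genome reproduces the structural features that make the human
sex chromosomes hard for standard pipelines: pseudoautosomal regions (PAR1,
PAR2) that are identical between X and Y, an X-transposed region (XTR) with
~98.78% X-Y identity, ampliconic segments, and unrelated non-PAR sequence.
Cohorts of XX and XY individuals carry per-haplotype SNP truth sets ("golden"
variants) from which every benchmark in this package is scored.

Coordinates are 0-based half-open internally (BED convention); VCF output is
1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import dna

REGION_CLASSES = ("PAR1", "PAR2", "XTR", "AMP", "NONPAR")
#: classes with an enforced X/Y homolog of equal length
HOMOLOG_CLASSES = ("PAR1", "PAR2", "XTR", "AMP")

DEFAULT_S_XTR = 0.9878  # X-Y sequence identity of the X-transposed region
DEFAULT_THETA = 0.001  # per-haplotype SNP density per bp


class ArchitectureError(ValueError):
    """Raised when a region layout violates the architecture invariants."""


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    cls: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeArchitecture:
    """Named region layout of a toy X/Y (plus optional autosome) genome.

    Parameters
    ----------
    chrom_lengths
        Basepairs per chromosome; keys are a subset of ``{"X", "Y", "A"}``.
    regions
        Non-overlapping regions tiling each chromosome. PAR1 must sit at the
        chromosome start and PAR2 at the chromosome end on both X and Y.
    s_par, s_xtr
        Fraction of identical bases between the X and Y copies of the PARs
        and the XTR. Non-PAR/ampliconic sequence is independently drawn.
    """

    chrom_lengths: Mapping[str, int]
    regions: tuple[Region, ...]
    s_par: float = 1.0
    s_xtr: float = DEFAULT_S_XTR

    def __post_init__(self) -> None:
        self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        for s, name in ((self.s_par, "s_par"), (self.s_xtr, "s_xtr")):
            if not 0.0 <= s <= 1.0:
                raise ArchitectureError(f"{name}={s} outside [0, 1]")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ArchitectureError(f"chromosome {chrom} has length {length}")
            regs = sorted(self.regions_of(chrom), key=lambda r: r.start)
            pos = 0
            for r in regs:
                if r.cls not in REGION_CLASSES:
                    raise ArchitectureError(f"unknown region class {r.cls!r} in {r}")
                if r.start < 0 or r.end > length or r.start >= r.end:
                    raise ArchitectureError(
                        f"region {r.cls} [{r.start}, {r.end}) out of bounds on "
                        f"{chrom} (length {length})"
                    )
                if r.start < pos:
                    raise ArchitectureError(
                        f"region {r.cls} [{r.start}, {r.end}) overlaps previous "
                        f"region ending at {pos} on {chrom}"
                    )
                if r.start > pos:
                    raise ArchitectureError(
                        f"gap [{pos}, {r.start}) on {chrom}: regions must tile "
                        "the chromosome"
                    )
                pos = r.end
            if pos != length:
                raise ArchitectureError(
                    f"regions on {chrom} end at {pos}, chromosome length {length}"
                )
        for chrom in ("X", "Y"):
            if chrom not in self.chrom_lengths:
                continue
            for cls in ("PAR1", "PAR2"):
                ivls = self.intervals(cls, chrom)
                if not ivls:
                    continue
                if cls == "PAR1" and ivls[0][0] != 0:
                    raise ArchitectureError(f"PAR1 on {chrom} must start at 0")
                if cls == "PAR2" and ivls[-1][1] != self.chrom_lengths[chrom]:
                    raise ArchitectureError(f"PAR2 on {chrom} must end the chromosome")
        if "X" in self.chrom_lengths and "Y" in self.chrom_lengths:
            for cls in HOMOLOG_CLASSES:
                lx = sum(e - s for s, e in self.intervals(cls, "X"))
                ly = sum(e - s for s, e in self.intervals(cls, "Y"))
                if lx != ly:
                    raise ArchitectureError(
                        f"homologous class {cls} has length {lx} on X but {ly} on Y"
                    )

    # -- queries --------------------------------------------------------
    def regions_of(self, chrom: str) -> list[Region]:
        return [r for r in self.regions if r.chrom == chrom]

    def intervals(self, cls: str, chrom: str) -> list[tuple[int, int]]:
        return [
            (r.start, r.end)
            for r in sorted(self.regions_of(chrom), key=lambda r: r.start)
            if r.cls == cls
        ]

    def class_at(self, chrom: str, pos: int) -> str:
        for r in self.regions_of(chrom):
            if r.start <= pos < r.end:
                return r.cls
        raise KeyError(f"{chrom}:{pos} outside all regions")

    def class_array(self, chrom: str) -> np.ndarray:
        """Region-class index per base (index into REGION_CLASSES)."""
        arr = np.empty(self.chrom_lengths[chrom], dtype=np.int8)
        for r in self.regions_of(chrom):
            arr[r.start : r.end] = REGION_CLASSES.index(r.cls)
        return arr

    def par_intervals(self, chrom: str) -> list[tuple[int, int]]:
        return self.intervals("PAR1", chrom) + self.intervals("PAR2", chrom)

    def nonpar_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Maximal intervals outside the PARs (XTR/AMP/NONPAR merged)."""
        pars = self.par_intervals(chrom)
        length = self.chrom_lengths[chrom]
        out: list[tuple[int, int]] = []
        pos = 0
        for s, e in sorted(pars):
            if s > pos:
                out.append((pos, s))
            pos = e
        if pos < length:
            out.append((pos, length))
        return out

    def ploidy_segments(self, chrom: str) -> list[tuple[int, int, str]]:
        """(start, end, 'PAR'|'nonPAR') segments; templates for read simulation."""
        segs = [(s, e, "PAR") for s, e in self.par_intervals(chrom)]
        segs += [(s, e, "nonPAR") for s, e in self.nonpar_intervals(chrom)]
        return sorted(segs)

    def homolog_pair(self, cls: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Paired (X interval, Y interval) for a homologous region class."""
        xs, ys = self.intervals(cls, "X"), self.intervals(cls, "Y")
        if len(xs) != len(ys):
            raise ArchitectureError(f"class {cls}: {len(xs)} X vs {len(ys)} Y intervals")
        return list(zip(xs, ys))


def build_architecture(
    x_segments: Sequence[tuple[str, int]],
    y_segments: Sequence[tuple[str, int]] | None = None,
    autosome_length: int = 0,
    s_par: float = 1.0,
    s_xtr: float = DEFAULT_S_XTR,
) -> GenomeArchitecture:
    """Assemble and validate an architecture from ordered (class, length) runs.

    Zero-length segments are dropped (an architecture without an XTR is valid;
    all downstream XTR tallies are then empty). The optional autosome "A" is a
    single diploid NONPAR chromosome serving as the autosomal baseline.
    """
    regions: list[Region] = []
    lengths: dict[str, int] = {}
    specs = {"X": x_segments}
    if y_segments is not None:
        specs["Y"] = y_segments
    for chrom, segments in specs.items():
        pos = 0
        for cls, length in segments:
            if length < 0:
                raise ArchitectureError(f"negative length for {cls} on {chrom}")
            if length == 0:
                continue
            regions.append(Region(chrom, pos, pos + length, cls))
            pos += length
        lengths[chrom] = pos
    if autosome_length:
        regions.append(Region("A", 0, autosome_length, "NONPAR"))
        lengths["A"] = autosome_length
    return GenomeArchitecture(lengths, tuple(regions), s_par=s_par, s_xtr=s_xtr)


def default_architecture(autosome_length: int = 100_000) -> GenomeArchitecture:
    """The standard desk-scale layout: X = 200 kb, Y = 100 kb, A = 100 kb."""
    return build_architecture(
        x_segments=[
            ("PAR1", 10_000),
            ("NONPAR", 70_000),
            ("XTR", 30_000),
            ("AMP", 10_000),
            ("NONPAR", 75_000),
            ("PAR2", 5_000),
        ],
        y_segments=[
            ("PAR1", 10_000),
            ("NONPAR", 20_000),
            ("XTR", 30_000),
            ("AMP", 10_000),
            ("NONPAR", 25_000),
            ("PAR2", 5_000),
        ],
        autosome_length=autosome_length,
    )


def write_region_beds(arch: GenomeArchitecture, outdir: str | os.PathLike) -> dict[str, Path]:
    """Emit one BED per region class plus a combined 4-column BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ordered = sorted(arch.regions, key=lambda r: (r.chrom, r.start))
    for cls in REGION_CLASSES:
        rows = [(r.chrom, r.start, r.end) for r in ordered if r.cls == cls]
        p = outdir / f"{cls}.bed"
        dna.write_bed(rows, p)
        paths[cls] = p
    combined = outdir / "regions.bed"
    dna.write_bed([(r.chrom, r.start, r.end, r.cls) for r in ordered], combined)
    paths["combined"] = combined
    return paths


# ---------------------------------------------------------------------------
# reference pair
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferencePair:
    """Simulated reference sequences keyed by chromosome, plus the seed used."""

    seqs: Mapping[str, np.ndarray]
    seed: int

    def sequence(self, chrom: str) -> str:
        return dna.decode(self.seqs[chrom])


def _substitute(rng: np.random.Generator, seq: np.ndarray, n_subs: int) -> np.ndarray:
    """Return a copy of ``seq`` with exactly n_subs positions changed."""
    out = seq.copy()
    if n_subs == 0:
        return out
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_subs)) % 4
    return out


def simulate_reference_pair(arch: GenomeArchitecture, seed: int) -> ReferencePair:
    """Draw an X/Y(/A) reference with the architecture's similarity structure.

    Y PARs are copies of the X PARs with exactly ``floor((1 - s_par) * L)``
    substituted positions (identical when s_par = 1); the Y XTR is a copy of
    the X XTR with ``floor((1 - s_xtr) * L)`` substitutions at uniformly
    chosen positions; ampliconic and non-PAR Y sequence is drawn independently
    of X.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {}
    for chrom in arch.chrom_lengths:
        seqs[chrom] = rng.integers(0, 4, size=arch.chrom_lengths[chrom], dtype=np.uint8)
    if "X" in seqs and "Y" in seqs:
        for cls, s in (("PAR1", arch.s_par), ("PAR2", arch.s_par), ("XTR", arch.s_xtr)):
            for (xs, xe), (ys, ye) in arch.homolog_pair(cls):
                copy = seqs["X"][xs:xe]
                # tolerance guards against float representation of s
                # (e.g. (1 - 0.9878) * 30000 evaluating to 365.999...)
                n_subs = int(np.floor((1.0 - s) * (xe - xs) + 1e-9))
                seqs["Y"][ys:ye] = _substitute(rng, copy, n_subs)
    return ReferencePair(seqs={k: v for k, v in seqs.items()}, seed=seed)


# ---------------------------------------------------------------------------
# cohort truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Haplotype:
    """A chromosome copy carried by a sample, as intervals on an anchor chrom.

    Intervals are split at PAR/non-PAR junctions: each interval is an
    independent template for variant placement and read simulation, mirroring
    region-by-region simulation with region-specific coverage.
    """

    name: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]

    def span(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class CohortConfig:
    n_xx: int = 10
    n_xy: int = 10
    theta: float = DEFAULT_THETA  # SNPs per bp per haplotype

    def __post_init__(self) -> None:
        if self.n_xx < 0 or self.n_xy < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass
class SampleTruth:
    """Karyotype plus per-haplotype golden SNPs (the golden-VCF content)."""

    sample_id: str
    karyotype: str  # "XX" | "XY"
    haplotypes: tuple[Haplotype, ...]
    snps: dict[str, list[tuple[str, int, int, int]]]  # hap -> (chrom, pos0, ref, alt)

    def site_truth(self, arch: GenomeArchitecture) -> dict[tuple[str, int], tuple[int, int, int, int]]:
        """Collapse haplotype SNPs to sites: (chrom, pos0) -> (ref, alt, n_alt, ploidy)."""
        n_alt: dict[tuple[str, int], list] = {}
        for hap in self.haplotypes:
            for chrom, pos, ref, alt in self.snps[hap.name]:
                key = (chrom, pos)
                if key in n_alt:
                    n_alt[key][2] += 1
                else:
                    n_alt[key] = [ref, alt, 1]
        out = {}
        for (chrom, pos), (ref, alt, count) in n_alt.items():
            out[(chrom, pos)] = (ref, alt, count, self.ploidy_at(arch, chrom, pos))
        return out

    def ploidy_at(self, arch: GenomeArchitecture, chrom: str, pos: int) -> int:
        return ploidy_of(arch, self.karyotype, chrom, pos)


def ploidy_of(arch: GenomeArchitecture, karyotype: str, chrom: str, pos: int) -> int:
    """Region ploidy: autosome 2; X PAR 2; X non-PAR 2 (XX) / 1 (XY);
    Y non-PAR 1 (XY) / 0 (XX); Y PAR 0 (PAR variation is X-anchored)."""
    if chrom == "A":
        return 2
    cls = arch.class_at(chrom, pos)
    in_par = cls in ("PAR1", "PAR2")
    if chrom == "X":
        if in_par:
            return 2
        return 2 if karyotype == "XX" else 1
    if chrom == "Y":
        if karyotype == "XX" or in_par:
            return 0
        return 1
    raise KeyError(chrom)


def sample_haplotypes(arch: GenomeArchitecture, karyotype: str) -> tuple[Haplotype, ...]:
    """Chromosome copies carried by a karyotype, split at ploidy boundaries.

    XY samples carry one full X, the PARs a second time (the PARs are diploid
    and X-anchored, as in the source VCFs the study emulated), and the Y
    non-PARs once. Y PAR copies are never templates.
    """
    x_segs = tuple((s, e) for s, e, _ in arch.ploidy_segments("X"))
    haps: list[Haplotype] = []
    if karyotype == "XX":
        haps.append(Haplotype("X.0", "X", x_segs))
        haps.append(Haplotype("X.1", "X", x_segs))
    elif karyotype == "XY":
        haps.append(Haplotype("X.0", "X", x_segs))
        haps.append(Haplotype("XPAR.1", "X", tuple(arch.par_intervals("X"))))
        if "Y" in arch.chrom_lengths:
            haps.append(Haplotype("Y.0", "Y", tuple(arch.nonpar_intervals("Y"))))
    else:
        raise ValueError(f"unknown karyotype {karyotype!r}")
    if "A" in arch.chrom_lengths:
        a_seg = ((0, arch.chrom_lengths["A"]),)
        haps.append(Haplotype("A.0", "A", a_seg))
        haps.append(Haplotype("A.1", "A", a_seg))
    return tuple(haps)


def _draw_hap_snps(
    rng: np.random.Generator,
    hap: Haplotype,
    ref: np.ndarray,
    theta: float,
) -> list[tuple[str, int, int, int]]:
    """Bernoulli(theta) SNP placement over the haplotype's eligible bases."""
    span = hap.span()
    k = rng.binomial(span, theta)
    if k == 0:
        return []
    flat = rng.choice(span, size=k, replace=False)
    flat.sort()
    # map flat offsets back to genomic positions
    positions = np.empty(k, dtype=np.int64)
    off = 0
    for s, e in hap.intervals:
        w = e - s
        inside = (flat >= off) & (flat < off + w)
        positions[inside] = flat[inside] - off + s
        off += w
    refs = ref[positions]
    alts = (refs + rng.integers(1, 4, size=k)) % 4
    return [
        (hap.chrom, int(p), int(r), int(a)) for p, r, a in zip(positions, refs, alts)
    ]


def simulate_cohort(
    arch: GenomeArchitecture,
    refpair: ReferencePair,
    cohort: CohortConfig,
    seed: int,
) -> list[SampleTruth]:
    """Draw golden truth sets for ``n_xx`` XX and ``n_xy`` XY samples.

    SNP positions are i.i.d. Bernoulli(theta) per haplotype; alt alleles are
    uniform over the three non-reference bases. When two haplotypes of one
    sample hit the same anchored position the later draw adopts the first
    alt allele, keeping every golden site biallelic (a homozygous variant).
    """
    rng = np.random.default_rng(seed)
    samples: list[SampleTruth] = []
    karyotypes = ["XX"] * cohort.n_xx + ["XY"] * cohort.n_xy
    n_seen = {"XX": 0, "XY": 0}
    for kt in karyotypes:
        n_seen[kt] += 1
        sid = f"{kt}{n_seen[kt]:02d}"
        haps = sample_haplotypes(arch, kt)
        snps: dict[str, list[tuple[str, int, int, int]]] = {}
        site_alt: dict[tuple[str, int], int] = {}
        for hap in haps:
            drawn = _draw_hap_snps(rng, hap, refpair.seqs[hap.chrom], cohort.theta)
            fixed = []
            for chrom, pos, ref, alt in drawn:
                key = (chrom, pos)
                alt = site_alt.setdefault(key, alt)
                fixed.append((chrom, pos, ref, alt))
            snps[hap.name] = fixed
        samples.append(SampleTruth(sid, kt, haps, snps))
    return samples


# ---------------------------------------------------------------------------
# golden VCF
# ---------------------------------------------------------------------------

_CHROM_ORDER = {"X": 0, "Y": 1, "A": 2}


def golden_records(
    sample: SampleTruth, arch: GenomeArchitecture
) -> list[tuple[str, int, str, str, str]]:
    """Sorted (chrom, pos1, ref, alt, GT) rows for a sample's golden VCF."""
    rows = []
    for (chrom, pos), (ref, alt, n_alt, ploidy) in sample.site_truth(arch).items():
        if ploidy == 1:
            gt = "1"
        else:
            n_alt = min(n_alt, ploidy)
            gt = "/".join(["1"] * n_alt + ["0"] * (ploidy - n_alt))
            gt = "/".join(sorted(gt.split("/")))  # "0/1" or "1/1"
        rows.append((chrom, pos + 1, dna.BASES[ref], dna.BASES[alt], gt))
    rows.sort(key=lambda r: (_CHROM_ORDER.get(r[0], 99), r[1]))
    return rows


def write_golden_vcf(
    sample: SampleTruth, arch: GenomeArchitecture, path: str | os.PathLike
) -> None:
    """Write the golden truth set as a sorted biallelic SNP VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=sexchrom_varbench golden truth\n')
        for chrom, length in arch.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample.sample_id
            + "\n"
        )
        for chrom, pos1, ref, alt, gt in golden_records(sample, arch):
            fh.write(f"{chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def read_golden_vcf(path: str | os.PathLike) -> dict[tuple[str, int], tuple[str, str, str]]:
    """Read a golden VCF back as (chrom, pos1) -> (ref, alt, GT) using pysam."""
    import pysam

    out: dict[tuple[str, int], tuple[str, str, str]] = {}
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            gt = rec.samples[sample]["GT"]
            gt_str = "/".join(str(a) for a in gt if a is not None)
            out[(rec.chrom, rec.pos)] = (rec.ref, rec.alts[0], gt_str)
    return out
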