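"""Ploidy-aware paired-end read simulation and quality trimming.

Reads are 150 bp by default, drawn per haplotype template so that every
chromosome copy receives its own coverage (10x per copy: diploid regions see
20x in total, haploid regions 10x). Fragments are drawn within ploidy-class
segments — PAR and non-PAR sequence are simulated as separate templates with
their own coverage settings, so no fragment spans a PAR/non-PAR junction.

The trimmer applies end-quality trimming (maximal low-quality runs removed
from both read ends), a minimum post-trim length, and a minimum mean quality,
with mates dropped jointly when either fails.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import dna
from .genome_sim import GenomeArchitecture, ReferencePair, SampleTruth


@dataclass(frozen=True)
class ReadParams:
    """Read-length, fragment and base-quality model parameters.

    The per-base error probability is derived from the simulated quality
    string as ``10**(-Q/10)``. Setting ``epsilon`` switches to a constant
    error rate: every base gets the corresponding constant Phred score
    (``epsilon = 0`` yields error-free Q40 reads).
    """

    read_length: int = 150
    frag_mean: float = 350.0
    frag_sd: float = 40.0
    epsilon: float | None = None
    q_high: int = 25
    q_low: int = 12
    low_q_end_prob: float = 0.3  # chance of a low-quality run at each read end
    low_q_run_mean: float = 25.0

    def __post_init__(self) -> None:
        if self.read_length > self.frag_mean:
            raise ValueError("read_length must not exceed mean fragment length")
        if self.epsilon is not None and not 0.0 <= self.epsilon < 0.75:
            raise ValueError("epsilon must be in [0, 0.75)")


@dataclass(frozen=True)
class CoveragePolicy:
    """Expected depth contributed by each chromosome copy (haplotype).

    With the default 10x per copy, diploid regions reach 20x and each haploid
    chromosome copy 10x, matching the study's coverage design.
    """

    depth_per_copy: float = 10.0

    def __post_init__(self) -> None:
        if self.depth_per_copy <= 0:
            raise ValueError("depth must be > 0")


@dataclass(frozen=True)
class TrimConfig:
    trimq: int = 20  # end-trim bases with Phred < trimq
    minlen: int = 75  # discard reads shorter than this after trimming
    maq: int = 20  # discard reads with mean Phred below this

    def __post_init__(self) -> None:
        if min(self.trimq, self.minlen, self.maq) < 0:
            raise ValueError("trim thresholds must be >= 0")


@dataclass
class Mate:
    """One mate of a pair: sequence/quality codes plus hidden truth origin."""

    seq: np.ndarray  # uint8 base codes, read orientation
    qual: np.ndarray  # uint8 Phred scores
    chrom: str
    hap: str
    start: int  # 0-based genomic start of the aligned-through portion
    strand: str  # '+' mate matches the reference forward strand

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    read_id: str
    mate1: Mate
    mate2: Mate

    @property
    def mates(self) -> tuple[Mate, Mate]:
        return (self.mate1, self.mate2)


def _haplotype_sequence(
    refpair: ReferencePair, sample: SampleTruth, hap_name: str
) -> np.ndarray:
    """Anchor-chromosome sequence with the haplotype's golden SNPs applied."""
    hap = next(h for h in sample.haplotypes if h.name == hap_name)
    seq = refpair.seqs[hap.chrom].copy()
    for _, pos, _, alt in sample.snps[hap_name]:
        seq[pos] = alt
    return seq


def _qualities(rng: np.random.Generator, length: int, params: ReadParams) -> np.ndarray:
    if params.epsilon is not None:
        q = 40 if params.epsilon == 0 else int(round(-10.0 * np.log10(params.epsilon)))
        return np.full(length, q, dtype=np.uint8)
    qual = np.full(length, params.q_high, dtype=np.uint8)
    for end in (0, 1):
        if rng.random() < params.low_q_end_prob:
            run = min(length, rng.geometric(1.0 / params.low_q_run_mean))
            if end == 0:
                qual[:run] = params.q_low
            else:
                qual[length - run :] = params.q_low
    return qual


def _apply_errors(
    rng: np.random.Generator, seq: np.ndarray, qual: np.ndarray, params: ReadParams
) -> np.ndarray:
    err = (
        np.full(len(seq), params.epsilon)
        if params.epsilon is not None
        else dna.phred_to_error(qual)
    )
    flip = rng.random(len(seq)) < err
    out = seq.copy()
    n = int(flip.sum())
    if n:
        out[flip] = (out[flip] + rng.integers(1, 4, size=n)) % 4
    return out


def simulate_reads(
    sample: SampleTruth,
    refpair: ReferencePair,
    arch: GenomeArchitecture,
    policy: CoveragePolicy = CoveragePolicy(),
    params: ReadParams = ReadParams(),
    seed: int = 0,
) -> list[ReadPair]:
    """Simulate paired-end reads for one sample across all its haplotypes.

    Fragment counts per template interval are ``depth * span / (2 * read
    length)``; fragment starts are uniform, lengths Normal(frag_mean,
    frag_sd) clipped to [read_length, span]. Mate 1 is the fragment 5' end on
    the forward strand; mate 2 is the reverse-complemented 3' end. Intervals
    shorter than the read length are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    L = params.read_length
    pairs: list[ReadPair] = []
    idx = 0
    for hap in sample.haplotypes:
        seq = _haplotype_sequence(refpair, sample, hap.name)
        for s, e in hap.intervals:
            span = e - s
            if span < L:
                warnings.warn(
                    f"interval {hap.chrom}:[{s},{e}) shorter than read length; skipped"
                )
                continue
            n_pairs = int(round(policy.depth_per_copy * span / (2.0 * L)))
            frag_lens = np.clip(
                np.round(rng.normal(params.frag_mean, params.frag_sd, size=n_pairs)),
                L,
                span,
            ).astype(np.int64)
            starts = s + (rng.random(n_pairs) * (span - frag_lens + 1)).astype(np.int64)
            for fl, st in zip(frag_lens, starts):
                st2 = int(st + fl - L)
                seq1 = seq[st : st + L].copy()
                seq2 = dna.revcomp(seq[st2 : st2 + L])
                q1 = _qualities(rng, L, params)
                q2 = _qualities(rng, L, params)
                m1 = Mate(_apply_errors(rng, seq1, q1, params), q1, hap.chrom, hap.name, int(st), "+")
                m2 = Mate(_apply_errors(rng, seq2, q2, params), q2, hap.chrom, hap.name, st2, "-")
                pairs.append(ReadPair(f"{sample.sample_id}.{hap.name}.{idx}", m1, m2))
                idx += 1
    return pairs


def truth_table(pairs: Iterable[ReadPair]) -> pd.DataFrame:
    """Hidden-truth read placements as a tidy table (one row per mate)."""
    rows = []
    for p in pairs:
        for i, m in enumerate(p.mates, start=1):
            rows.append((p.read_id, i, m.chrom, m.hap, m.start, m.strand, len(m)))
    return pd.DataFrame(
        rows, columns=["read_id", "mate", "chrom", "hap", "start", "strand", "length"]
    )


def realized_depth(
    pairs: Iterable[ReadPair], chrom: str, start: int, end: int
) -> float:
    """Mean truth-placement depth over [start, end) on ``chrom``."""
    cov = np.zeros(end - start, dtype=np.int64)
    for p in pairs:
        for m in p.mates:
            if m.chrom != chrom:
                continue
            lo, hi = max(m.start, start), min(m.start + len(m), end)
            if lo < hi:
                cov[lo - start : hi - start] += 1
    return float(cov.mean())


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


def _trim_mate(mate: Mate, cfg: TrimConfig) -> tuple[Mate | None, str]:
    """Apply end trimming + length/mean-quality gates to one mate."""
    q = mate.qual
    keep = np.flatnonzero(q >= cfg.trimq)
    if keep.size == 0:
        return None, "too_short"
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    if hi - lo < cfg.minlen:
        return None, "too_short"
    if float(q[lo:hi].mean()) < cfg.maq:
        return None, "low_mean_q"
    if lo == 0 and hi == len(q):
        return mate, "kept"
    # adjust the genomic start of the retained portion
    if mate.strand == "+":
        new_start = mate.start + lo
    else:  # read position 0 sits at the genomic 3' end
        new_start = mate.start + (len(q) - hi)
    trimmed = Mate(mate.seq[lo:hi], mate.qual[lo:hi], mate.chrom, mate.hap, new_start, mate.strand)
    return trimmed, "trimmed"


def trim_reads(
    pairs: Sequence[ReadPair], cfg: TrimConfig = TrimConfig()
) -> tuple[list[ReadPair], pd.DataFrame]:
    """bbduk-style trimming: qtrim from both ends at ``trimq``, drop reads
    shorter than ``minlen`` or with mean quality below ``maq``.

    Mates are dropped jointly: a pair survives only if both mates pass.
    Returns the surviving (possibly shortened) pairs and a disposition log.
    """
    kept: list[ReadPair] = []
    log_rows = []
    for p in pairs:
        m1, d1 = _trim_mate(p.mate1, cfg)
        m2, d2 = _trim_mate(p.mate2, cfg)
        ok = m1 is not None and m2 is not None
        log_rows.append((p.read_id, d1, d2, "kept" if ok else "dropped"))
        if ok:
            kept.append(ReadPair(p.read_id, m1, m2))
    log = pd.DataFrame(log_rows, columns=["read_id", "mate1", "mate2", "pair"])
    return kept, log


# ---------------------------------------------------------------------------
# FASTQ IO
# ---------------------------------------------------------------------------


def write_fastq(
    pairs: Sequence[ReadPair], path1: str | os.PathLike, path2: str | os.PathLike
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            for fh, mate, tag in ((f1, p.mate1, "/1"), (f2, p.mate2, "/2")):
                qual = "".join(chr(q + 33) for q in mate.qual)
                fh.write(f"@{p.read_id}{tag}\n{dna.decode(mate.seq)}\n+\n{qual}\n")


def read_fastq_pair(
    path1: str | os.PathLike, path2: str | os.PathLike
) -> list[ReadPair]:
    """Load a FASTQ pair written by :func:`write_fastq` (origins unknown)."""

    def _records(path):
        recs = []
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if len(lines) % 4:
            raise ValueError(f"malformed FASTQ (truncated record) in {path}")
        for i in range(0, len(lines), 4):
            if not lines[i].startswith("@") or lines[i + 2][:1] != "+":
                raise ValueError(f"malformed FASTQ record at index {i // 4} in {path}")
            name = lines[i][1:].split("/")[0]
            seq = dna.encode(lines[i + 1])
            qual = np.frombuffer(lines[i + 3].encode(), dtype=np.uint8) - 33
            if len(seq) != len(qual):
                raise ValueError(f"length mismatch at record {i // 4} in {path}")
            recs.append((name, seq, qual.astype(np.uint8)))
        return recs

    out = []
    for (n1, s1, q1), (n2, s2, q2) in zip(_records(path1), _records(path2), strict=True):
        if n1 != n2:
            raise ValueError(f"mate name mismatch: {n1} vs {n2}")
        m1 = Mate(s1, q1, chrom="", hap="", start=-1, strand="+")
        m2 = Mate(s2, q2, chrom="", hap="", start=-1, strand="-")
        out.append(ReadPair(n1, m1, m2))
    return out
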