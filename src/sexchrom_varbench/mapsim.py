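"""A small, fully specified read mapper for toy genomes.

The mapper reproduces the mapping phenomena that drive sex-chromosome variant
calling artifacts without emulating any particular aligner's heuristics:

* best placement by ungapped mismatch count over the full read, both strands;
* reference ``N`` counts as a mismatch, so hard-masked homologs can never
  compete with an unmasked true locus;
* ties among co-optimal placements collapse MAPQ to 0, with the reported
  placement chosen by a deterministic per-read tie hash (seeded) — the
  multi-mapper regime that empties the PARs under an unmasked default
  reference;
* otherwise ``MAPQ = min(60, 6 * (second_best_mismatches - best) + 20)``, a
  declared surrogate whose two regimes that matter downstream are MAPQ 0
  (tie) and MAPQ >= 40 (confidently unique).

Candidate placements come from a k-mer seed index; splitting a read of length
L into ``L // k`` non-overlapping seeds guarantees that every placement with
fewer than ``L // k`` mismatches is found (pigeonhole), which on these
genomes makes the seeded mapper equivalent to an exhaustive Hamming scan
(property-tested).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import dna
from .read_sim import ReadPair

DEFAULT_K = 11
_PAD = 200  # N padding between concatenated chromosomes


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chrom: str
    start: int  # 0-based
    strand: str
    nm: int  # mismatch count of the chosen placement
    mapq: int
    length: int


@dataclass
class AlignedRead:
    """An alignment together with the read bases/qualities it places."""

    aln: Alignment
    seq: np.ndarray  # reference-orientation base codes
    qual: np.ndarray  # reference-orientation Phred scores


class ReferenceIndex:
    """Exact k-mer index over the concatenated reference."""

    def __init__(self, seqs: Mapping[str, np.ndarray], k: int = DEFAULT_K):
        self.k = k
        self.chroms = list(seqs)
        parts, offsets, pos = [], {}, 0
        for name in self.chroms:
            arr = np.asarray(seqs[name], dtype=np.uint8)
            offsets[name] = pos
            parts.append(arr)
            parts.append(np.full(_PAD, dna.N, dtype=np.uint8))
            pos += len(arr) + _PAD
        self.genome = np.concatenate(parts)
        self.offsets = offsets
        self.lengths = {name: len(seqs[name]) for name in self.chroms}
        self._starts = np.array([offsets[c] for c in self.chroms])
        self._ends = np.array([offsets[c] + self.lengths[c] for c in self.chroms])
        self._build()

    def _build(self) -> None:
        g, k = self.genome, self.k
        n = len(g) - k + 1
        keys = np.zeros(n, dtype=np.int64)
        for j in range(k):
            keys = keys * 4 + g[j : n + j]
        has_n = np.convolve((g == dna.N).astype(np.int64), np.ones(k, dtype=np.int64))[
            k - 1 : n + k - 1
        ]
        valid = np.flatnonzero(has_n == 0)
        vkeys = keys[valid]
        order = np.argsort(vkeys, kind="stable")
        sorted_keys = vkeys[order]
        self._sorted_pos = valid[order]
        uniq, starts = np.unique(sorted_keys, return_index=True)
        bounds = np.append(starts, len(sorted_keys))
        self._slices = {int(key): (int(starts[i]), int(bounds[i + 1])) for i, key in enumerate(uniq)}

    def lookup(self, key: int) -> np.ndarray:
        sl = self._slices.get(key)
        if sl is None:
            return np.empty(0, dtype=np.int64)
        return self._sorted_pos[sl[0] : sl[1]]

    def locate(self, flat_start: int, length: int) -> tuple[str, int] | None:
        """Map a flat coordinate to (chrom, start); None if it spans padding."""
        i = int(np.searchsorted(self._starts, flat_start, side="right")) - 1
        if i < 0:
            return None
        chrom = self.chroms[i]
        if flat_start + length > self._ends[i]:
            return None
        return chrom, flat_start - self.offsets[chrom]


def _seed_candidates(index: ReferenceIndex, read: np.ndarray) -> np.ndarray:
    k = index.k
    nseg = len(read) // k
    cands = []
    for i in range(nseg):
        o = i * k
        seg = read[o : o + k]
        if (seg >= 4).any():
            continue
        key = 0
        for b in seg:
            key = key * 4 + int(b)
        hits = index.lookup(key)
        if hits.size:
            cands.append(hits - o)
    if not cands:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(cands))


def _score(index: ReferenceIndex, starts: np.ndarray, read: np.ndarray) -> np.ndarray:
    L = len(read)
    windows = index.genome[starts[:, None] + np.arange(L)]
    return (windows != read).sum(axis=1)


def placements(
    seq: np.ndarray, index: ReferenceIndex
) -> list[tuple[str, int, str, int]]:
    """All scored candidate placements of a read: (chrom, start, strand, nm)."""
    out: list[tuple[str, int, str, int]] = []
    L = len(seq)
    for strand, read in (("+", seq), ("-", dna.revcomp(seq))):
        starts = _seed_candidates(index, read)
        if not starts.size:
            continue
        keep = []
        for s in starts:
            loc = index.locate(int(s), L)
            if loc is not None:
                keep.append((int(s), loc))
        if not keep:
            continue
        flat = np.array([s for s, _ in keep], dtype=np.int64)
        nms = _score(index, flat, read)
        out.extend(
            (loc[0], loc[1], strand, int(nm)) for (_, loc), nm in zip(keep, nms)
        )
    return out


def exhaustive_best(
    seq: np.ndarray, seqs: Mapping[str, np.ndarray]
) -> tuple[list[tuple[str, int, str, int]], int | None]:
    """Full Hamming scan over every offset of every chromosome, both strands.

    Oracle for the seeded mapper: returns the exact co-optimal placement set
    and the runner-up mismatch count, with every placement evaluated.
    Quadratic; intended for genomes <= a few hundred kb in tests.
    """
    L = len(seq)
    best_nm: int | None = None
    second_nm: int | None = None
    co: list[tuple[str, int, str, int]] = []
    for strand, read in (("+", seq), ("-", dna.revcomp(seq))):
        for chrom, ref in seqs.items():
            n = len(ref) - L + 1
            if n <= 0:
                continue
            nm = np.zeros(n, dtype=np.int32)
            for j in range(L):
                nm += ref[j : n + j] != read[j]
            lo = int(nm.min())
            if best_nm is None or lo < best_nm:
                if best_nm is not None:
                    second_nm = best_nm if second_nm is None else min(second_nm, best_nm)
                best_nm, co = lo, []
            if lo == best_nm:
                co.extend(
                    (chrom, int(s), strand, lo) for s in np.flatnonzero(nm == lo)
                )
            above = nm[nm > best_nm]
            if above.size:
                nxt = int(above.min())
                second_nm = nxt if second_nm is None else min(second_nm, nxt)
    return co, second_nm


def best_placements(
    cands: Sequence[tuple[str, int, str, int]]
) -> tuple[list[tuple[str, int, str, int]], int | None]:
    """Co-optimal placement set and the runner-up mismatch count."""
    if not cands:
        return [], None
    best = min(nm for _, _, _, nm in cands)
    co = [c for c in cands if c[3] == best]
    others = [nm for _, _, _, nm in cands if nm > best]
    return co, (min(others) if others else None)


def _mapq(best_nm: int, second_nm: int | None, n_co: int) -> int:
    if n_co >= 2:
        return 0
    if second_nm is None:
        return 60
    return min(60, 6 * (second_nm - best_nm) + 20)


def align_read(
    read_id: str,
    seq: np.ndarray,
    index: ReferenceIndex,
    tie_seed: int = 0,
    max_mismatch_frac: float = 0.25,
) -> Alignment | None:
    """Best placement of one read, or None if nothing acceptable exists.

    Reads whose best placement exceeds ``max_mismatch_frac * L`` mismatches
    (e.g. all-N reads, or reads whose only home is fully masked) are
    unaligned. Among co-optimal placements one is chosen pseudo-randomly as
    a deterministic function of (tie_seed, read id) — like a production
    aligner's per-read tie hash, the same read picks the same home whenever
    its candidate set is unchanged, so masking-strategy contrasts are not
    blurred by placement noise. The golden truth table, not the placement,
    defines correctness downstream.
    """
    L = len(seq)
    if L == 0 or not any(index.lengths[c] >= L for c in index.chroms):
        return None
    co, second_nm = best_placements(placements(seq, index))
    if not co:
        return None
    best_nm = co[0][3]
    if best_nm > max_mismatch_frac * L:
        return None
    if len(co) > 1:
        h = zlib.crc32(read_id.encode()) ^ (tie_seed & 0xFFFFFFFF)
        pick = sorted(co)[h % len(co)]
    else:
        pick = co[0]
    chrom, start, strand, nm = pick
    return Alignment(read_id, chrom, start, strand, nm, _mapq(best_nm, second_nm, len(co)), L)


def align_pairs(
    pairs: Iterable[ReadPair],
    index: ReferenceIndex,
    seed: int,
    max_mismatch_frac: float = 0.25,
) -> list[AlignedRead]:
    """Align both mates of each pair independently (no pairing constraints)."""
    out: list[AlignedRead] = []
    for p in pairs:
        for mate_no, m in enumerate(p.mates, start=1):
            aln = align_read(f"{p.read_id}/{mate_no}", m.seq, index, seed, max_mismatch_frac)
            if aln is None:
                continue
            if aln.strand == "+":
                seq, qual = m.seq, m.qual
            else:
                seq, qual = dna.revcomp(m.seq), m.qual[::-1]
            out.append(AlignedRead(aln, seq, qual))
    return out


def write_alignment_tsv(aligned: Sequence[AlignedRead], path) -> None:
    """SAM-like TSV: read, chrom, pos (1-based), strand, NM, MAPQ."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tpos\tstrand\tNM\tMAPQ\n")
        for ar in aligned:
            a = ar.aln
            fh.write(f"{a.read_id}\t{a.chrom}\t{a.start + 1}\t{a.strand}\t{a.nm}\t{a.mapq}\n")


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


@dataclass
class PileupColumn:
    """Per-site stack of read observations (raw depth: no MAPQ filtering)."""

    chrom: str
    pos: int  # 1-based
    ref: int  # reference base code
    bases: np.ndarray
    quals: np.ndarray
    mapqs: np.ndarray
    strands: np.ndarray  # 1 = forward
    enddists: np.ndarray  # distance from the nearer read end

    @property
    def depth(self) -> int:
        return len(self.bases)


class Pileup:
    """Column-store pileup for one sample over a shared reference."""

    def __init__(self, reference: Mapping[str, np.ndarray]):
        self.reference = reference
        self._cols: dict[str, dict[str, np.ndarray]] = {}

    @classmethod
    def from_aligned(
        cls, aligned: Iterable[AlignedRead], reference: Mapping[str, np.ndarray]
    ) -> "Pileup":
        self = cls(reference)
        per_chrom: dict[str, list] = {}
        for ar in aligned:
            if ar.aln.chrom not in reference:
                raise KeyError(f"alignment on unknown chromosome {ar.aln.chrom!r}")
            per_chrom.setdefault(ar.aln.chrom, []).append(ar)
        for chrom, items in per_chrom.items():
            pos_l, base_l, qual_l, mapq_l, strand_l, end_l = [], [], [], [], [], []
            for ar in items:
                L = ar.aln.length
                pos_l.append(np.arange(ar.aln.start, ar.aln.start + L, dtype=np.int64))
                base_l.append(ar.seq)
                qual_l.append(ar.qual)
                mapq_l.append(np.full(L, ar.aln.mapq, dtype=np.uint8))
                strand_l.append(np.full(L, 1 if ar.aln.strand == "+" else 0, dtype=np.uint8))
                idx = np.arange(L)
                end_l.append(np.minimum(idx, L - 1 - idx).astype(np.uint16))
            pos = np.concatenate(pos_l)
            order = np.argsort(pos, kind="stable")
            self._cols[chrom] = {
                "pos": pos[order],
                "base": np.concatenate(base_l)[order],
                "qual": np.concatenate(qual_l)[order],
                "mapq": np.concatenate(mapq_l)[order],
                "strand": np.concatenate(strand_l)[order],
                "enddist": np.concatenate(end_l)[order],
            }
        return self

    def chroms(self) -> list[str]:
        return list(self._cols)

    def arrays(self, chrom: str) -> dict[str, np.ndarray]:
        return self._cols.get(chrom, {k: np.empty(0) for k in ("pos", "base", "qual", "mapq", "strand", "enddist")})

    def slice_at(self, chrom: str, pos0: int) -> dict[str, np.ndarray]:
        """All read observations covering 0-based position ``pos0``."""
        cols = self._cols.get(chrom)
        if cols is None:
            return {k: np.empty(0, dtype=np.int64) for k in ("pos", "base", "qual", "mapq", "strand", "enddist")}
        lo = int(np.searchsorted(cols["pos"], pos0, side="left"))
        hi = int(np.searchsorted(cols["pos"], pos0, side="right"))
        return {k: v[lo:hi] for k, v in cols.items()}

    def column(self, chrom: str, pos: int) -> PileupColumn:
        """1-based accessor returning a :class:`PileupColumn`."""
        sl = self.slice_at(chrom, pos - 1)
        return PileupColumn(
            chrom,
            pos,
            int(self.reference[chrom][pos - 1]),
            sl["base"],
            sl["qual"],
            sl["mapq"],
            sl["strand"],
            sl["enddist"],
        )

    def total_aligned_bases(self) -> int:
        return sum(len(c["pos"]) for c in self._cols.values())


def build_pileups(
    aligned: Iterable[AlignedRead], reference: Mapping[str, np.ndarray]
) -> Pileup:
    """One pileup column per covered reference position for one sample."""
    return Pileup.from_aligned(aligned, reference)
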