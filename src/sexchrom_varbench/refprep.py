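"""Sex-chromosome-complement reference preparation by hard masking.

Four reference variants are produced from one simulated X/Y pair:

``default``
    No masking; both PAR copies (and the XTR) present on X and Y. This is the
    reference a standard autosomal pipeline would use.
``xx_scc``
    Entire Y chromosome hard-masked — the complement-matched reference for
    samples without a Y.
``xy_scc``
    Y PAR1 + PAR2 hard-masked — the complement-matched reference for XY
    samples (PAR variation is represented on X only).
``xy_scc_yxtr_masked``
    Y PARs plus the Y XTR hard-masked — the tested (and rejected) strategy of
    forcing all XTR reads onto the X copy.

Hard masking replaces bases with ``N``; lengths and unmasked bases are never
altered.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np

from . import dna
from .genome_sim import GenomeArchitecture, ReferencePair

REFERENCE_KINDS = ("default", "xx_scc", "xy_scc", "xy_scc_yxtr_masked")


def mask_intervals(
    seqs: Mapping[str, np.ndarray],
    intervals: Iterable[tuple[str, int, int]],
) -> dict[str, np.ndarray]:
    """Return copies of ``seqs`` with every base in ``intervals`` set to N.

    Intervals are (chrom, start, end), 0-based half-open; an interval beyond
    its sequence end is an error naming the interval. Masking is idempotent
    and order-independent.
    """
    out = {name: np.asarray(s, dtype=np.uint8).copy() for name, s in seqs.items()}
    for chrom, start, end in intervals:
        if chrom not in out:
            raise ValueError(f"interval on unknown sequence {chrom!r}")
        n = len(out[chrom])
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"interval {chrom}:[{start},{end}) outside sequence of length {n}"
            )
        out[chrom][start:end] = dna.N
    return out


def mask_fasta(
    fasta_in: str | os.PathLike, bed: str | os.PathLike, fasta_out: str | os.PathLike
) -> None:
    """File-level wrapper: hard-mask BED intervals in a FASTA (bedtools-maskfasta-like)."""
    seqs = dna.read_fasta(fasta_in)
    rows = [(c, s, e) for c, s, e, *_ in dna.read_bed(bed)]
    dna.write_fasta(mask_intervals(seqs, rows), fasta_out)


def masking_intervals(
    kind: str, arch: GenomeArchitecture
) -> list[tuple[str, int, int]]:
    """The hard-mask set defining each reference kind."""
    if kind == "default":
        return []
    if kind == "xx_scc":
        if "Y" not in arch.chrom_lengths:
            return []
        return [("Y", 0, arch.chrom_lengths["Y"])]
    if kind == "xy_scc":
        return [("Y", s, e) for s, e in arch.par_intervals("Y")]
    if kind == "xy_scc_yxtr_masked":
        ivls = [("Y", s, e) for s, e in arch.par_intervals("Y")]
        ivls += [("Y", s, e) for s, e in arch.intervals("XTR", "Y")]
        return ivls
    raise ValueError(f"unknown reference kind {kind!r}; expected one of {REFERENCE_KINDS}")


def build_reference(
    kind: str, refpair: ReferencePair, arch: GenomeArchitecture
) -> dict[str, np.ndarray]:
    """Materialize one of the four reference variants as code arrays."""
    return mask_intervals(refpair.seqs, masking_intervals(kind, arch))
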