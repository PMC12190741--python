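"""Small sequence codec and plain-text genomics IO helpers.

Sequences are held as ``numpy.uint8`` code arrays (A=0, C=1, G=2, T=3, N=4)
throughout the package; strings only appear at file boundaries.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement map over codes; N stays N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (unknown letters become N)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def write_fasta(seqs: Mapping[str, np.ndarray], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, codes in seqs.items():
            fh.write(f">{name}\n")
            s = decode(np.asarray(codes, dtype=np.uint8))
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Read a FASTA file into code arrays (indexed access via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, build_index=True)
    out = {name: encode(str(fa[name][:])) for name in fa.keys()}
    fa.close()
    return out


def write_bed(intervals: Iterable[Sequence], path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name]) rows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple]:
    rows: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = (parts[0], int(parts[1]), int(parts[2]), *parts[3:])
            rows.append(row)
    return rows


def phred_to_error(quals: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Convert Phred scores to error probabilities, clipped to [floor, 0.75]."""
    e = np.power(10.0, -np.asarray(quals, dtype=float) / 10.0)
    return np.clip(e, floor, 0.75)
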