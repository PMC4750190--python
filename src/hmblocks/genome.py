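"""In-memory genome sequences with FASTA I/O and GC utilities."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping

import numpy as np

ALPHABET = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
# complement code: A<->T, C<->G, N->N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A=0 C=1 G=2 T=3, anything else N=4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


class Genome:
    """Per-chromosome sequences stored as uint8 code arrays."""

    def __init__(self, chrom_codes: Mapping[str, np.ndarray]) -> None:
        self._codes: Dict[str, np.ndarray] = {
            c: np.asarray(a, dtype=np.uint8) for c, a in chrom_codes.items()
        }

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "Genome":
        return cls({c: encode(s) for c, s in sequences.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from Bio import SeqIO

        codes: Dict[str, np.ndarray] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            codes[record.id] = encode(str(record.seq))
        if not codes:
            raise ValueError(f"no sequences found in FASTA {path}")
        return cls(codes)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._codes)

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in sorted(self._codes.items())}

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def fetch_codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self._codes[chrom]
        if start < 0 or end > len(arr) or start >= end:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside chromosome (length {len(arr)})"
            )
        return arr[start:end]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return decode(self.fetch_codes(chrom, start, end))

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        """GC fraction of called (non-N) bases; 0.0 if all N."""
        codes = self.fetch_codes(chrom, start, end)
        called = codes < 4
        n_called = int(called.sum())
        if n_called == 0:
            return 0.0
        gc = int(np.isin(codes, (1, 2)).sum())
        return gc / n_called

    def base_frequencies(self) -> np.ndarray:
        """Genome-wide A/C/G/T frequencies over called bases."""
        counts = np.zeros(4, dtype=np.int64)
        for arr in self._codes.values():
            counts += np.bincount(arr[arr < 4], minlength=4)
        total = counts.sum()
        if total == 0:
            raise ValueError("genome contains no called bases")
        return counts / total

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with Path(path).open("w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                seq = decode(self._codes[chrom])
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
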