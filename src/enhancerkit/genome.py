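"""In-memory genome with FASTA round-tripping and a designated holdout chromosome.

The holdout chromosome plays the role of a fixed, shared test set: it is
systematically excluded from training and validation everywhere downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta

from .sequences import codes_to_seq, seq_to_codes


@dataclass
class Genome:
    """Chromosome name -> uint8 code array, plus which chromosome is held out."""

    chroms: dict[str, np.ndarray] = field(default_factory=dict)
    holdout_chrom: str | None = None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch_codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        if start < 0 or end > len(self.chroms[chrom]) or start >= end:
            raise IndexError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return self.chroms[chrom][start:end]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return codes_to_seq(self.fetch_codes(chrom, start, end))

    def to_fasta(self, path: str | os.PathLike, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, codes in self.chroms.items():
                fh.write(f">{name}\n")
                seq = codes_to_seq(codes)
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike, holdout_chrom: str | None = None) -> "Genome":
        fa = Fasta(str(path), rebuild=True)
        chroms = {name: seq_to_codes(str(fa[name][:])) for name in fa.keys()}
        if holdout_chrom is not None and holdout_chrom not in chroms:
            raise KeyError(f"holdout chromosome {holdout_chrom!r} not in FASTA")
        return cls(chroms=chroms, holdout_chrom=holdout_chrom)
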