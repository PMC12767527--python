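"""DNA sequence encodings shared across the package.

Bases are coded A=0, C=1, G=2, T=3; anything else (N) is 4.  One-hot
encoding follows A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0], T=[0,0,0,1],
with all-zero rows for N.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of codes 0..4 (N stays N)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """String -> uint8 code array (A=0, C=1, G=2, T=3, other=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def one_hot(seq: str | np.ndarray) -> np.ndarray:
    """Encode a sequence (string or code array) as an (L, 4) float32 matrix."""
    codes = seq_to_codes(seq) if isinstance(seq, str) else np.asarray(seq)
    out = np.zeros((len(codes), 4), dtype=np.float32)
    valid = codes < N_CODE
    out[np.nonzero(valid)[0], codes[valid]] = 1.0
    return out


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` for N-free sequences (all-zero rows -> N)."""
    codes = np.where(mat.sum(axis=1) > 0, mat.argmax(axis=1), N_CODE).astype(np.uint8)
    return codes_to_seq(codes)


def reverse_complement(seq: str) -> str:
    return codes_to_seq(_COMP[seq_to_codes(seq)][::-1])


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def reverse_complement_one_hot(mat: np.ndarray) -> np.ndarray:
    """RC of a one-hot matrix: reverse positions and swap A<->T, C<->G."""
    return mat[::-1, ::-1].copy()


def dinucleotide_counts(seq: str | np.ndarray) -> np.ndarray:
    """4x4 matrix of overlapping dinucleotide counts (N-containing pairs skipped)."""
    codes = seq_to_codes(seq) if isinstance(seq, str) else np.asarray(seq)
    a, b = codes[:-1], codes[1:]
    ok = (a < N_CODE) & (b < N_CODE)
    counts = np.bincount((a[ok].astype(np.int64) * 4 + b[ok]), minlength=16)
    return counts.reshape(4, 4)
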