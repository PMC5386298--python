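"""2-bit k-mer encoding shared by the vector screen and the host anchorer.

Sequences are encoded base-per-byte (A=0, C=1, G=2, T=3, anything else=4);
k-mers become exact integer codes in base 4, so two k-mers share a code iff
they are the same ACGT string.  k is limited to 31 so codes fit in a signed
64-bit integer (4**31 < 2**63).
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_TRANS = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence to an int8 array (A,C,G,T -> 0..3; other -> 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def complement_codes(enc: np.ndarray) -> np.ndarray:
    return _COMP[enc]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_TRANS)[::-1]


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of an encoded sequence.

    Returns ``(codes, valid)`` where ``codes[i]`` is the base-4 code of the
    k-mer starting at position ``i`` and ``valid[i]`` is False when that
    window contains a non-ACGT base (such codes must not be matched).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    e = enc.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + e[j : j + n]
    bad = np.cumsum(np.concatenate(([0], (enc == 4).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def kmer_codes_matrix(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k-mer codes for a batch of equal-length encoded reads.

    ``mat`` is (n_reads, read_len) int8; returns codes of shape
    (n_reads, read_len - k + 1) and a matching validity mask.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = mat.shape[1] - k + 1
    if n <= 0:
        raise ValueError(f"k={k} exceeds read length {mat.shape[1]}")
    e = mat.astype(np.int64)
    codes = np.zeros((mat.shape[0], n), dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + e[:, j : j + n]
    isn = (mat == 4).astype(np.int64)
    bad = np.cumsum(np.concatenate([np.zeros((mat.shape[0], 1), dtype=np.int64), isn], axis=1), axis=1)
    valid = (bad[:, k:] - bad[:, :-k]) == 0
    return codes, valid
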