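"""Low-level 2-bit nucleotide encoding shared by the k-mer and simulation code.

Bases are encoded A=0, C=1, G=2, T=3 (case-insensitive); every other character
maps to the sentinel 255 and invalidates any k-mer window covering it.  The
complement of a valid code is ``3 - code``, which is what makes the vectorised
reverse-complement and canonical-k-mer arithmetic below cheap.
"""

from __future__ import annotations

import numpy as np

#: ASCII byte -> 2-bit code (255 = not A/C/G/T)
CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    CODE[_b] = _i
    CODE[_b + 32] = _i  # lowercase

#: 2-bit code -> ASCII byte
BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_RC_TABLE = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to a uint8 code array (255 for non-ACGT)."""
    return CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a (valid) code array back to an uppercase string."""
    return BASE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence string (keeps N/n)."""
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a valid code array."""
    return (3 - codes)[::-1]


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def rc_kmer_codes(fwd: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement k-mer codes from forward codes, elementwise.

    Complementing a 2-bit base is bitwise NOT within its field; reversing the
    base order is a 2-bit-group reversal of the 64-bit word (two mask-swap
    steps within each byte, then a byteswap) followed by realignment.
    """
    x = np.invert(fwd)
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement k-mer codes for every window.

    ``codes`` is a 1-D uint8 array; windows containing invalid bases yield
    garbage values and must be masked by the caller (see :func:`valid_windows`).
    Returns two uint64 arrays of length ``len(codes) - k + 1``.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.uint64)
    # invalid bases (255) are clipped to keep the packed value in range; the
    # affected windows are discarded by the caller's validity mask
    fwd = np.minimum(codes[0:n], 3).astype(np.uint64)
    for i in range(1, k):
        np.left_shift(fwd, np.uint64(2), out=fwd)
        np.add(fwd, np.minimum(codes[i : i + n], 3), out=fwd, casting="unsafe")
    return fwd, rc_kmer_codes(fwd, k)


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (min of strand pair) k-mer codes for all *valid* windows."""
    fwd, rev = kmer_codes(codes, k)
    canon = np.minimum(fwd, rev)
    return canon[valid_windows(codes, k)]


def valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over windows: True where all k bases are A/C/G/T."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, bool)
    bad = (codes >= 4).astype(np.int32)
    if not bad.any():
        return np.ones(n, bool)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[k:] - cs[:-k]) == 0


def kmer_codes_2d(codes2d: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes for a batch of equal-length valid reads.

    ``codes2d`` has shape (n_reads, read_len) with all entries < 4.  Returns a
    uint64 array of shape (n_reads, read_len - k + 1).
    """
    n = codes2d.shape[1] - k + 1
    if n <= 0:
        return np.empty((codes2d.shape[0], 0), np.uint64)
    fwd = codes2d[:, 0:n].astype(np.uint64)
    for i in range(1, k):
        np.left_shift(fwd, np.uint64(2), out=fwd)
        np.add(fwd, codes2d[:, i : i + n], out=fwd, casting="unsafe")
    rev = rc_kmer_codes(fwd, k)
    np.minimum(fwd, rev, out=fwd)
    return fwd
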