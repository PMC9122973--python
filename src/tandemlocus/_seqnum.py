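"""Vectorised sequence numerics shared by the simulator and read classifier.

DNA is held as uint8 codes 0..3 (A,C,G,T); N maps to 4 and poisons any k-mer
window it touches (N never counts as a match anywhere in the toolkit).
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def comp(codes: np.ndarray) -> np.ndarray:
    """Complement in code space (N stays N)."""
    out = 3 - codes
    out[codes == 4] = 4
    return out.astype(np.uint8)


def kmer_codes(codes: np.ndarray, k: int) -> tuple:
    """All k-mer integer codes of a sequence plus a validity mask.

    Returns ``(values, valid)`` where ``values[i]`` encodes
    ``codes[i:i+k]`` in base 4 (2 bits/base, first base most significant)
    and ``valid[i]`` is False when the window contains an N.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    clean = np.where(codes == 4, 0, codes).astype(np.uint64)
    values = np.zeros(n, dtype=np.uint64)
    for j in range(k):  # Horner roll: 2 bits per base, first base high
        values = (values << np.uint64(2)) | clean[j : j + n]
    bad = (codes == 4)
    if bad.any():
        # a window is invalid when any of its k bases is N
        bad_cum = np.concatenate(([0], np.cumsum(bad)))
        valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    else:
        valid = np.ones(n, dtype=bool)
    return values, valid


def canonical_kmer_codes(codes: np.ndarray, k: int) -> tuple:
    """Canonical (strand-symmetric) k-mer codes: min(fwd, revcomp)."""
    fwd, valid_f = kmer_codes(codes, k)
    rc_seq = comp(codes)[::-1]
    rev, _ = kmer_codes(rc_seq, k)
    rev = rev[::-1]  # align rc k-mer i with fwd k-mer i
    return np.minimum(fwd, rev), valid_f


def kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a sequence."""
    vals, valid = canonical_kmer_codes(encode(seq), k)
    return np.unique(vals[valid])


def kmer_set_both_strands(seq: str, k: int) -> np.ndarray:
    """Sorted unique plain k-mer codes of a sequence and its revcomp.

    Querying this with plain (non-canonical) read k-mers is equivalent to a
    canonical comparison but does half the per-read work."""
    codes = encode(seq)
    fwd, vf = kmer_codes(codes, k)
    rc = comp(codes)[::-1]
    rev, vr = kmer_codes(rc, k)
    return np.unique(np.concatenate([fwd[vf], rev[vr]]))


def isin_sorted(values: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    """Membership of values in a sorted unique array (searchsorted trick)."""
    if len(sorted_set) == 0:
        return np.zeros(len(values), dtype=bool)
    idx = np.searchsorted(sorted_set, values)
    idx[idx == len(sorted_set)] = len(sorted_set) - 1
    return sorted_set[idx] == values
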