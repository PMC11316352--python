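"""Low-level nucleotide sequence utilities shared across modules.

Sequences are handled as plain upper-case strings at the API boundary and as
``numpy.uint8`` code arrays (A=0, C=1, G=2, T=3, N=4) internally.  All k-mer
machinery works on 2-bit packed integer codes; any window containing an
ambiguous base is excluded from indexing and seeding.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string onto uint8 codes (non-ACGT -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _BYTES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    n = int((codes != 4).sum())
    if n == 0:
        return 0.0
    return float(((codes == 1) | (codes == 2)).sum() / n)


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer codes for every window of ``codes``.

    Returns ``(positions, kmers)`` restricted to windows free of ambiguous
    bases.  Empty arrays when the sequence is shorter than ``k``.
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes != 4
    vals = np.where(valid, codes, 0).astype(np.int64)
    # polynomial rolling code base 4 via cumulative trick
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    kmers = np.convolve(vals, weights, mode="valid") if k > 1 else vals.copy()
    ok = (
        np.convolve(valid.astype(np.int64), np.ones(k, dtype=np.int64), mode="valid")
        == k
    )
    pos = np.nonzero(ok)[0]
    return pos, kmers[pos]


class KmerIndex:
    """Exact k-mer lookup table over one reference sequence (forward strand).

    Built once per reference; ``positions(kmer)`` returns every start position
    of the k-mer, in ascending order.
    """

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        self.length = codes.shape[0]
        pos, kmers = kmer_codes(codes, k)
        order = np.argsort(kmers, kind="stable")
        self._sorted_kmers = kmers[order]
        self._sorted_pos = pos[order]

    def positions(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self._sorted_kmers, kmer, side="right")
        return self._sorted_pos[lo:hi]


def expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten half-open index ranges ``[lo_i, hi_i)`` into one index array.

    Returns ``(owner, flat)`` where ``flat`` concatenates
    ``arange(lo_i, hi_i)`` for every i and ``owner[j]`` is the range index
    that produced ``flat[j]``.
    """
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    owner = np.repeat(np.arange(lo.shape[0]), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return owner, np.repeat(lo, counts) + offsets


def ungapped_identity(
    ref: np.ndarray, query: np.ndarray, offset: int
) -> tuple[float, int]:
    """Identity of ``query`` placed at ``offset`` on ``ref``, no gaps.

    Bases hanging off either reference end are clipped; ambiguous reference
    positions (code 4) never match.  Returns ``(matches / aligned_length,
    aligned_length)``; ``(0.0, 0)`` when there is no overlap.
    """
    qlen = query.shape[0]
    q_start = max(0, -offset)
    q_end = min(qlen, ref.shape[0] - offset)
    if q_end <= q_start:
        return 0.0, 0
    r = ref[offset + q_start : offset + q_end]
    q = query[q_start:q_end]
    matches = int(((r == q) & (r != 4)).sum())
    aligned = q_end - q_start
    return matches / aligned, aligned
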