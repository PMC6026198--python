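"""k-mer length planning and lowest-hash k-mer selection.

Two ideas make the k-mer stage both specific and consistent across
homologous sequences:

* The k-mer length is set from the statistics of the input set so that the
  expected number of chance (non-homologous) members per k-mer group is at
  most one: k_spec = floor(log(N * L_avg) / log(A_eff)), where A_eff is the
  effective size of the reduced alphabet.  A floor k_seqid (10, or 14 for
  identity thresholds >= 90%) keeps k-mers long enough for the requested
  clustering identity.  k = max(k_spec, k_seqid).

* From each sequence only the m k-mers with the lowest 16-bit hash values
  are selected.  Because the hash depends only on k-mer content, homologous
  sequences tend to select the same k-mers, while the selection behaves
  like a pseudo-random, positionally spread sample.

The reference hash is FNV-1a (64-bit) over the reduced-code byte sequence,
XOR-folded 64 -> 32 -> 16 bits.  Any optimized reformulation must be
bit-identical to :func:`hash_kmer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from linclust.alphabet import INVALID_CODE

FNV_OFFSET = 0xCBF29CE484222325
FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1

#: Default number of k-mers selected per sequence.
DEFAULT_KMERS_PER_SEQ = 20
#: Sensitivity preset (the "-m80" variant).
SENSITIVE_KMERS_PER_SEQ = 80


@dataclass(frozen=True)
class KmerPlan:
    """The chosen k-mer length and the set statistics behind it.

    ``e_fp_bound = N * L_avg / a_eff**k`` is the implied expected number of
    chance members per k-mer group; it is <= 1 whenever k >= k_spec.
    """

    k: int
    k_spec: int
    k_seqid: int
    N: int
    L_avg: float
    a_eff: float
    e_fp_bound: float


@dataclass(frozen=True)
class SelectedKmer:
    """One selected k-mer: positional base-A code, start offset, 16-bit hash."""

    kmer_code: int
    position: int
    hash16: int


def plan_kmer_length(
    N: int,
    L_avg: float,
    a_eff: float,
    min_seq_id: float = 0.5,
    k_override: int | None = None,
) -> KmerPlan:
    """Choose the k-mer length for a set of ``N`` sequences.

    ``k_override`` (if given) bypasses the automatic choice but the plan
    still reports k_spec/k_seqid and the resulting false-positive bound.
    """
    if N < 1 or L_avg < 1:
        raise ValueError("N and L_avg must be >= 1")
    if a_eff <= 1:
        raise ValueError("a_eff must be > 1")
    if k_override is not None and k_override < 1:
        raise ValueError(f"k override must be >= 1, got {k_override}")
    k_spec = int(math.floor(math.log(N * L_avg) / math.log(a_eff)))
    k_seqid = 14 if min_seq_id >= 0.9 else 10
    k = k_override if k_override is not None else max(k_spec, k_seqid)
    return KmerPlan(
        k=k,
        k_spec=k_spec,
        k_seqid=k_seqid,
        N=N,
        L_avg=L_avg,
        a_eff=a_eff,
        e_fp_bound=N * L_avg / a_eff**k,
    )


def hash_kmer(codes) -> int:
    """Reference 16-bit hash of a k-mer given as reduced-alphabet codes.

    FNV-1a over the code bytes, then XOR-fold 64 -> 32 -> 16 bits.  Pure
    function of the code sequence; callers must not pass wildcards.
    """
    h = FNV_OFFSET
    for c in codes:
        c = int(c)
        if c == INVALID_CODE:
            raise ValueError("wildcard code in k-mer")
        h ^= c
        h = (h * FNV_PRIME) & _MASK64
    h = (h >> 32) ^ (h & 0xFFFFFFFF)
    return (h >> 16) ^ (h & 0xFFFF)


def _window_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized :func:`hash_kmer` over all windows of length ``k``."""
    n = codes.shape[0] - k + 1
    h = np.full(n, FNV_OFFSET, dtype=np.uint64)
    prime = np.uint64(FNV_PRIME)
    for off in range(k):
        h ^= codes[off : off + n].astype(np.uint64)
        h *= prime
    h = (h >> np.uint64(32)) ^ (h & np.uint64(0xFFFFFFFF))
    return ((h >> np.uint64(16)) ^ (h & np.uint64(0xFFFF))).astype(np.uint32)


def _window_codes(codes: np.ndarray, k: int, base: int) -> np.ndarray:
    """Big-endian base-``base`` positional value of every k-window."""
    n = codes.shape[0] - k + 1
    out = np.zeros(n, dtype=np.uint64)
    b = np.uint64(base)
    for off in range(k):
        out = out * b + codes[off : off + n].astype(np.uint64)
    return out


def select_kmer_arrays(
    codes: np.ndarray, mask: np.ndarray, k: int, m: int, base: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array form of :func:`select_kmers`: (kmer_codes, positions, hashes).

    Only windows free of wildcard positions are candidates.  The min(m,
    #valid) windows with the lowest (hash, position) are returned, sorted
    by (hash, position).
    """
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    L = codes.shape[0]
    empty = (
        np.empty(0, dtype=np.uint64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.uint32),
    )
    if L < k:
        return empty
    bad = np.concatenate(([0], np.cumsum(~mask)))
    valid = (bad[k:] - bad[:-k]) == 0
    positions = np.flatnonzero(valid).astype(np.int64)
    if positions.size == 0:
        return empty
    # Hash only over valid windows would break vectorization; wildcard
    # codes are hashed too but those windows are dropped by the mask.
    safe = np.where(mask, codes, 0).astype(np.uint8)
    hashes = _window_hashes(safe, k)[positions]
    kcodes = _window_codes(safe, k, base)[positions]
    order = np.lexsort((positions, hashes))[: min(m, positions.size)]
    return kcodes[order], positions[order], hashes[order]


def select_kmers(codes: np.ndarray, mask: np.ndarray, k: int, m: int, base: int):
    """Select the ``m`` lowest-hash k-mers of an encoded sequence.

    Returns a list of :class:`SelectedKmer` sorted by (hash16, position).
    A sequence shorter than ``k`` yields an empty list; if fewer than ``m``
    valid windows exist, all of them are returned.
    """
    kcodes, positions, hashes = select_kmer_arrays(codes, mask, k, m, base)
    return [
        SelectedKmer(kmer_code=int(c), position=int(p), hash16=int(h))
        for c, p, h in zip(kcodes, positions, hashes)
    ]
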