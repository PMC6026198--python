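"""The m*N k-mer table: grouping, center selection and match diagonals.

Every sequence contributes at most m selected k-mers to a table of records
(kmer_code, seq_id, seq_len, position).  Sorting the table by k-mer code
groups sequences that share a selected k-mer; the longest sequence of each
group (ties: smallest seq_id) becomes the group's *center*.  Every other
group member yields a candidate pair (center, member) with the match
diagonal i - j, where i is the k-mer position in the center and j in the
member.  Duplicate (center, member) pairs keep one diagonal: by default
the diagonal of the shared k-mer with the lowest hash value, whose
distribution over the pair's shared k-mers does not depend on how many
k-mers are selected per sequence; ``diagonal_rule`` can instead keep the
diagonal closest to the main diagonal ("absolute") or the minimum signed
value ("signed").  Because each of a sequence's <= m k-mers joins at most one
group, at most m*N candidate pairs exist in total -- the linearity bound
of the whole pipeline.

For sets whose table does not fit in memory, the table can be built in C
chunks restricted to k-mer codes with ``code % C == c``; every k-mer group
lies wholly inside one chunk, so merging the per-chunk match streams (and
deduplicating across chunks) reproduces the single-pass result exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from linclust.kmer_selection import select_kmer_arrays

#: Sequence lengths are clamped to this value in table records (storage
#: convention of 2-byte length fields); longer sequences keep their true
#: length everywhere else in the pipeline.
MAX_STORED_LEN = 65535


@dataclass(frozen=True)
class KmerRecord:
    """One line of the k-mer table."""

    kmer_code: int
    seq_id: int
    seq_len: int
    position: int
    hash16: int = 0


@dataclass(frozen=True)
class DiagonalMatch:
    """A candidate pair: member shares a selected k-mer with the center."""

    center_id: int
    member_id: int
    diagonal: int
    hash16: int = 0


class KmerTable(NamedTuple):
    """Column-array form of the k-mer table."""

    kmer_code: np.ndarray  # uint64
    seq_id: np.ndarray  # int64
    seq_len: np.ndarray  # int64
    position: np.ndarray  # int64
    hash16: np.ndarray  # uint32, hash of kmer_code

    def __len__(self) -> int:
        return self.kmer_code.shape[0]

    def records(self) -> Iterator[KmerRecord]:
        for c, s, l, p, h in zip(*self):
            yield KmerRecord(int(c), int(s), int(l), int(p), int(h))


class MatchTable(NamedTuple):
    """Column-array form of the candidate-pair list, sorted by
    (center_id, member_id)."""

    center_id: np.ndarray  # int64
    member_id: np.ndarray  # int64
    diagonal: np.ndarray  # int64
    hash16: np.ndarray  # uint32, hash of the seeding k-mer

    def __len__(self) -> int:
        return self.center_id.shape[0]

    def matches(self) -> Iterator[DiagonalMatch]:
        for c, m, d, h in zip(*self):
            yield DiagonalMatch(int(c), int(m), int(d), int(h))


def build_table(
    encoded: Sequence[tuple[np.ndarray, np.ndarray]],
    k: int,
    m: int,
    base: int,
    chunk_filter: tuple[int, int] | None = None,
) -> KmerTable:
    """Build the k-mer table for encoded sequences.

    ``encoded[i]`` is the (reduced codes, validity mask) pair of sequence i;
    seq_ids are assigned by position.  With ``chunk_filter=(C, c)`` only
    records whose kmer_code satisfies ``code % C == c`` are emitted; the
    union of the C chunk tables equals the unchunked table as a multiset,
    because chunking filters the already-selected k-mers.
    """
    if chunk_filter is not None:
        C, c = chunk_filter
        if not 0 <= c < C:
            raise ValueError(f"chunk index {c} outside [0, {C})")
    codes_out: list[np.ndarray] = []
    sids_out: list[np.ndarray] = []
    lens_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    hash_out: list[np.ndarray] = []
    for sid, (codes, mask) in enumerate(encoded):
        kcodes, positions, hashes = select_kmer_arrays(codes, mask, k, m, base)
        if chunk_filter is not None:
            keep = kcodes % np.uint64(C) == np.uint64(c)
            kcodes, positions, hashes = (
                kcodes[keep], positions[keep], hashes[keep]
            )
        if kcodes.size == 0:
            continue
        codes_out.append(kcodes)
        sids_out.append(np.full(kcodes.size, sid, dtype=np.int64))
        seq_len = min(codes.shape[0], MAX_STORED_LEN)
        lens_out.append(np.full(kcodes.size, seq_len, dtype=np.int64))
        pos_out.append(positions)
        hash_out.append(hashes)
    if not codes_out:
        empty = np.empty(0, dtype=np.int64)
        return KmerTable(
            np.empty(0, dtype=np.uint64), empty, empty, empty,
            np.empty(0, dtype=np.uint32),
        )
    return KmerTable(
        np.concatenate(codes_out),
        np.concatenate(sids_out),
        np.concatenate(lens_out),
        np.concatenate(pos_out),
        np.concatenate(hash_out),
    )


def group_and_pick_centers(
    table: KmerTable | Iterable[KmerRecord],
    diagonal_rule: str = "hash",
) -> MatchTable:
    """Sort the table by k-mer code, pick group centers, emit diagonals.

    Within each equal-code block the center is the sequence with maximal
    seq_len (ties: smallest seq_id, then smallest position).  Every other
    block row yields a match with diagonal = center position - member
    position.  The result is sorted by (center_id, member_id) with
    duplicates merged keeping the lowest diagonal under ``diagonal_rule``
    ("hash": the diagonal of the lowest-hash shared k-mer, the default;
    "absolute": smallest |diagonal|; "signed": smallest signed value).
    """
    if not isinstance(table, KmerTable):
        recs = list(table)
        table = KmerTable(
            np.array([r.kmer_code for r in recs], dtype=np.uint64),
            np.array([r.seq_id for r in recs], dtype=np.int64),
            np.array([r.seq_len for r in recs], dtype=np.int64),
            np.array([r.position for r in recs], dtype=np.int64),
            np.array([r.hash16 for r in recs], dtype=np.uint32),
        )
    if len(table) == 0:
        empty = np.empty(0, dtype=np.int64)
        return MatchTable(empty, empty, empty, np.empty(0, dtype=np.uint32))

    kcode, sid, slen, pos, khash = table
    order = np.lexsort((pos, sid, -slen, kcode))
    kcode, sid, slen, pos, khash = (
        kcode[order], sid[order], slen[order], pos[order], khash[order]
    )

    new_block = np.empty(kcode.shape[0], dtype=bool)
    new_block[0] = True
    new_block[1:] = kcode[1:] != kcode[:-1]
    block_id = np.cumsum(new_block) - 1
    starts = np.flatnonzero(new_block)

    center_sid = sid[starts][block_id]
    center_pos = pos[starts][block_id]
    is_member = sid != center_sid
    centers = center_sid[is_member]
    members = sid[is_member]
    diagonals = center_pos[is_member] - pos[is_member]
    hashes = khash[is_member]
    return _dedup_min_diagonal(centers, members, diagonals, hashes,
                               diagonal_rule)


def _dedup_min_diagonal(
    centers: np.ndarray,
    members: np.ndarray,
    diagonals: np.ndarray,
    hashes: np.ndarray,
    diagonal_rule: str = "hash",
) -> MatchTable:
    """Sort by (center, member) keeping the lowest diagonal per pair.

    All rules are total orders (final tie-break: signed diagonal), so the
    result is deterministic and identical across chunked runs.
    """
    if diagonal_rule == "hash":
        order = np.lexsort(
            (diagonals, np.abs(diagonals), hashes, members, centers)
        )
    elif diagonal_rule == "absolute":
        order = np.lexsort((diagonals, np.abs(diagonals), members, centers))
    elif diagonal_rule == "signed":
        order = np.lexsort((diagonals, members, centers))
    else:
        raise ValueError(f"unknown diagonal rule {diagonal_rule!r}")
    centers, members, diagonals, hashes = (
        centers[order], members[order], diagonals[order], hashes[order]
    )
    if centers.size:
        first = np.empty(centers.shape[0], dtype=bool)
        first[0] = True
        first[1:] = (centers[1:] != centers[:-1]) | (members[1:] != members[:-1])
        centers, members, diagonals, hashes = (
            centers[first], members[first], diagonals[first], hashes[first]
        )
    return MatchTable(centers, members, diagonals, hashes)


def write_chunk(path, matches: MatchTable) -> None:
    """Write a chunk's match stream as TSV (center, member, diagonal,
    seed-k-mer hash)."""
    with open(path, "w") as fh:
        for c, m, d, h in zip(*matches):
            fh.write(f"{c}\t{m}\t{d}\t{h}\n")


def read_chunk(path) -> MatchTable:
    """Read a chunk TSV, verifying it is sorted by (center_id, member_id)."""
    with open(path) as fh:
        if not fh.read(1):
            empty = np.empty(0, dtype=np.int64)
            return MatchTable(empty, empty, empty, np.empty(0, dtype=np.uint32))
    rows = np.loadtxt(path, dtype=np.int64, ndmin=2)
    centers, members, diagonals = rows[:, 0], rows[:, 1], rows[:, 2]
    hashes = rows[:, 3].astype(np.uint32)
    key_ok = (centers[1:] > centers[:-1]) | (
        (centers[1:] == centers[:-1]) & (members[1:] >= members[:-1])
    )
    if not key_ok.all():
        raise ValueError(f"chunk file {path} is not sorted by (center, member)")
    return MatchTable(centers, members, diagonals, hashes)


def merge_chunk_outputs(
    chunks: Sequence, diagonal_rule: str = "hash"
) -> MatchTable:
    """Merge per-chunk match streams into one stream sorted by center id.

    ``chunks`` may contain :class:`MatchTable` objects or paths to chunk
    TSV files.  Pairs appearing in several chunks keep the lowest
    diagonal under ``diagonal_rule``.  With a single chunk the output
    equals the input.
    """
    tables = [c if isinstance(c, MatchTable) else read_chunk(c) for c in chunks]
    if not tables:
        empty = np.empty(0, dtype=np.int64)
        return MatchTable(empty, empty, empty, np.empty(0, dtype=np.uint32))
    centers = np.concatenate([t.center_id for t in tables])
    members = np.concatenate([t.member_id for t in tables])
    diagonals = np.concatenate([t.diagonal for t in tables])
    hashes = np.concatenate([t.hash16 for t in tables])
    return _dedup_min_diagonal(centers, members, diagonals, hashes,
                               diagonal_rule)
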