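"""Reduced amino-acid alphabets built from Blosum62 substitution statistics.

A reduced alphabet merges the 20 standard amino acids into a smaller number
of letter groups so that k-mers extracted from homologous sequences are more
likely to match exactly.  Groups are chosen by iterative greedy merging of
the pair of letters whose union loses the least mutual information (MI)
between aligned residue pairs,

    MI = sum_{x,y} p(x,y) * log2( p(x,y) / (p(x) p(y)) ),

where p(x,y) is the probability of observing letters x and y aligned to
each other and p(x) the background probability of x.  Both are taken from
the Blosum62 target (joint) frequencies embedded with the package.

Alphabet sizes follow the convention common to sequence-search tools: the
wildcard letter X counts as one letter, so ``size=13`` (the default) means
12 merged residue groups plus X.  The default 13-letter alphabet merges
(L,M), (I,V), (K,R), (E,Q), (A,S,T), (N,D) and (F,Y).

The reduced alphabet is used only for k-mer extraction and matching; all
residue-level scoring (Hamming, ungapped and gapped alignment) uses the
full 20-letter alphabet with Blosum62 scores.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

#: The 20 standard amino acids, in the row order of the embedded tables.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Code used for the wildcard letter in full-alphabet encodings.
WILDCARD_CODE = 20
#: Sentinel for invalid (wildcard) positions in reduced encodings.
INVALID_CODE = 255

#: Ambiguous or non-standard residue letters; all are treated as wildcard X.
NON_STANDARD = frozenset("BZJUOX")

#: Blosum62 score assigned to the wildcard against every letter (and itself).
#: X never counts as identical anywhere in the pipeline.
WILDCARD_SCORE = -1


@dataclass(frozen=True)
class JointDistribution:
    """Joint distribution p(x,y) of aligned letter pairs.

    ``labels[i]`` is the set of original amino acids merged into letter i,
    stored as a sorted string (e.g. ``"LM"``).  ``p_xy`` is the symmetric
    pair-probability matrix (sums to 1 over all ordered pairs) and ``p_x``
    its marginals.
    """

    labels: tuple[str, ...]
    p_xy: np.ndarray
    p_x: np.ndarray

    def validate(self) -> None:
        n = len(self.labels)
        if self.p_xy.shape != (n, n):
            raise ValueError("p_xy shape does not match labels")
        if not np.allclose(self.p_xy, self.p_xy.T, atol=1e-12):
            raise ValueError("p_xy is not symmetric")
        if (self.p_xy < 0).any():
            raise ValueError("p_xy has negative entries")
        if abs(float(self.p_xy.sum()) - 1.0) > 1e-9:
            raise ValueError("p_xy does not sum to 1")
        if not np.allclose(self.p_x, self.p_xy.sum(axis=1), atol=1e-12):
            raise ValueError("p_x does not equal the row sums of p_xy")

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown letter {label!r}") from None


@dataclass(frozen=True)
class ReducedAlphabet:
    """A partition of the 20 standard amino acids into merged letter groups.

    ``size`` counts the wildcard X, so ``size == len(groups) + 1``.
    ``encode_map`` maps each standard amino-acid character to its group code
    in ``[0, len(groups))``.  ``p_a`` holds the background probability of
    each group and ``a_eff = 1 / sum(p_a^2)`` the effective alphabet size,
    i.e. the inverse probability that two background-drawn letters match.
    """

    size: int
    groups: tuple[str, ...]
    encode_map: dict[str, int]
    p_a: np.ndarray
    a_eff: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @functools.cached_property
    def _char_lookup(self) -> np.ndarray:
        """Maps ASCII byte -> reduced code; INVALID_CODE for wildcards."""
        table = np.full(256, INVALID_CODE, dtype=np.uint8)
        for aa, code in self.encode_map.items():
            table[ord(aa)] = code
            table[ord(aa.lower())] = code
        return table

    @functools.cached_property
    def full_to_code(self) -> np.ndarray:
        """Maps full-alphabet code (0..20) -> reduced code (X -> invalid)."""
        table = np.full(21, INVALID_CODE, dtype=np.uint8)
        for aa, code in self.encode_map.items():
            table[AA_INDEX[aa]] = code
        return table


def _load_qij() -> np.ndarray:
    """Read the embedded Blosum62 target-frequency table (lower triangle).

    Off-diagonal entries are the probability of an *ordered* aligned pair,
    so mirroring the triangle yields the full symmetric matrix.  The matrix
    is renormalized to absorb the rounding of the published 4-decimal values.
    """
    text = (
        resources.files("linclust.data").joinpath("blosum62_qij.txt").read_text()
    )
    q = np.zeros((20, 20))
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        i = AA_INDEX[parts[0]]
        for j, value in enumerate(parts[1:]):
            q[i, j] = q[j, i] = float(value)
    return q / q.sum()


@functools.cache
def _blosum62_scores() -> np.ndarray:
    """21x21 integer Blosum62 score matrix (index 20 = wildcard, scores -1)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    s = np.full((21, 21), WILDCARD_SCORE, dtype=np.int32)
    alpha = mat.alphabet
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = int(mat[alpha.index(a), alpha.index(b)])
    return s


@functools.cache
def load_blosum62() -> tuple[JointDistribution, np.ndarray]:
    """Return the 20-letter Blosum62 joint distribution and score matrix.

    The score matrix is 21x21 with the wildcard as index 20; it is symmetric
    and the wildcard scores -1 against everything including itself.
    """
    p_xy = _load_qij()
    d = JointDistribution(
        labels=tuple(AMINO_ACIDS),
        p_xy=p_xy,
        p_x=p_xy.sum(axis=1),
    )
    d.validate()
    return d, _blosum62_scores()


def mutual_information(d: JointDistribution) -> float:
    """Mutual information (bits) between aligned letters under ``d``."""
    p = d.p_xy
    outer = np.outer(d.p_x, d.p_x)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / outer[mask])))


def merge_letters(d: JointDistribution, a: str, b: str) -> JointDistribution:
    """Merge letters ``a`` and ``b`` of ``d`` into one.

    Probabilities add: p(a') = p(a) + p(b) and p(a', y) = p(a, y) + p(b, y).
    The merged letter keeps position min(i, j); its label is the sorted union
    of the two labels.
    """
    if a == b:
        raise ValueError("cannot merge a letter with itself")
    i, j = d.index_of(a), d.index_of(b)
    i, j = min(i, j), max(i, j)
    p = d.p_xy.copy()
    p[i, :] += p[j, :]
    p[:, i] += p[:, j]
    p = np.delete(np.delete(p, j, axis=0), j, axis=1)
    merged = "".join(sorted(d.labels[i] + d.labels[j]))
    labels = tuple(
        merged if k == i else lab
        for k, lab in enumerate(d.labels)
        if k != j
    )
    return JointDistribution(labels=labels, p_xy=p, p_x=p.sum(axis=1))


def _greedy_merge(d: JointDistribution, n_merges: int) -> JointDistribution:
    """Perform ``n_merges`` greedy MI-preserving merges.

    Each step merges the pair leaving maximum MI; ties (within 1e-12) go to
    the lexicographically smallest (label, label) pair for determinism.
    """
    for _ in range(n_merges):
        best_mi = -np.inf
        best_pair: tuple[str, str] | None = None
        n = len(d.labels)
        for i in range(n):
            for j in range(i + 1, n):
                candidate = merge_letters(d, d.labels[i], d.labels[j])
                mi = mutual_information(candidate)
                pair = tuple(sorted((d.labels[i], d.labels[j])))
                if mi > best_mi + 1e-12 or (
                    abs(mi - best_mi) <= 1e-12
                    and (best_pair is None or pair < best_pair)
                ):
                    best_mi = mi
                    best_pair = pair
        assert best_pair is not None
        d = merge_letters(d, best_pair[0], best_pair[1])
    return d


def build_reduced_alphabet(d: JointDistribution, size: int) -> ReducedAlphabet:
    """Greedily reduce ``d`` to an alphabet of ``size`` letters.

    ``size`` includes the wildcard letter, i.e. ``size - 1`` residue groups
    are produced by ``20 - (size - 1)`` greedy merges.  ``size=21`` returns
    the identity partition.
    """
    if not 2 < size <= 21:
        raise ValueError(f"alphabet size must be in (2, 21], got {size}")
    n_groups = size - 1
    d = _greedy_merge(d, 20 - n_groups)
    groups = tuple(sorted(d.labels))
    order = [d.labels.index(g) for g in groups]
    p_a = d.p_x[order].copy()
    encode_map = {aa: code for code, g in enumerate(groups) for aa in g}
    return ReducedAlphabet(
        size=size,
        groups=groups,
        encode_map=encode_map,
        p_a=p_a,
        a_eff=float(1.0 / np.sum(p_a**2)),
    )


def effective_size(alphabet: ReducedAlphabet) -> float:
    """Effective alphabet size 1 / sum(p_a^2) of ``alphabet``."""
    return float(1.0 / np.sum(alphabet.p_a**2))


@functools.cache
def default_alphabet(size: int = 13) -> ReducedAlphabet:
    """The reduced alphabet of ``size`` letters built from Blosum62 (cached)."""
    d, _ = load_blosum62()
    return build_reduced_alphabet(d, size)


def encode(sequence: str, alphabet: ReducedAlphabet) -> tuple[np.ndarray, np.ndarray]:
    """Encode an amino-acid string into reduced codes plus a validity mask.

    Standard residues map through ``alphabet.encode_map`` (case-insensitive).
    B, Z, J, U, O, X and any unrecognized character are wildcards: their
    code is ``INVALID_CODE`` and their mask entry is False, which prevents
    any k-mer window covering them from being extracted.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = alphabet._char_lookup[raw]
    return codes, codes != INVALID_CODE


def encode_full(sequence: str) -> np.ndarray:
    """Encode an amino-acid string into full-alphabet codes 0..20 (20 = X)."""
    table = _full_char_lookup()
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return table[raw]


@functools.cache
def _full_char_lookup() -> np.ndarray:
    table = np.full(256, WILDCARD_CODE, dtype=np.uint8)
    for aa, i in AA_INDEX.items():
        table[ord(aa)] = i
        table[ord(aa.lower())] = i
    return table
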