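"""Seeded synthetic protein-family generator.

Supplies every test, calibration and benchmark input of the package:
families of homologous sequences with controlled identity to a founder
sequence, and labeled alignment pairs for calibrating the ungapped filter.

Roots are drawn i.i.d. from the Blosum62 background frequencies.  A
homolog at target identity t substitutes positions with overall
probability 1 - t, drawing each replacement from the Blosum62 conditional
p(y | x) restricted to y != x, so that simulated alignments have realistic
substitution-score distributions.  Substitution rates are not uniform
along the sequence: sites carry a block-structured rate profile
(geometric blocks of ~30 residues, gamma-distributed relative rates,
shape 0.5), emulating the conserved cores and variable loops of real
protein families; the profile is rescaled per sequence so the mean
substitution probability is exactly 1 - t.  Within a family all members
mutate under the same profile, as conservation is a property of the
family.  Indel events occur uniformly at rate indel_rate * (1 - t) per
position with geometric(0.7) lengths.  By default every indel is a
deletion: members derive from a full-length founder by substitution and
loss (as in protein-fragment-rich metagenomic sets), so the founder is
its family's longest sequence; insertions relative to the founder can be
enabled via ``insertion_fraction``.  The generating alignment is tracked
exactly, so every homolog carries its realized identity (identical pairs
over alignment columns, internal gaps included).

All randomness flows from one seed; equal seeds give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from linclust.alphabet import AMINO_ACIDS, encode_full, load_blosum62

#: Geometric length parameter of indel events.
INDEL_LENGTH_P = 0.7
#: Gamma shape of per-block substitution rates (smaller = more contrast
#: between conserved and variable regions).
RATE_SHAPE = 0.3
#: Upper bound on relative rates, so even the most variable blocks stay
#: locally alignable homologous sequence rather than de facto inserts.
RATE_CAP = 2.0
#: Mean length (residues) of constant-rate blocks.
RATE_BLOCK = 30

_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _AA_ARRAY[codes].tobytes().decode("ascii")


def _background() -> np.ndarray:
    d, _ = load_blosum62()
    return d.p_x / d.p_x.sum()


def _conditional_no_self() -> np.ndarray:
    """cond[x, y] = p(y | x, y != x), cumulative over y for sampling."""
    d, _ = load_blosum62()
    cond = d.p_xy / d.p_x[:, None]
    np.fill_diagonal(cond, 0.0)
    cond /= cond.sum(axis=1, keepdims=True)
    return np.cumsum(cond, axis=1)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family dataset.

    Ranged fields accept a scalar or an inclusive (lo, hi) tuple sampled
    uniformly.  ``target_identity`` is the identity of each member to the
    family founder; the founder itself is emitted as the first member.
    ``fragment_fraction`` of the non-founder members are truncated to a
    contiguous 30-80% piece.
    """

    n_families: int = 100
    members_per_family: int | tuple[int, int] = 10
    root_length: int | tuple[int, int] = (200, 400)
    target_identity: float | tuple[float, float] = (0.6, 0.95)
    indel_rate: float = 0.1
    insertion_fraction: float = 0.0
    fragment_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo = (
            self.target_identity[0]
            if isinstance(self.target_identity, tuple)
            else self.target_identity
        )
        if not 0 < lo <= 1:
            raise ValueError("target_identity must lie in (0, 1]")
        if self.n_families < 1 or _low(self.members_per_family) < 1:
            raise ValueError("counts must be >= 1")


def _low(value) -> float:
    return value[0] if isinstance(value, tuple) else value


def _draw(value, rng: np.random.Generator, integer: bool = False):
    if isinstance(value, tuple):
        lo, hi = value
        if integer:
            return int(rng.integers(lo, hi + 1))
        return float(rng.uniform(lo, hi))
    return value


def sample_root(length: int, rng: np.random.Generator) -> str:
    """A random sequence with i.i.d. Blosum62 background residues."""
    if length < 1:
        raise ValueError("length must be >= 1")
    codes = rng.choice(20, size=length, p=_background())
    return _codes_to_str(codes.astype(np.uint8))


@dataclass(frozen=True)
class MutationTrace:
    """Bookkeeping of one generating alignment (root vs. homolog)."""

    codes: np.ndarray  # homolog residue codes
    identity: float  # identical pairs / alignment columns
    n_pairs: int  # gapless alignment columns
    n_columns: int
    x_kept: np.ndarray  # bool per root position: aligned to a residue?
    y_index: np.ndarray  # homolog index of each kept root position (-1 if not)
    x_matched: np.ndarray  # bool per root position: aligned AND identical


def rate_profile(
    length: int,
    rng: np.random.Generator,
    shape: float = RATE_SHAPE,
    cap: float = RATE_CAP,
    mean_block: float = RATE_BLOCK,
) -> np.ndarray:
    """Block-structured relative substitution rates (mean ~1).

    Consecutive blocks of geometric length carry a common gamma(shape)
    rate, capped at ``cap``; low-rate blocks model conserved cores,
    the cap keeps variable blocks recognizably homologous.
    """
    rates = np.empty(length)
    pos = 0
    while pos < length:
        g = 1 + int(rng.geometric(1.0 / mean_block))
        rates[pos : pos + g] = min(rng.gamma(shape, 1.0 / shape), cap)
        pos += g
    return rates


def _site_probabilities(rates: np.ndarray, p_sub: float) -> np.ndarray:
    """Rescale rates so mean per-site substitution probability is p_sub."""
    if p_sub <= 0:
        return np.zeros_like(rates)
    lo, hi = 0.0, 1e6
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.minimum(1.0, mid * rates).mean() < p_sub:
            lo = mid
        else:
            hi = mid
    return np.minimum(1.0, hi * rates)


def _mutate_codes(
    root: np.ndarray,
    target_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
    rates: np.ndarray | None = None,
    insertion_fraction: float = 0.0,
) -> MutationTrace:
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must lie in (0, 1]")
    L = root.shape[0]
    if rates is None:
        rates = rate_profile(L, rng)

    # Indels first: substitution pressure is then chosen so the realized
    # identity (identical pairs over alignment columns, gap columns
    # included) targets target_identity exactly despite the gap columns.
    # Indel events follow the same conservation profile as substitutions
    # (indels concentrate in variable loops, sparing conserved cores).
    kept = np.ones(L, dtype=bool)
    ins_len = np.zeros(L + 1, dtype=np.int64)
    p_event = indel_rate * (1.0 - target_identity)
    if p_event > 0:
        p_site = np.minimum(1.0, p_event * rates)
        events = np.flatnonzero(rng.random(L) < p_site)
        for p in events:
            g = int(rng.geometric(INDEL_LENGTH_P))
            if rng.random() < insertion_fraction:
                ins_len[p] += g
            else:
                kept[p : p + g] = False
    if not kept.any():
        kept[: max(1, L // 2)] = True  # degenerate: keep something

    n_columns_planned = L + int(ins_len.sum())
    n_kept = int(kept.sum())
    p_sub = max(0.0, 1.0 - target_identity * n_columns_planned / n_kept)

    subbed = root.copy()
    sub_mask = np.zeros(L, dtype=bool)
    kept_idx = np.flatnonzero(kept)
    sub_mask[kept_idx] = rng.random(n_kept) < _site_probabilities(
        rates[kept_idx], p_sub
    )
    if sub_mask.any():
        cum = _conditional_no_self()
        idx = np.flatnonzero(sub_mask)
        u = rng.random(idx.size)
        for x in np.unique(root[idx]):
            sel = root[idx] == x
            subbed[idx[sel]] = np.searchsorted(cum[x], u[sel], side="right")

    base = subbed[kept]
    total_ins = int(ins_len.sum())
    if total_ins:
        ins_positions = np.flatnonzero(ins_len)
        kept_before = np.concatenate(([0], np.cumsum(kept)))
        idx_rep = np.repeat(kept_before[ins_positions], ins_len[ins_positions])
        values = rng.choice(20, size=total_ins, p=_background()).astype(root.dtype)
        y = np.insert(base, idx_rep, values)
    else:
        y = base

    # Homolog index of each kept root position: residues kept before it
    # plus insertions at positions q <= p.
    ins_before = np.cumsum(ins_len[:-1])
    kept_rank = np.cumsum(kept) - 1
    y_index = np.where(kept, kept_rank + ins_before, -1)

    matched = kept & ~sub_mask
    n_columns = L + total_ins
    return MutationTrace(
        codes=y,
        identity=float(matched.sum() / n_columns),
        n_pairs=int(kept.sum()),
        n_columns=n_columns,
        x_kept=kept,
        y_index=y_index.astype(np.int64),
        x_matched=matched,
    )


def mutate_homolog(
    root: str,
    target_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
    rates: np.ndarray | None = None,
    insertion_fraction: float = 0.0,
) -> tuple[str, float]:
    """Mutate ``root`` to a homolog; returns (sequence, realized identity).

    ``rates`` fixes the per-site substitution-rate profile (drawn fresh
    when omitted); members of one family should share it.  The realized
    identity is measured on the generating alignment: identical aligned
    pairs divided by all alignment columns (internal gap columns
    included).
    """
    trace = _mutate_codes(
        encode_full(root),
        target_identity,
        indel_rate,
        rng,
        rates=rates,
        insertion_fraction=insertion_fraction,
    )
    return _codes_to_str(trace.codes), trace.identity


@dataclass(frozen=True)
class TruthRow:
    accession: str
    family: int
    identity_to_root: float


def generate_family_dataset(
    spec: FamilySpec,
) -> tuple[list[tuple[str, str]], list[TruthRow]]:
    """Generate mutually unrelated families; returns (records, truth).

    ``records`` is a list of (accession, residues); the founder of family f
    is ``F{f}_M00`` with identity 1.  Fragments (if requested) keep a
    contiguous 30-80% piece of the mutated member.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    truth: list[TruthRow] = []
    for fam in range(spec.n_families):
        length = _draw(spec.root_length, rng, integer=True)
        root = sample_root(length, rng)
        rates = rate_profile(length, rng)
        n_members = _draw(spec.members_per_family, rng, integer=True)
        for i in range(n_members):
            acc = f"F{fam:04d}_M{i:02d}"
            if i == 0:
                seq, ident = root, 1.0
            else:
                ident_target = _draw(spec.target_identity, rng)
                seq, ident = mutate_homolog(
                    root,
                    ident_target,
                    spec.indel_rate,
                    rng,
                    rates=rates,
                    insertion_fraction=spec.insertion_fraction,
                )
                if rng.random() < spec.fragment_fraction:
                    keep = rng.uniform(0.3, 0.8)
                    w = max(1, int(round(keep * len(seq))))
                    start = int(rng.integers(0, len(seq) - w + 1))
                    seq = seq[start : start + w]
            records.append((acc, seq))
            truth.append(TruthRow(acc, fam, ident))
    return records, truth


def write_family_dataset(spec: FamilySpec, out_prefix: str) -> tuple[str, str]:
    """Write a family dataset as FASTA plus a truth TSV."""
    records, truth = generate_family_dataset(spec)
    fasta = f"{out_prefix}.fasta"
    tsv = f"{out_prefix}_truth.tsv"
    with open(fasta, "w") as fh:
        for acc, seq in records:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(tsv, "w") as fh:
        fh.write("accession\tfamily\tidentity_to_root\n")
        for row in truth:
            fh.write(f"{row.accession}\t{row.family}\t{row.identity_to_root:.6f}\n")
    return fasta, tsv


@dataclass
class AlignmentSample:
    """Labeled pairs for prefilter calibration.

    ``diagonal[i]`` is the k-mer-anchored diagonal of pair i: for
    homologous pairs a same-group run of the generating alignment, for
    unrelated pairs the planted chance k-mer collision.
    ``identity``/``coverage`` are the generator's labels (identity over
    generating-alignment columns; aligned pairs over the longer
    sequence); both are 0 for unrelated pairs, which have no generating
    alignment.  ``is_homolog`` distinguishes the two components.
    """

    x: list[str] = field(default_factory=list)
    y: list[str] = field(default_factory=list)
    diagonal: list[int] = field(default_factory=list)
    identity: list[float] = field(default_factory=list)
    coverage: list[float] = field(default_factory=list)
    is_homolog: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.x)


def _anchored_diagonal(
    x_window: np.ndarray,
    trace: MutationTrace,
    anchor_k: int,
    rng: np.random.Generator,
) -> int | None:
    """A diagonal of the generating alignment as a k-mer match would seed it.

    The pipeline stores the diagonal of an exact k-mer match in the reduced
    alphabet, so candidate anchors are maximal runs of aligned columns in
    which both residues fall in the same reduced-alphabet group and no
    indel intervenes.  Runs of length >= anchor_k are sampled with
    probability proportional to the number of k-windows they contain
    (run_len - anchor_k + 1); if no run is that long, the longest run wins.
    Returns None when the alignment has no same-group column at all.
    """
    from linclust.alphabet import default_alphabet

    alpha = default_alphabet()
    red = alpha.full_to_code
    kept = np.flatnonzero(trace.x_kept)
    if kept.size == 0:
        return None
    same = red[x_window[kept]] == red[trace.codes[trace.y_index[kept]]]
    diag = kept - trace.y_index[kept]
    # A run breaks on a group mismatch or an indel (diagonal change or
    # non-consecutive root position).
    brk = np.ones(kept.size, dtype=bool)
    brk[1:] = (
        (diag[1:] != diag[:-1]) | (kept[1:] != kept[:-1] + 1) | ~same[1:]
    )
    brk |= ~same
    run_id = np.cumsum(brk) - 1
    valid = np.flatnonzero(same)
    if valid.size == 0:
        return None
    run_of = run_id[valid]
    run_starts = np.flatnonzero(np.concatenate(([True], run_of[1:] != run_of[:-1])))
    run_lens = np.diff(np.concatenate((run_starts, [valid.size])))
    run_diags = diag[valid[run_starts]]
    weights = run_lens - anchor_k + 1
    if (weights > 0).any():
        w = np.where(weights > 0, weights, 0).astype(float)
        choice = rng.choice(run_diags.size, p=w / w.sum())
    else:
        choice = int(np.argmax(run_lens))
    return int(run_diags[choice])


def _group_partners() -> list[np.ndarray]:
    """For each full-alphabet code, the codes sharing its reduced group."""
    from linclust.alphabet import AMINO_ACIDS, default_alphabet

    alpha = default_alphabet()
    partners = []
    for i, aa in enumerate(AMINO_ACIDS):
        group = alpha.groups[alpha.encode_map[aa]]
        partners.append(
            np.array([AMINO_ACIDS.index(b) for b in group], dtype=np.uint8)
        )
    return partners


def _chance_collision_pair(
    L: int, w: int, anchor_k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Two unrelated sequences sharing one planted reduced-alphabet k-mer.

    Emulates the chance k-mer collisions that feed non-homologous pairs
    into the prefilter: y gets a window whose residues fall in the same
    reduced groups as a random window of x.
    """
    x = rng.choice(20, size=L, p=_background()).astype(np.uint8)
    y = rng.choice(20, size=w, p=_background()).astype(np.uint8)
    partners = _group_partners()
    i = int(rng.integers(0, L - anchor_k + 1))
    j = int(rng.integers(0, w - anchor_k + 1))
    for p in range(anchor_k):
        options = partners[x[i + p]]
        y[j + p] = options[rng.integers(0, options.size)]
    return x, y, i - j


def sample_alignment_pairs(
    n: int,
    identity_range: tuple[float, float] = (0.3, 1.0),
    coverage_range: tuple[float, float] = (0.1, 1.0),
    rng: np.random.Generator | None = None,
    length_range: tuple[int, int] = (150, 400),
    indel_rate: float = 0.1,
    anchor_k: int = 10,
    unrelated_fraction: float = 0.5,
) -> AlignmentSample:
    """Generate ``n`` labeled pairs for filter calibration.

    The sample mimics what an all-against-all comparison feeds into the
    prefilter: a homologous component at uniform identities
    (``identity_range``) and coverages, and an ``unrelated_fraction`` of
    chance pairs whose only relationship is a planted reduced-alphabet
    k-mer collision.  Each homologous pair is a root x and a homolog y of
    a contiguous piece of x whose length fraction sets the coverage; its
    stored diagonal is drawn as a k-mer match would seed it (see
    :func:`_anchored_diagonal`), and pairs whose generating alignment
    retains no anchorable column are redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    sample = AlignmentSample()
    while len(sample) < n:
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        cov = float(rng.uniform(*coverage_range))
        w = max(5, int(round(cov * L)))
        if rng.random() < unrelated_fraction:
            w = max(w, anchor_k)
            x, y, diagonal = _chance_collision_pair(L, w, anchor_k, rng)
            sample.x.append(_codes_to_str(x))
            sample.y.append(_codes_to_str(y))
            sample.diagonal.append(diagonal)
            sample.identity.append(0.0)
            sample.coverage.append(0.0)
            sample.is_homolog.append(False)
            continue
        root_codes = rng.choice(20, size=L, p=_background()).astype(np.uint8)
        ident = float(rng.uniform(*identity_range))
        start = int(rng.integers(0, L - w + 1))
        trace = _mutate_codes(
            root_codes[start : start + w], ident, indel_rate, rng
        )
        if trace.codes.size == 0:
            continue
        diagonal = _anchored_diagonal(
            root_codes[start : start + w], trace, anchor_k, rng
        )
        if diagonal is None:
            continue
        sample.x.append(_codes_to_str(root_codes))
        sample.y.append(_codes_to_str(trace.codes))
        sample.diagonal.append(diagonal + start)
        sample.identity.append(trace.identity)
        sample.coverage.append(trace.n_pairs / max(L, trace.codes.size))
        sample.is_homolog.append(True)
    return sample
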