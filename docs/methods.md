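# Methods

`linclust` clusters a set of N protein sequences so that every cluster
member satisfies user-set identity, coverage and E-value criteria with
respect to a representative sequence, while computing at most m·N pairwise
verifications (m = 20 by default).  This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Pipeline

1. **Reduced-alphabet k-mer table.**  Sequences are transcoded into a
   reduced amino-acid alphabet (default size 13 = 12 residue groups plus
   the wildcard X) and from each sequence the m k-mers with the lowest
   16-bit hash values are selected.  Each selected k-mer contributes one
   table record (k-mer code, sequence id, length, position), so the table
   has at most m·N lines.
2. **Groups and centers.**  Sorting by k-mer code groups sequences that
   selected the same k-mer.  The longest sequence of each group (ties:
   smallest id) becomes its *center*; every other group member forms a
   candidate pair with the center, annotated with the match diagonal
   i − j.  Duplicate (center, member) pairs keep one diagonal — by
   default that of the lowest-hash shared k-mer, whose distribution over
   the pair's shared k-mers does not depend on m, so that sensitivity
   grows monotonically with m (smallest-|i−j| and smallest-signed-value
   rules are available as `diagonal_rule`).  Because each of a
   sequence's ≤ m k-mers joins exactly one
   group, candidate pairs number at most m·N — the linearity bound that
   every later stage inherits.
3. **Hamming pre-clustering.**  Candidates whose full-alphabet identity
   and coverage over the entire diagonal overlap already satisfy the
   thresholds are accepted without alignment.
4. **Ungapped filter.**  For the rest, the maximum-scoring contiguous
   segment on the diagonal (Blosum62, one-pass DP with score floor 0) is
   divided by the overlap length and compared with a calibrated
   threshold (below).
5. **Gapped verification.**  Survivors are aligned with affine-gap
   Smith–Waterman and kept as edges iff all enabled criteria hold.
6. **Greedy incremental clustering.**  Edges are made undirected;
   repeatedly the longest unassigned sequence becomes a representative
   and absorbs its unassigned neighbors.  Representatives are therefore
   the longest members of their clusters.

## Reduced alphabet

Letter groups are found by greedily merging the pair of letters whose
union preserves maximum mutual information of the Blosum62 joint
distribution p(x, y) (embedded as the published 4-decimal target
frequencies, renormalized).  Alphabet sizes count the wildcard: the
default size 13 means 12 groups, which are exactly
(L,M), (I,V), (K,R), (E,Q), (A,S,T), (N,D), (F,Y) plus six singletons.
Its effective size A_eff = 1/Σ p_a² is 8.87 with the Blosum62 letter
frequencies used here (the figure depends on the background composition:
corpus-specific frequencies shift it by a few percent, e.g. Swiss-Prot
composition gives ≈ 8.5).  The reduced alphabet is used only for k-mer
extraction; all residue-level scoring is in the full 20-letter alphabet.
Non-standard residues (B, Z, J, U, O, X, anything unrecognized) are
wildcards: never inside an extracted k-mer, scored −1 against everything,
never identical to anything.

## k-mer length and selection

k = max(k_spec, k_seqid) with k_spec = ⌊log(N·L̄)/log(A_eff)⌋ (bounds the
expected number of chance members per k-mer group by one) and k_seqid =
14 for identity thresholds ≥ 0.9, else 10.  Selection uses a reference
hash defined as 64-bit FNV-1a over the reduced-code bytes, XOR-folded to
16 bits; any faster rolling formulation must be bit-identical.  The hash
is a pure function of k-mer content, so homologous sequences tend to
select the same k-mers.

## Acceptance criteria

A pair (center q, member t) is linked iff

* E-value K·q_len·D·exp(−λ·score) ≤ e (default 1e−3), with the published
  gapped Karlin–Altschul parameters for Blosum62/11/1 (λ = 0.267,
  K = 0.041) and D the total residue count of the input;
* coverage = aligned residue pairs / denominator ≥ c (default 0.8), the
  denominator being the longer sequence (cov_mode 0, default), the member
  (1) or the center (2);
* identity ≥ min_seq_id, by default through the score-per-column
  surrogate: alignment score divided by the longer aligned segment,
  thresholded via a linear identity→score-per-column map fitted by least
  squares on simulated alignments (`--alignment-mode 3` switches to
  identical residues over aligned columns including internal gaps).

Gap costs follow the NCBI convention (gap of length g costs
open + g·extend; defaults 11/1).  Alignment ties are broken
deterministically (first best cell in scan order; diagonal preferred in
traceback).

## Prefilter calibration

For every cell of the {50..100}% identity × {0..100}% coverage grid, the
threshold on the overlap-normalized ungapped score is the largest value
that loses at most 1% of the pairs satisfying both final criteria — the
1% quantile of the qualifying pairs' score distribution, measured with
the gapped aligner on a seeded synthetic sample of 200,000 alignment
pairs.  Anchoring the false-negative rate on the qualifying pairs keeps
the sensitivity loss bounded at 1% regardless of how much unrelated
material the calibration sample or the input set contains (a bound
defined relative to the below-threshold population would degenerate as
the unrelated fraction grows).  The sample mimics what an
all-against-all comparison feeds into the prefilter: half homologous
pairs spanning identities 30–100% and coverages 10–100%, half unrelated
pairs whose only relationship is a planted chance k-mer collision in the
reduced alphabet (without the unrelated mass, the 1% threshold would sit
in the extreme tail of the score distribution and the false-negative
rate would not be measurable).  Cells with no qualifying pairs use the
maximum
observed score; cells with fewer than 100 qualifying pairs disable the
filter (threshold 0) with a warning.  The shipped table and identity map
(`data/calibration.json`, seed 42) are regenerable with
`linclust calibrate`.

## Synthetic data

The generator supplies every test and calibration input.  Families are
built from an i.i.d. Blosum62-background founder; members substitute
residues via the Blosum62 conditional p(y | x, y ≠ x) with an overall
substitution probability of 1 − t for target identity t.  Three
deliberate departures from the simplest i.i.d. model, all motivated by
features of real protein families that this method is designed to
exploit:

* **Conservation profile.**  Substitution rates are piecewise-constant
  over blocks (geometric length, mean 30 residues) with
  gamma(0.3)-distributed relative rates capped at 2× the mean, rescaled
  per sequence so the mean substitution probability is exact.  All
  members of a family share one profile, since conservation is a
  property of the family.  Without spatially correlated conservation, a
  conserved k-mer at 60% identity is vanishingly rare (window survival
  factorizes to ≈ (1 − p)^k for any i.i.d. rate model) and min-hash
  seeding cannot work at the identity ranges it is used for in practice.
  The cap keeps even the most variable blocks recognizably homologous
  rather than de facto inserts.
* **Deletion-biased indels in variable regions.**  Indel events occur at
  rate indel_rate·(1 − t) per position (default 0.1 indels per
  substitution), placed proportionally to the same conservation profile
  as substitutions — indels concentrate in variable loops and spare
  conserved cores, as in real alignments — with geometric(0.7) lengths,
  and are deletions by default
  (`insertion_fraction` enables insertions): members derive from a
  full-length founder, as in fragment-rich metagenomic protein sets,
  making the founder its family's longest sequence.  Substitution
  pressure is applied after indels and chosen so the realized identity
  (identical pairs over alignment columns, gap columns included) hits
  the target exactly in expectation.
* **Anchored diagonals.**  Calibration pairs carry the diagonal a k-mer
  match would store: a maximal run of same-reduced-group aligned columns
  sampled proportionally to the number of k-windows it contains.  A
  uniformly random match column would produce diagonals no k-mer match
  could seed and starve the calibration cells.

What the generator does **not** emulate: domain shuffling and repeats,
compositional bias (low-complexity regions), length-correlated
similarity, realistic family-size distributions, and alignments against
non-homologous sequence.  Pipeline results on these data therefore
establish algorithmic correctness (work bounds, chunk equivalence,
determinism, criteria consistency) and relative sensitivity behavior,
not absolute sensitivity on natural sequence sets.

## Out-of-memory chunking

With `--split-chunks C`, k-mer extraction keeps only codes with
code mod C = c in pass c; since selection precedes filtering, the C
chunk tables partition the single-pass table, every k-mer group lies
wholly inside one chunk, and the merged, per-pair-deduplicated match
streams are identical to the single-pass stream.  Chunk streams are
written as sorted TSV files and k-way merged; C = 1 uses the same merge
path in memory.  Output is byte-identical for any C.

## Problem sizes and determinism

The acceptance suite exercises 10k/20k/40k-sequence sets for the
linearity bound, a 5k set for chunk equivalence, a 10k set for
member–representative self-consistency, and 100×10 families for
recovery; these sizes keep the full suite within a normal CI budget
while leaving every measured bound far from its asymptotic regime's
noise floor.  All randomness flows from explicit seeds; the pipeline
itself is deterministic (integer sort keys, fixed tie-breaks, stages
merged in sequence-id order) and independent of the `--threads` setting.

## Known limitations

* Identity at the clustering threshold is judged by the
  score-per-column surrogate by default; pairs near the threshold can be
  classified differently than under the column-identity definition.
* The m = 20 default trades sensitivity for speed: on families whose
  members sit near the low end of the clustering identity range, a few
  percent of member–representative links are missed relative to m = 80,
  which on our synthetic families reaches the ceiling set by the
  acceptance criteria themselves.
* E-values use fixed published Karlin–Altschul parameters for
  Blosum62/11/1 rather than input-specific fits; with the permissive
  default threshold (1e−3) this is never the binding criterion in
  practice.
* Compositional bias correction and cascaded profile-search refinement
  are out of scope.
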