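"""Gapped local alignment and the pairwise acceptance criteria.

Candidate pairs that survive the prefilter cascade are aligned with an
affine-gap Smith-Waterman algorithm (Blosum62, gap open 11 / extend 1,
where a gap of length g costs open + g * extend).  A pair is linked by an
edge when all enabled criteria hold:

* E-value  E = K * q_len * db_residues * exp(-lambda * score)  <= max_evalue
  (gapped Karlin-Altschul statistics with the published Blosum62/11/1
  parameters lambda = 0.267, K = 0.041);
* coverage >= c, with the number of aligned residue pairs divided by the
  longer sequence (cov_mode 0, default), the target/member (1) or the
  query/center (2);
* sequence identity >= min_seq_id, either as identical residues divided by
  aligned columns including internal gaps (COLUMNS mode), or -- the default
  -- via the highly correlated score-per-column surrogate: alignment score
  divided by the longer aligned segment, thresholded through a linear
  identity -> score-per-column map fitted on simulated alignments.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from linclust import _kernels

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
#: Published gapped Karlin-Altschul parameters for Blosum62 with gap 11/1.
DEFAULT_KA_LAMBDA = 0.267
DEFAULT_KA_K = 0.041


class IdMode(enum.Enum):
    """How the minimum-identity criterion is evaluated."""

    COLUMNS = "columns"
    SCORE_PER_COLUMN = "score_per_column"


@dataclass(frozen=True)
class Alignment:
    """A gapped local alignment of query (center) and target (member).

    Segment bounds are 0-based inclusive; ``n_columns`` counts aligned
    columns including internal gap columns, ``n_pairs`` the gapless
    columns, ``n_identical`` the identical residue pairs.
    """

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_columns: int
    n_identical: int
    n_pairs: int

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@dataclass(frozen=True)
class IdentityScoreMap:
    """Linear map from sequence identity to a score-per-column threshold."""

    slope: float
    intercept: float

    def threshold(self, min_seq_id: float) -> float:
        return self.slope * min_seq_id + self.intercept


@dataclass(frozen=True)
class AcceptParams:
    """The criteria that link two sequences by an edge."""

    min_seq_id: float = 0.5
    c: float = 0.8
    cov_mode: int = 0
    max_evalue: float = 1e-3
    id_mode: IdMode = IdMode.SCORE_PER_COLUMN
    ka_lambda: float = DEFAULT_KA_LAMBDA
    ka_K: float = DEFAULT_KA_K
    db_residues: int = 1
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND
    id_score_map: IdentityScoreMap | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.min_seq_id <= 1 and 0 <= self.c <= 1):
            raise ValueError("min_seq_id and c must lie in [0, 1]")
        if self.cov_mode not in (0, 1, 2):
            raise ValueError(f"cov_mode must be 0, 1 or 2, got {self.cov_mode}")


@dataclass(frozen=True)
class Edge:
    """Verdict for one candidate pair."""

    center_id: int
    member_id: int
    passed: bool
    origin: str  # "HAMMING" or "GAPPED"
    alignment: Alignment | None = None
    failed_criteria: tuple[str, ...] = field(default=())


def local_align(
    q_codes: np.ndarray,
    t_codes: np.ndarray,
    scores: np.ndarray,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal affine-gap Smith-Waterman alignment of two code arrays.

    Ties are broken deterministically: highest score, then smallest q_end,
    then smallest t_end; the traceback prefers diagonal moves over gaps.
    """
    if q_codes.shape[0] == 0 or t_codes.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    res = _kernels.smith_waterman(
        np.ascontiguousarray(q_codes, dtype=np.uint8),
        np.ascontiguousarray(t_codes, dtype=np.uint8),
        scores,
        gap_open,
        gap_extend,
    )
    return Alignment(*(int(x) for x in res))


def coverage(aln: Alignment, q_len: int, t_len: int, cov_mode: int) -> float:
    """Alignment coverage: aligned residue pairs over the mode's denominator."""
    if cov_mode == 0:
        return aln.n_pairs / max(q_len, t_len)
    if cov_mode == 1:
        return aln.n_pairs / t_len
    if cov_mode == 2:
        return aln.n_pairs / q_len
    raise ValueError(f"cov_mode must be 0, 1 or 2, got {cov_mode}")


def identity_measures(aln: Alignment) -> tuple[float, float]:
    """(identity over aligned columns, score per aligned-segment column).

    The second value divides the score by the longer of the two locally
    aligned segments.  Raises on an empty alignment.
    """
    if aln.is_empty:
        raise ValueError("empty alignment has no identity")
    identity_cols = aln.n_identical / aln.n_columns
    longest_segment = max(aln.q_end - aln.q_start + 1, aln.t_end - aln.t_start + 1)
    return identity_cols, aln.score / longest_segment


def evalue(score: int, q_len: int, params: AcceptParams) -> float:
    """Karlin-Altschul E-value of a local alignment score."""
    return params.ka_K * q_len * params.db_residues * math.exp(
        -params.ka_lambda * score
    )


def fit_identity_score_map(
    identities: np.ndarray, scores_per_column: np.ndarray
) -> IdentityScoreMap:
    """Least-squares line mapping identity to score per column.

    Fitted on simulated local alignments spanning the identity range of
    interest; the line converts a --min-seq-id threshold into an
    equivalent score-per-column threshold.
    """
    identities = np.asarray(identities, dtype=float)
    scores_per_column = np.asarray(scores_per_column, dtype=float)
    if identities.size < 2 or float(np.var(identities)) < 1e-12:
        raise ValueError("degenerate sample: need >= 2 distinct identities")
    slope, intercept = np.polyfit(identities, scores_per_column, 1)
    return IdentityScoreMap(slope=float(slope), intercept=float(intercept))


def accept_edge(
    aln: Alignment,
    q_len: int,
    t_len: int,
    params: AcceptParams,
    center_id: int = -1,
    member_id: int = -1,
) -> Edge:
    """Apply the acceptance criteria to an alignment and build the edge."""
    failed: list[str] = []
    if aln.is_empty:
        failed = ["identity", "coverage", "evalue"]
    else:
        if evalue(aln.score, q_len, params) > params.max_evalue:
            failed.append("evalue")
        if coverage(aln, q_len, t_len, params.cov_mode) < params.c:
            failed.append("coverage")
        identity_cols, spc = identity_measures(aln)
        if params.id_mode is IdMode.COLUMNS:
            if identity_cols < params.min_seq_id:
                failed.append("identity")
        else:
            if params.id_score_map is None:
                raise ValueError(
                    "SCORE_PER_COLUMN mode requires params.id_score_map"
                )
            if spc < params.id_score_map.threshold(params.min_seq_id):
                failed.append("identity")
    return Edge(
        center_id=center_id,
        member_id=member_id,
        passed=not failed,
        origin="GAPPED",
        alignment=aln,
        failed_criteria=tuple(failed),
    )
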