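"""Diagonal prefilter cascade: Hamming pre-clustering and ungapped filter.

Candidate pairs arrive with a single stored diagonal d = i - j from the
k-mer match.  Both prefilter stages look only at the gapless overlap of the
two sequences along that diagonal, in the full 20-letter alphabet:

* Step A (Hamming pre-clustering): the fraction of identical positions over
  the whole overlap.  Pairs that already satisfy the identity threshold and
  the coverage criterion on the entire overlap are accepted outright
  (PRE_ACCEPT) and skip alignment entirely.

* Step B (ungapped filter): the maximum-scoring contiguous segment on the
  diagonal (one-pass dynamic programming, Blosum62).  The score divided by
  the overlap length is compared against a calibrated threshold; pairs
  below it are dropped.  Thresholds are calibrated per cell of the identity
  x coverage grid {50,55,...,100}% x {0,10,...,100}% so that at most 1% of
  the pairs satisfying both final criteria are dropped (a 1% false-negative
  rate), following the empirical-calibration approach on simulated
  alignment samples.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from linclust import _kernels
from linclust.align import AcceptParams

#: Identity levels (%) of the calibration grid.
GRID_IDENTITIES = tuple(range(50, 101, 5))
#: Coverage levels (%) of the calibration grid.
GRID_COVERAGES = tuple(range(0, 101, 10))

#: Calibration design false-negative rate.
TARGET_FN_RATE = 0.01
#: Cells with fewer qualifying sample pairs than this are disabled.
MIN_QUALIFYING = 100


class Verdict(enum.Enum):
    PRE_ACCEPT = "pre_accept"
    PASS = "pass"
    REJECT = "reject"


@dataclass(frozen=True)
class DiagonalOverlap:
    """The gapless comparison frame of two sequences on one diagonal."""

    x_start: int  # start in the center
    y_start: int  # start in the member
    length: int


@dataclass(frozen=True)
class PrefilterVerdict:
    status: Verdict
    hamming_identity: float
    ungapped_score: int
    norm_score: float
    overlap: DiagonalOverlap


def diagonal_overlap(
    center_len: int, member_len: int, diagonal: int
) -> DiagonalOverlap:
    """Overlap geometry of center x and member y with x_pos - y_pos = d."""
    if not -member_len < diagonal < center_len:
        raise ValueError(
            f"diagonal {diagonal} outside (-{member_len}, {center_len})"
        )
    x_start = max(0, diagonal)
    length = min(center_len, member_len + diagonal) - x_start
    return DiagonalOverlap(
        x_start=x_start, y_start=x_start - diagonal, length=length
    )


def _overlap_coverage(
    overlap_len: int, center_len: int, member_len: int, cov_mode: int
) -> float:
    """Coverage with the overlap standing in for the aligned length."""
    if cov_mode == 0:
        return overlap_len / max(center_len, member_len)
    if cov_mode == 1:
        return overlap_len / member_len
    if cov_mode == 2:
        return overlap_len / center_len
    raise ValueError(f"cov_mode must be 0, 1 or 2, got {cov_mode}")


def hamming_verdict(
    center: np.ndarray,
    member: np.ndarray,
    diagonal: int,
    params: AcceptParams,
    scores: np.ndarray,
) -> PrefilterVerdict:
    """Evaluate one candidate pair along its stored diagonal.

    ``center``/``member`` are full-alphabet code arrays.  PRE_ACCEPT
    requires the Hamming identity and the coverage criterion to hold on the
    entire overlap; otherwise the pair PASSes to the ungapped filter with
    its best-segment score and overlap-normalized score filled in.
    """
    ov = diagonal_overlap(center.shape[0], member.shape[0], diagonal)
    if ov.length < 1:
        raise ValueError("empty diagonal overlap")
    a = center[ov.x_start : ov.x_start + ov.length]
    b = member[ov.y_start : ov.y_start + ov.length]
    n_ident = int(_kernels.hamming_identical(a, b))
    identity = n_ident / ov.length
    score, _, _ = _kernels.best_ungapped_segment(a, b, scores)
    score = int(score)
    cov = _overlap_coverage(
        ov.length, center.shape[0], member.shape[0], params.cov_mode
    )
    status = (
        Verdict.PRE_ACCEPT
        if identity >= params.min_seq_id and cov >= params.c
        else Verdict.PASS
    )
    return PrefilterVerdict(
        status=status,
        hamming_identity=identity,
        ungapped_score=score,
        norm_score=score / ov.length,
        overlap=ov,
    )


def ungapped_best_segment(
    center: np.ndarray, member: np.ndarray, diagonal: int, scores: np.ndarray
) -> tuple[int, DiagonalOverlap]:
    """Best gapless segment score along the diagonal, plus its frame.

    The returned overlap describes the best-scoring segment itself
    (possibly empty); the score floor is 0.
    """
    ov = diagonal_overlap(center.shape[0], member.shape[0], diagonal)
    if ov.length < 1:
        raise ValueError("empty diagonal overlap")
    a = center[ov.x_start : ov.x_start + ov.length]
    b = member[ov.y_start : ov.y_start + ov.length]
    score, start, length = _kernels.best_ungapped_segment(a, b, scores)
    return int(score), DiagonalOverlap(
        x_start=ov.x_start + int(start),
        y_start=ov.y_start + int(start),
        length=int(length),
    )


class ThresholdTable:
    """Calibrated minimum norm_score per (identity, coverage) grid cell."""

    def __init__(
        self,
        thresholds: np.ndarray,
        identities: tuple[int, ...] = GRID_IDENTITIES,
        coverages: tuple[int, ...] = GRID_COVERAGES,
    ) -> None:
        thresholds = np.asarray(thresholds, dtype=float)
        if thresholds.shape != (len(identities), len(coverages)):
            raise ValueError("threshold grid shape mismatch")
        self.identities = identities
        self.coverages = coverages
        self.thresholds = thresholds

    def lookup(self, min_seq_id: float, c: float) -> float:
        """Threshold of the cell obtained by rounding both settings down.

        Identity settings below the grid disable the filter (threshold 0):
        a stricter cell would drop pairs that could still qualify.
        """
        id_pct = min_seq_id * 100.0
        cov_pct = c * 100.0
        if id_pct < self.identities[0]:
            return 0.0
        i = min(
            int((id_pct - self.identities[0]) // 5), len(self.identities) - 1
        )
        j = min(int(cov_pct // 10), len(self.coverages) - 1)
        return float(self.thresholds[i, j])

    def to_json(self) -> str:
        return json.dumps(
            {
                "identities": list(self.identities),
                "coverages": list(self.coverages),
                "thresholds": self.thresholds.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdTable":
        obj = json.loads(text)
        return cls(
            np.array(obj["thresholds"], dtype=float),
            tuple(obj["identities"]),
            tuple(obj["coverages"]),
        )


def calibrate_ungapped_thresholds(
    norm_scores: np.ndarray,
    identities: np.ndarray,
    coverages: np.ndarray,
    fn_rate: float = TARGET_FN_RATE,
    min_qualifying: int = MIN_QUALIFYING,
) -> ThresholdTable:
    """Calibrate per-cell thresholds from a labeled alignment sample.

    ``norm_scores`` holds the overlap-normalized ungapped score of each
    sampled pair; ``identities``/``coverages`` its identity and coverage
    as fractions, measured by the gapped aligner.  For each grid cell
    (I, C) the threshold is the largest observed norm_score t such that
    at most a fraction ``fn_rate`` of the pairs satisfying identity >= I
    and coverage >= C score strictly below t — i.e. the ``fn_rate``
    quantile of the qualifying pairs' score distribution, so the filter
    loses at most 1% of true pairs regardless of how much unrelated
    material the sample (or the input set) contains.  Degenerate cells:
    with no qualifying pair the threshold is the maximum observed
    norm_score (everything is filterable); with fewer than
    ``min_qualifying`` qualifying pairs the filter is disabled
    (threshold 0) with a warning.
    """
    norm_scores = np.asarray(norm_scores, dtype=float)
    ids = np.asarray(identities, dtype=float)
    covs = np.asarray(coverages, dtype=float)
    n = norm_scores.size
    if n == 0:
        raise ValueError("empty calibration sample")

    grid = np.zeros((len(GRID_IDENTITIES), len(GRID_COVERAGES)))
    for gi, ident in enumerate(GRID_IDENTITIES):
        for gj, cov in enumerate(GRID_COVERAGES):
            qual = (ids >= ident / 100.0) & (covs >= cov / 100.0)
            n_qual = int(qual.sum())
            if n_qual == 0:
                grid[gi, gj] = float(norm_scores.max())
                continue
            if n_qual < min_qualifying:
                warnings.warn(
                    f"grid cell ({ident}%, {cov}%): only {n_qual} qualifying "
                    "sample pairs; ungapped filter disabled for this cell",
                    stacklevel=2,
                )
                grid[gi, gj] = 0.0
                continue
            qs = np.sort(norm_scores[qual])
            # qs[k] keeps the pairs strictly below it to at most k of
            # n_qual, i.e. a false-negative fraction <= fn_rate.
            k = int(np.floor(fn_rate * n_qual))
            grid[gi, gj] = float(qs[k])
    return ThresholdTable(grid)


def ungapped_filter(
    verdict: PrefilterVerdict, params: AcceptParams, table: ThresholdTable
) -> bool:
    """Whether a PASS pair proceeds to gapped alignment (>= threshold)."""
    return verdict.norm_score >= table.lookup(params.min_seq_id, params.c)


def load_default_calibration() -> tuple[ThresholdTable, "object"]:
    """The threshold table and identity->score map shipped with the package.

    Regenerable with ``linclust calibrate``; see that command for the
    sampling conditions.
    """
    from linclust.align import IdentityScoreMap

    text = (
        resources.files("linclust.data").joinpath("calibration.json").read_text()
    )
    obj = json.loads(text)
    table = ThresholdTable(
        np.array(obj["threshold_table"]["thresholds"], dtype=float),
        tuple(obj["threshold_table"]["identities"]),
        tuple(obj["threshold_table"]["coverages"]),
    )
    m = obj["identity_score_map"]
    return table, IdentityScoreMap(slope=m["slope"], intercept=m["intercept"])
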