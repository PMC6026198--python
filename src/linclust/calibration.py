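"""Calibration of the ungapped-filter thresholds and the identity map.

Both calibration artifacts shipped with the package are produced here from
seeded synthetic alignment samples:

* the :class:`~linclust.prefilter.ThresholdTable` of minimum
  overlap-normalized ungapped scores per (identity, coverage) grid cell,
  set so that at most 1% of the filtered pairs would have satisfied both
  final criteria (measured by the gapped aligner);
* the linear identity -> score-per-column map used by the default
  sequence-similarity criterion.

Run ``linclust calibrate`` to regenerate them.
"""

from __future__ import annotations

import json

import numpy as np

from linclust import align, prefilter, simdata
from linclust.alphabet import encode_full, load_blosum62

DEFAULT_N_PAIRS = 200_000
DEFAULT_SEED = 42


def label_sample(
    sample: simdata.AlignmentSample,
    gap_open: int = align.DEFAULT_GAP_OPEN,
    gap_extend: int = align.DEFAULT_GAP_EXTEND,
) -> dict[str, np.ndarray]:
    """Norm scores and gapped-aligner labels for a generated pair sample.

    For each pair: the ungapped best-segment score along the stored
    diagonal divided by the overlap length, and the identity (over aligned
    columns) and coverage (aligned pairs over the longer sequence) of the
    optimal gapped local alignment.  Pairs whose gapped alignment is empty
    get identity and coverage 0.
    """
    _, scores = load_blosum62()
    n = len(sample)
    norm = np.zeros(n)
    identity = np.zeros(n)
    cov = np.zeros(n)
    spc = np.zeros(n)
    for i in range(n):
        x = encode_full(sample.x[i])
        y = encode_full(sample.y[i])
        score, _ = prefilter.ungapped_best_segment(
            x, y, sample.diagonal[i], scores
        )
        ov = prefilter.diagonal_overlap(
            x.shape[0], y.shape[0], sample.diagonal[i]
        )
        norm[i] = score / ov.length
        aln = align.local_align(x, y, scores, gap_open, gap_extend)
        if not aln.is_empty:
            ident_cols, score_per_col = align.identity_measures(aln)
            identity[i] = ident_cols
            spc[i] = score_per_col
            cov[i] = align.coverage(aln, x.shape[0], y.shape[0], cov_mode=0)
    return {
        "norm_score": norm,
        "identity": identity,
        "coverage": cov,
        "score_per_column": spc,
    }


def build_calibration(
    n_pairs: int = DEFAULT_N_PAIRS, seed: int = DEFAULT_SEED
) -> dict:
    """Generate a sample, calibrate the table and fit the identity map."""
    rng = np.random.default_rng(seed)
    sample = simdata.sample_alignment_pairs(n_pairs, rng=rng)
    labels = label_sample(sample)
    table = prefilter.calibrate_ungapped_thresholds(
        labels["norm_score"], labels["identity"], labels["coverage"]
    )
    # The identity map is a property of homologous alignments; chance
    # pairs (short spurious local hits) would distort the low end.
    homolog = np.array(sample.is_homolog) & (labels["identity"] > 0)
    id_map = align.fit_identity_score_map(
        labels["identity"][homolog], labels["score_per_column"][homolog]
    )
    return {
        "threshold_table": json.loads(table.to_json()),
        "identity_score_map": {
            "slope": id_map.slope,
            "intercept": id_map.intercept,
        },
        "meta": {"n_pairs": n_pairs, "seed": seed},
    }


def write_calibration(path: str, n_pairs: int, seed: int) -> None:
    with open(path, "w") as fh:
        json.dump(build_calibration(n_pairs, seed), fh, indent=1)
        fh.write("\n")
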