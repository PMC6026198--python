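"""Gapped local alignment and the pairwise acceptance criteria."""

import math

import numpy as np
import pytest

from _oracles import local_align_score_oracle
from linclust.align import (
    AcceptParams,
    Alignment,
    IdMode,
    IdentityScoreMap,
    accept_edge,
    coverage,
    evalue,
    fit_identity_score_map,
    identity_measures,
    local_align,
)
from linclust.alphabet import encode_full
from conftest import random_protein


class TestLocalAlign:
    def test_self_alignment_is_full_length(self, scores, rng):
        seq = random_protein(rng, 60)
        q = encode_full(seq)
        aln = local_align(q, q, scores)
        assert aln.score == sum(int(scores[c, c]) for c in q)
        assert (aln.q_start, aln.q_end) == (0, 59)
        assert aln.n_identical == aln.n_pairs == aln.n_columns == 60

    def test_score_matches_textbook_dp(self, scores, rng):
        for _ in range(60):
            q = encode_full(random_protein(rng, int(rng.integers(5, 60))))
            t = encode_full(random_protein(rng, int(rng.integers(5, 60))))
            assert local_align(q, t, scores).score == local_align_score_oracle(
                q, t, scores
            )

    def test_gap_versus_mismatch_decision(self, scores):
        q = encode_full("AAAA")
        t = encode_full("AATAA")
        aln = local_align(q, t, scores)
        assert aln.score == local_align_score_oracle(q, t, scores)

    def test_score_symmetric_under_swap(self, scores, rng):
        for _ in range(30):
            q = encode_full(random_protein(rng, 40))
            t = encode_full(random_protein(rng, 50))
            assert local_align(q, t, scores).score == local_align(
                t, q, scores
            ).score

    def test_matches_biopython_aligner(self, scores, rng):
        # independent cross-check against an established implementation
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12  # first gap residue: open 11 + extend 1
        aligner.extend_gap_score = -1
        for _ in range(30):
            a = random_protein(rng, int(rng.integers(10, 90)))
            b = random_protein(rng, int(rng.integers(10, 90)))
            aln = local_align(encode_full(a), encode_full(b), scores)
            assert aln.score == int(aligner.score(a, b))

    def test_empty_sequence_rejected(self, scores):
        with pytest.raises(ValueError):
            local_align(np.empty(0, dtype=np.uint8), encode_full("AA"), scores)


class TestCoverageAndIdentity:
    def _gapless(self, n_pairs, n_identical=None, score=100):
        n_identical = n_pairs if n_identical is None else n_identical
        return Alignment(
            score=score, q_start=0, q_end=n_pairs - 1,
            t_start=0, t_end=n_pairs - 1,
            n_columns=n_pairs, n_identical=n_identical, n_pairs=n_pairs,
        )

    def test_full_self_alignment_has_unit_coverage(self):
        aln = self._gapless(100)
        for mode in (0, 1, 2):
            assert coverage(aln, 100, 100, mode) == 1.0

    def test_mode_denominators(self):
        aln = self._gapless(100)
        assert coverage(aln, 200, 100, 0) == 0.5
        assert coverage(aln, 200, 100, 1) == 1.0
        assert coverage(aln, 200, 100, 2) == 0.5

    def test_gap_columns_do_not_count_as_pairs(self):
        aln = Alignment(score=100, q_start=0, q_end=99, t_start=0, t_end=89,
                        n_columns=100, n_identical=70, n_pairs=90)
        assert coverage(aln, 150, 100, 1) == pytest.approx(0.9)

    def test_identity_over_columns_includes_gaps(self):
        aln = Alignment(score=50, q_start=0, q_end=99, t_start=0, t_end=89,
                        n_columns=100, n_identical=70, n_pairs=90)
        ident, spc = identity_measures(aln)
        assert ident == pytest.approx(0.70)
        assert spc == pytest.approx(0.5)  # score / longer segment (100)

    def test_empty_alignment_has_no_identity(self):
        empty = Alignment(0, -1, -1, -1, -1, 0, 0, 0)
        with pytest.raises(ValueError):
            identity_measures(empty)

    def test_identity_and_score_per_column_correlate(self, scores):
        from linclust.calibration import label_sample
        from linclust.simdata import sample_alignment_pairs

        sample = sample_alignment_pairs(
            2000, rng=np.random.default_rng(9)
        )
        labels = label_sample(sample)
        # the correlation claim concerns homologous local alignments;
        # planted chance pairs have no meaningful identity
        ok = np.array(sample.is_homolog) & (labels["identity"] > 0)
        r = np.corrcoef(labels["identity"][ok], labels["score_per_column"][ok])
        assert r[0, 1] >= 0.9


class TestEvalue:
    def test_zero_score_closed_form(self):
        params = AcceptParams(db_residues=10**6)
        assert evalue(0, 300, params) == pytest.approx(
            0.041 * 300 * 10**6
        )

    def test_linear_in_database_size(self):
        small = AcceptParams(db_residues=10**6)
        large = AcceptParams(db_residues=2 * 10**6)
        assert evalue(50, 300, large) == pytest.approx(
            2 * evalue(50, 300, small)
        )

    def test_direct_evaluation(self):
        params = AcceptParams(db_residues=10**6)
        expected = 0.041 * 300 * 1e6 * math.exp(-0.267 * 100)
        assert evalue(100, 300, params) == pytest.approx(expected, rel=1e-12)


class TestIdentityScoreMap:
    def test_exact_recovery_on_linear_sample(self):
        ids = np.linspace(0.3, 1.0, 50)
        spc = 4.0 * ids - 1.0
        m = fit_identity_score_map(ids, spc)
        assert m.slope == pytest.approx(4.0)
        assert m.intercept == pytest.approx(-1.0)
        assert m.threshold(0.5) == pytest.approx(1.0)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_identity_score_map(np.full(10, 0.5), np.linspace(0, 1, 10))

    def test_refit_stability_and_agreement(self):
        from linclust.calibration import label_sample
        from linclust.prefilter import load_default_calibration
        from linclust.align import fit_identity_score_map
        from linclust.simdata import sample_alignment_pairs

        maps = []
        for seed in (21, 22):
            sample = sample_alignment_pairs(
                4000, rng=np.random.default_rng(seed)
            )
            labels = label_sample(sample)
            ok = np.array(sample.is_homolog) & (labels["identity"] > 0)
            maps.append(
                fit_identity_score_map(
                    labels["identity"][ok], labels["score_per_column"][ok]
                )
            )
        for ident in (0.5, 0.7, 0.9):
            a, b = (m.threshold(ident) for m in maps)
            assert abs(a - b) / abs(b) < 0.10

        # classification agreement vs the direct identity rule at 90%
        sample = sample_alignment_pairs(3000, rng=np.random.default_rng(23))
        labels = label_sample(sample)
        ok = np.array(sample.is_homolog) & (labels["identity"] > 0)
        direct = labels["identity"][ok] >= 0.9
        surrogate = labels["score_per_column"][ok] >= maps[0].threshold(0.9)
        agreement = np.mean(direct == surrogate)
        assert agreement >= 0.95


class TestAcceptEdge:
    def test_self_alignment_passes_defaults(self, scores, rng):
        _, id_map = _default_maps()
        seq = encode_full(random_protein(rng, 100))
        aln = local_align(seq, seq, scores)
        params = AcceptParams(db_residues=10**5, id_score_map=id_map)
        edge = accept_edge(aln, 100, 100, params)
        assert edge.passed and edge.failed_criteria == ()

    def test_failing_criterion_is_reported(self):
        _, id_map = _default_maps()
        aln = Alignment(score=500, q_start=0, q_end=49, t_start=0, t_end=49,
                        n_columns=50, n_identical=50, n_pairs=50)
        params = AcceptParams(c=0.9, db_residues=100, id_score_map=id_map)
        edge = accept_edge(aln, 200, 200, params)  # coverage 50/200
        assert not edge.passed
        assert edge.failed_criteria == ("coverage",)

    def test_monotone_in_thresholds(self, scores):
        _, id_map = _default_maps()
        rng = np.random.default_rng(4)
        from linclust.simdata import sample_alignment_pairs

        sample = sample_alignment_pairs(200, rng=rng)
        for i in range(50):
            q = encode_full(sample.x[i])
            t = encode_full(sample.y[i])
            aln = local_align(q, t, scores)
            if aln.is_empty:
                continue
            loose = AcceptParams(min_seq_id=0.3, c=0.5, db_residues=10**4,
                                 id_score_map=id_map)
            tight = AcceptParams(min_seq_id=0.6, c=0.8, db_residues=10**4,
                                 id_score_map=id_map)
            e_loose = accept_edge(aln, q.shape[0], t.shape[0], loose)
            e_tight = accept_edge(aln, q.shape[0], t.shape[0], tight)
            assert not (e_tight.passed and not e_loose.passed)

    def test_columns_mode_uses_identity_directly(self):
        aln = Alignment(score=10, q_start=0, q_end=9, t_start=0, t_end=9,
                        n_columns=10, n_identical=6, n_pairs=10)
        params = AcceptParams(min_seq_id=0.5, c=0.1, cov_mode=1,
                              max_evalue=1e6, id_mode=IdMode.COLUMNS,
                              db_residues=1)
        assert accept_edge(aln, 10, 10, params).passed
        params_strict = AcceptParams(min_seq_id=0.7, c=0.1, cov_mode=1,
                                     max_evalue=1e6, id_mode=IdMode.COLUMNS,
                                     db_residues=1)
        assert not accept_edge(aln, 10, 10, params_strict).passed


def _default_maps():
    from linclust.prefilter import load_default_calibration

    return load_default_calibration()
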