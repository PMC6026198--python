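"""Diagonal Hamming pre-clustering and the calibrated ungapped filter."""

import numpy as np
import pytest

from _oracles import best_segment_oracle
from linclust.align import AcceptParams
from linclust.alphabet import encode_full
from linclust.prefilter import (
    ThresholdTable,
    Verdict,
    calibrate_ungapped_thresholds,
    diagonal_overlap,
    hamming_verdict,
    load_default_calibration,
    ungapped_best_segment,
    ungapped_filter,
)
from conftest import random_protein


class TestDiagonalOverlap:
    def test_equal_lengths_zero_diagonal(self):
        ov = diagonal_overlap(50, 50, 0)
        assert (ov.x_start, ov.y_start, ov.length) == (0, 0, 50)

    def test_offset_geometry(self):
        ov = diagonal_overlap(50, 30, 5)
        assert (ov.x_start, ov.y_start, ov.length) == (5, 0, 30)

    def test_boundary_single_residue(self):
        assert diagonal_overlap(50, 50, 49).length == 1
        assert diagonal_overlap(50, 50, -49).length == 1

    def test_out_of_range_diagonal(self):
        with pytest.raises(ValueError):
            diagonal_overlap(50, 30, 50)
        with pytest.raises(ValueError):
            diagonal_overlap(50, 30, -30)

    def test_geometry_matches_index_scan(self, rng):
        for _ in range(50):
            cl = int(rng.integers(1, 40))
            ml = int(rng.integers(1, 40))
            d = int(rng.integers(-ml + 1, cl))
            ov = diagonal_overlap(cl, ml, d)
            pairs = [
                (x, x - d)
                for x in range(cl)
                if 0 <= x - d < ml
            ]
            assert ov.length == len(pairs)
            if pairs:
                assert (ov.x_start, ov.y_start) == pairs[0]


class TestHammingVerdict:
    def test_identical_sequences_pre_accepted(self, scores, rng):
        seq = encode_full(random_protein(rng, 80))
        params = AcceptParams(min_seq_id=1.0, c=1.0, cov_mode=0)
        v = hamming_verdict(seq, seq, 0, params, scores)
        assert v.status is Verdict.PRE_ACCEPT
        assert v.hamming_identity == 1.0

    def test_identity_is_mismatch_ratio(self, scores, rng):
        a = random_protein(rng, 100)
        b = list(a)
        for i in range(0, 100, 10):
            b[i] = "W" if a[i] != "W" else "Y"
        v = hamming_verdict(
            encode_full(a), encode_full("".join(b)), 0,
            AcceptParams(min_seq_id=0.99, c=0.0), scores,
        )
        assert v.hamming_identity == pytest.approx(0.90)
        assert v.status is Verdict.PASS

    def test_wildcard_never_identical(self, scores):
        a = encode_full("WXWX")
        v = hamming_verdict(a, a, 0, AcceptParams(min_seq_id=0.1, c=0.0),
                            scores)
        assert v.hamming_identity == pytest.approx(0.5)

    def test_matches_brute_force_scan(self, scores, rng):
        params = AcceptParams(min_seq_id=0.9, c=0.9, cov_mode=1)
        for _ in range(50):
            a = encode_full(random_protein(rng, int(rng.integers(20, 120))))
            b = encode_full(random_protein(rng, int(rng.integers(20, 120))))
            d = int(rng.integers(-b.shape[0] + 1, a.shape[0]))
            v = hamming_verdict(a, b, d, params, scores)
            ident = sum(
                1
                for x in range(a.shape[0])
                if 0 <= x - d < b.shape[0]
                and a[x] == b[x - d] and a[x] != 20
            )
            overlap = sum(
                1 for x in range(a.shape[0]) if 0 <= x - d < b.shape[0]
            )
            assert v.hamming_identity == pytest.approx(ident / overlap)
            expected = (
                Verdict.PRE_ACCEPT
                if ident / overlap >= 0.9 and overlap / b.shape[0] >= 0.9
                else Verdict.PASS
            )
            assert v.status is expected


class TestUngappedBestSegment:
    def test_all_mismatch_floor_zero(self, scores):
        a = encode_full("WWWW")
        b = encode_full("PPPP")
        score, seg = ungapped_best_segment(a, b, 0, scores)
        assert score == 0 and seg.length == 0

    def test_two_tryptophans(self, scores):
        a = encode_full("WW")
        score, seg = ungapped_best_segment(a, a, 0, scores)
        assert score == 2 * scores[17, 17]
        assert seg.length == 2

    def test_matches_exhaustive_enumeration(self, scores, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            a = encode_full(random_protein(rng, n))
            b = encode_full(random_protein(rng, n))
            score, _ = ungapped_best_segment(a, b, 0, scores)
            assert score == best_segment_oracle(a, b, scores)


class TestCalibration:
    def test_vacuous_cell_uses_max_observed(self):
        ns = np.array([0.1, 0.5, 2.0])
        table = calibrate_ungapped_thresholds(
            ns, np.zeros(3), np.zeros(3), min_qualifying=1
        )
        assert table.lookup(0.5, 0.9) == pytest.approx(2.0)

    def test_threshold_is_the_qualifying_quantile(self):
        ns = np.linspace(0.1, 3.0, 200)
        table = calibrate_ungapped_thresholds(
            ns, np.ones(200), np.ones(200), min_qualifying=1
        )
        # all pairs qualify: the threshold sits at the 1% quantile of
        # their scores, losing at most 2 of 200 pairs
        thr = table.lookup(0.5, 0.9)
        assert thr == pytest.approx(np.sort(ns)[2])
        assert (ns < thr).sum() <= 2

    def test_sparse_cell_warns_and_disables(self):
        ns = np.linspace(0, 1, 500)
        ident = np.zeros(500)
        ident[:5] = 1.0  # five qualifying pairs only
        cov = np.ones(500)
        with pytest.warns(UserWarning, match="qualifying"):
            table = calibrate_ungapped_thresholds(ns, ident, cov)
        assert table.lookup(0.5, 0.9) == 0.0

    def test_fn_rate_constraint_holds_in_sample(self):
        rng = np.random.default_rng(5)
        n = 20000
        qual = rng.random(n) < 0.3
        ns = np.where(qual, rng.normal(2.0, 0.5, n), rng.normal(0.5, 0.4, n))
        ns = np.clip(ns, 0, None)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = calibrate_ungapped_thresholds(
                    ns, np.where(qual, 1.0, 0.0), np.ones(n)
                )
        thr = table.lookup(0.9, 0.9)
        below = ns < thr
        assert below.sum() > 0
        # at most 1% of qualifying pairs are lost to the filter
        assert (qual & below).sum() / qual.sum() <= 0.01

    def test_grid_rises_with_identity_in_the_large(self):
        # Stricter identity shrinks the qualifying set, so thresholds
        # rise with identity over the grid as a whole (individual
        # adjacent rows may wiggle within the quantile's sampling noise;
        # cells disabled for lack of samples are 0 and excluded).
        table, _ = load_default_calibration()
        t = table.thresholds
        low, high = t[0, :], t[8, :]  # 50% vs 90% identity rows
        active = (low > 0) & (high > 0)
        assert (high[active] >= low[active]).all()


class TestUngappedFilter:
    def _verdict(self, norm):
        from linclust.prefilter import DiagonalOverlap, PrefilterVerdict

        return PrefilterVerdict(
            status=Verdict.PASS,
            hamming_identity=0.0,
            ungapped_score=int(norm * 100),
            norm_score=norm,
            overlap=DiagonalOverlap(0, 0, 100),
        )

    def test_boundary_score_passes(self):
        table = ThresholdTable(np.full((11, 11), 0.5))
        params = AcceptParams(min_seq_id=0.5, c=0.9)
        assert ungapped_filter(self._verdict(0.5), params, table)
        assert not ungapped_filter(self._verdict(0.499), params, table)

    def test_grid_rounding(self):
        grid = np.zeros((11, 11))
        grid[0, 9] = 0.7  # (50%, 90%)
        table = ThresholdTable(grid)
        params = AcceptParams(min_seq_id=0.5, c=0.9)
        assert not ungapped_filter(self._verdict(0.6), params, table)
        params2 = AcceptParams(min_seq_id=0.5, c=0.89)
        assert ungapped_filter(self._verdict(0.6), params2, table)

    def test_below_grid_identity_disables_filter(self):
        table = ThresholdTable(np.full((11, 11), 5.0))
        params = AcceptParams(min_seq_id=0.3, c=0.9)
        assert ungapped_filter(self._verdict(0.0), params, table)
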