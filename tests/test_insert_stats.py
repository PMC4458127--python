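"""Robust global insert-size estimation: MAD, filtering, contamination."""

import numpy as np
import pytest

from matemend.errors import NoUsablePairsError
from matemend.insert_stats import (
    GlobalInsertModel,
    PairFilterConfig,
    collect_proper_inserts,
    estimate_global_model,
    mad_to_sigma,
    median_absolute_deviation,
    orientation_is_correct,
)

from conftest import pair_lines, write_tiny_bam


class TestMedianAbsoluteDeviation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 5], 1.0),
            ([7, 7, 7, 7], 0.0),
            ([2000, 4000], 1000.0),
        ],
    )
    def test_small_cases(self, values, expected):
        assert median_absolute_deviation(values) == expected

    def test_standard_normal_mad(self):
        """MAD of a standard normal is ~0.6745 (Monte-Carlo estimate)."""
        draws = np.random.default_rng(42).standard_normal(10_001)
        assert median_absolute_deviation(draws) == pytest.approx(0.6745, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_absolute_deviation([])


class TestMadToSigma:
    @pytest.mark.parametrize(
        "mad, expected", [(1.0, 1.4826), (0.0, 0.0), (200.0, 296.52)]
    )
    def test_scaling(self, mad, expected):
        assert mad_to_sigma(mad) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mad_to_sigma(-1.0)


class TestEstimateGlobalModel:
    def test_constant_inserts(self):
        m = estimate_global_model([3000, 3000, 3000])
        assert (m.mu_hat, m.mad, m.sigma_hat, m.n_pairs_used) == (3000, 0, 0, 3)

    def test_two_point_case(self):
        m = estimate_global_model([2000, 4000])
        assert m.mu_hat == 3000
        assert m.mad == 1000
        assert m.sigma_hat == pytest.approx(1482.6)

    def test_sigma_is_scaled_mad_exactly(self):
        rng = np.random.default_rng(3)
        m = estimate_global_model(rng.normal(3000, 300, 5_000))
        assert m.sigma_hat == 1.4826 * m.mad

    def test_robust_to_contamination(self):
        """1% uniform contamination barely moves the MAD-based scale."""
        rng = np.random.default_rng(11)
        inserts = np.concatenate(
            [rng.normal(3000, 300, 10_000), rng.uniform(0, 30_000, 100)]
        )
        m = estimate_global_model(inserts)
        assert m.mu_hat == pytest.approx(inserts.mean())
        assert m.sigma_hat == pytest.approx(300, rel=0.05)

    def test_outlier_invariance_vs_naive_sd(self):
        """Appending 10% extreme values leaves sigma_hat nearly unchanged
        while the naive sample SD at least doubles."""
        rng = np.random.default_rng(5)
        base = rng.normal(3000, 300, 10_000)
        extremes = np.full(1_000, 12 * np.median(base))
        contaminated = np.concatenate([base, extremes])
        clean_sigma = estimate_global_model(base).sigma_hat
        dirty_sigma = estimate_global_model(contaminated).sigma_hat
        assert abs(dirty_sigma - clean_sigma) / clean_sigma < 0.15
        assert contaminated.std() >= 2 * base.std()

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        inserts = rng.normal(3000, 300, 501)
        shuffled = rng.permutation(inserts)
        a = estimate_global_model(inserts)
        b = estimate_global_model(shuffled)
        assert a.mu_hat == pytest.approx(b.mu_hat, rel=1e-12)
        assert a.mad == b.mad
        assert a.sigma_hat == b.sigma_hat
        assert a.n_pairs_used == b.n_pairs_used

    def test_empty_rejected(self):
        with pytest.raises(NoUsablePairsError):
            estimate_global_model([])

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            GlobalInsertModel(mu_hat=1.0, mad=1.0, sigma_hat=1.4826, n_pairs_used=0)


class TestOrientation:
    @pytest.mark.parametrize(
        "left_rev, right_rev, layout, ok",
        [
            (False, True, "fr", True),
            (True, False, "fr", False),
            (False, False, "fr", False),
            (True, True, "fr", False),
            (True, False, "rf", True),
            (False, True, "rf", False),
        ],
    )
    def test_layouts(self, left_rev, right_rev, layout, ok):
        assert orientation_is_correct(left_rev, right_rev, layout) is ok


class TestCollectProperInserts:
    LENGTHS = {"c1": 60_000, "c2": 60_000}

    def _bam(self, tmp_path, lines, name="t"):
        return write_tiny_bam(str(tmp_path), self.LENGTHS, lines, name=name)

    def test_passing_pairs(self, tmp_path):
        lines = pair_lines("p1", "c1", 1_000, 3_850) + pair_lines(
            "p2", "c1", 2_000, 4_950
        )
        bam = self._bam(tmp_path, lines)
        assert sorted(collect_proper_inserts(bam)) == [3000, 3100]

    def test_maxinsert_and_minmapq_filters(self, tmp_path):
        lines = (
            pair_lines("p1", "c1", 1_000, 3_850)
            + pair_lines("p2", "c1", 2_000, 4_950)
            + pair_lines("big", "c1", 100, 49_950)  # insert 50,000
            + pair_lines("lowq", "c1", 5_000, 7_850, mapq=10)
        )
        bam = self._bam(tmp_path, lines)
        assert sorted(collect_proper_inserts(bam)) == [3000, 3100]

    def test_one_low_mapq_mate_excludes_pair(self, tmp_path):
        lines = pair_lines("p1", "c1", 1_000, 3_850, mapq2=10) + pair_lines(
            "p2", "c1", 2_000, 4_950
        )
        bam = self._bam(tmp_path, lines)
        assert collect_proper_inserts(bam) == [3100]

    def test_wrong_orientation_excluded(self, tmp_path):
        lines = pair_lines("ff", "c1", 1_000, 3_850, rev1=False, rev2=False
                           ) + pair_lines("ok", "c1", 2_000, 4_950)
        bam = self._bam(tmp_path, lines)
        assert collect_proper_inserts(bam) == [3100]

    def test_intercontig_excluded(self, tmp_path):
        lines = pair_lines("x", "c1", 1_000, 2_000, contig2="c2") + pair_lines(
            "ok", "c1", 2_000, 4_950
        )
        bam = self._bam(tmp_path, lines)
        assert collect_proper_inserts(bam) == [3100]

    def test_no_usable_pairs_signalled(self, tmp_path):
        lines = pair_lines("lowq", "c1", 5_000, 7_850, mapq=10)
        bam = self._bam(tmp_path, lines)
        with pytest.raises(NoUsablePairsError):
            collect_proper_inserts(bam)

    def test_filter_monotonicity(self, tmp_path):
        """Tightening minmapq or maxinsert never admits more pairs."""
        rng = np.random.default_rng(17)
        lines = []
        for k in range(60):
            start = int(rng.integers(0, 40_000))
            insert = int(rng.integers(2_000, 20_000))
            mapq = int(rng.integers(0, 61))
            lines += pair_lines(
                f"r{k}", "c1", start, start + insert - 150, mapq=mapq
            )
        bam = self._bam(tmp_path, lines)
        counts_q = []
        for q in (0, 20, 40, 60):
            try:
                counts_q.append(
                    len(collect_proper_inserts(bam, PairFilterConfig(minmapq=q)))
                )
            except NoUsablePairsError:
                counts_q.append(0)
        assert counts_q == sorted(counts_q, reverse=True)
        counts_m = []
        for m in (25_000, 10_000, 5_000):
            try:
                counts_m.append(
                    len(collect_proper_inserts(bam, PairFilterConfig(maxinsert=m)))
                )
            except NoUsablePairsError:
                counts_m.append(0)
        assert counts_m == sorted(counts_m, reverse=True)

    def test_simulated_intercontig_exclusion_count(self, tmp_path):
        """Pairs placed across two contigs are excluded by construction."""
        rng = np.random.default_rng(23)
        lines = []
        n_inter = 0
        for k in range(300):
            start = int(rng.integers(0, 40_000))
            if rng.random() < 0.1:
                lines += pair_lines(f"r{k}", "c1", start, start, contig2="c2")
                n_inter += 1
            else:
                lines += pair_lines(f"r{k}", "c1", start, start + 2_850)
        bam = self._bam(tmp_path, lines)
        assert len(collect_proper_inserts(bam)) == 300 - n_inter
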