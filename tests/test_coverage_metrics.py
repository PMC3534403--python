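"""Coverage metrics: depth accumulation, breadth-at-depth, uniformity, specificity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tseq_eval.coverage_metrics import (
    DepthProfile,
    ReadPlacement,
    coverage_fraction,
    depth_profile,
    on_target_stats,
    summarize_coverage,
    uniformity_0_2x,
)


def brute_force_depths(reads, amp):
    """Oracle: per-base interval-stabbing count over the analyzable interior."""
    out = []
    for pos in range(amp.analyzable_start, amp.analyzable_end):
        out.append(
            sum(
                1
                for r in reads
                if r.mapped and r.chrom == amp.chrom and r.start <= pos < r.end
            )
        )
    return out


class TestDepthProfile:
    def test_no_reads_all_zero(self, tiny_panel):
        profile = depth_profile([], tiny_panel)
        assert profile.n_bases == tiny_panel.total_analyzable_bases
        assert profile.concatenated().sum() == 0

    def test_single_spanning_read(self, tiny_panel):
        reads = [ReadPlacement("chr1", 100, 200, True)]
        profile = depth_profile(reads, tiny_panel)
        assert (profile.depths["amp1"] == 1).all()
        assert (profile.depths["amp2"] == 0).all()

    def test_staggered_reads_match_brute_force(self, tiny_panel):
        rng = np.random.default_rng(3)
        reads = [
            ReadPlacement(
                rng.choice(["chr1", "chr2", "chrX"]),
                int(s := rng.integers(0, 400)),
                int(s + rng.integers(1, 120)),
                bool(rng.random() < 0.9),
            )
            for _ in range(60)
        ]
        profile = depth_profile(reads, tiny_panel)
        for amp in tiny_panel:
            assert profile.depths[amp.id].tolist() == brute_force_depths(reads, amp)

    def test_unmapped_reads_ignored(self, tiny_panel):
        reads = [ReadPlacement("chr1", 100, 200, False)]
        assert depth_profile(reads, tiny_panel).concatenated().sum() == 0


class TestOnTarget:
    def test_percentage_arithmetic(self, tiny_panel):
        reads = (
            [ReadPlacement("chr1", 150, 160, True)] * 330
            + [ReadPlacement("chr9", 0, 50, True)] * 170
            + [ReadPlacement("*", 0, 0, False)] * 500
        )
        total, mapped, on = on_target_stats(reads, tiny_panel)
        assert (total, mapped, on) == (1000, 500, 330)
        assert 100 * mapped / total == 50.0
        assert 100 * on / mapped == 66.0

    def test_one_base_overlap_is_on_target(self, tiny_panel):
        # amp1 spans [100, 200): a read ending at 101 overlaps exactly one base
        total, mapped, on = on_target_stats(
            [ReadPlacement("chr1", 95, 101, True)], tiny_panel
        )
        assert on == 1

    def test_adjacent_read_is_off_target(self, tiny_panel):
        total, mapped, on = on_target_stats(
            [ReadPlacement("chr1", 95, 100, True)], tiny_panel
        )
        assert on == 0

    def test_primer_footprint_counts_as_on_target(self, tiny_panel):
        # overlap only the fwd primer bases [100, 105)
        _, _, on = on_target_stats([ReadPlacement("chr1", 100, 104, True)], tiny_panel)
        assert on == 1

    def test_unknown_chromosome_is_off_target_not_error(self, tiny_panel):
        total, mapped, on = on_target_stats(
            [ReadPlacement("chrUn", 0, 50, True)], tiny_panel
        )
        assert (total, mapped, on) == (1, 1, 0)


class TestBreadth:
    def test_half_of_bases_at_20x(self):
        profile = DepthProfile({"a": np.array([0, 10, 20, 30])})
        assert coverage_fraction(profile, 20) == 50.0

    def test_all_zero_profile(self):
        profile = DepthProfile({"a": np.zeros(10, dtype=int)})
        assert coverage_fraction(profile, 1) == 0.0

    def test_matches_brute_force_count_on_lognormal_depths(self):
        rng = np.random.default_rng(5)
        depths = np.rint(rng.lognormal(3, 1.2, size=500)).astype(int)
        profile = DepthProfile({"a": depths})
        for k in (1, 20, 30, 50, 100):
            expected = 100.0 * sum(1 for d in depths if d >= k) / len(depths)
            assert coverage_fraction(profile, k) == pytest.approx(expected)

    def test_c1_complements_zero_depth_fraction(self):
        rng = np.random.default_rng(8)
        depths = rng.integers(0, 5, size=400)
        profile = DepthProfile({"a": depths})
        pct_zero = 100.0 * np.count_nonzero(depths == 0) / depths.size
        assert coverage_fraction(profile, 1) == pytest.approx(100.0 - pct_zero)

    @given(st.lists(st.integers(0, 500), min_size=1, max_size=200))
    def test_non_increasing_in_threshold(self, depths):
        profile = DepthProfile({"a": np.array(depths)})
        values = [coverage_fraction(profile, k) for k in range(1, 60, 7)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_empty_profile_is_error(self):
        with pytest.raises(ValueError, match="no target bases"):
            coverage_fraction(DepthProfile({}), 1)


class TestUniformity:
    def test_constant_depth_is_fully_uniform(self):
        profile = DepthProfile({"a": np.full(100, 7)})
        assert uniformity_0_2x(profile) == 100.0

    def test_hand_computed_example(self):
        # mean 77.5, cutoff 15.5 -> the depth-10 base fails
        profile = DepthProfile({"a": np.array([100, 100, 100, 10])})
        assert uniformity_0_2x(profile) == 75.0

    @given(
        st.lists(st.integers(0, 300), min_size=2, max_size=100).filter(
            lambda d: sum(d) > 0
        ),
        st.integers(2, 9),
    )
    def test_invariant_under_uniform_scaling(self, depths, factor):
        base = DepthProfile({"a": np.array(depths)})
        scaled = DepthProfile({"a": np.array(depths) * factor})
        assert uniformity_0_2x(base) == uniformity_0_2x(scaled)

    def test_zero_mean_is_error(self):
        with pytest.raises(ValueError, match="mean depth"):
            uniformity_0_2x(DepthProfile({"a": np.zeros(5, dtype=int)}))


class TestSummarize:
    def test_empty_stream_reports_missing(self, tiny_panel):
        rep = summarize_coverage([], tiny_panel, sample_id="empty")
        assert rep.reads_total == 0
        assert rep.mapped_pct is None and rep.on_target_pct is None
        assert rep.to_record()["mapped_pct"] == "NA"

    def test_breadth_ordering_invariant(self, tiny_panel):
        rng = np.random.default_rng(12)
        reads = [
            ReadPlacement("chr1", int(s := rng.integers(80, 400)), int(s + 50), True)
            for _ in range(2000)
        ]
        rep = summarize_coverage(reads, tiny_panel)
        assert rep.c1 >= rep.c20 >= rep.c30 >= rep.c50 >= rep.c100
        assert 0.0 <= rep.uniformity_0_2x <= 100.0
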