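"""Synthetic-data generator: panel structure, genotype truth, sampling models."""

import numpy as np
import pytest

from tseq_eval.concordance_eval import mendelian_consistent
from tseq_eval.pool_analysis import PoolSpec, nonref_dosage
from tseq_eval.synthetic_data import (
    SimConfig,
    make_panel,
    make_truth,
    simulate_pool_pileup,
    simulate_sample_pileup,
)


class TestMakePanel:
    def test_default_panel_shape(self):
        cfg = SimConfig(seed=4)
        panel = make_panel(cfg)
        assert len(panel) == 384
        for amp in panel:
            assert 300 <= amp.length <= 600
            assert amp.fwd_primer_len == amp.rev_primer_len == 20
        # non-overlapping, sorted
        for a, b in zip(panel.amplicons, panel.amplicons[1:]):
            assert b.start >= a.end

    def test_seed_determinism(self):
        cfg = SimConfig(seed=9)
        assert make_panel(cfg).amplicons == make_panel(cfg).amplicons

    def test_single_amplicon_panel(self):
        panel = make_panel(SimConfig(seed=1, n_amplicons=1, n_variant_sites=5))
        assert len(panel) == 1


class TestTruth:
    def test_maf_zero_everyone_hom_ref(self, small_sim):
        cfg = SimConfig(seed=2, n_amplicons=20, n_variant_sites=30, maf_values=(0.0,))
        panel = make_panel(cfg)
        truth = make_truth(panel, cfg)
        for per_site in truth.genotypes.values():
            for (chrom, pos), gt in per_site.items():
                v = next(s for s in truth.sites if s.pos == pos)
                assert gt == (v.ref_base, v.ref_base)

    def test_maf_one_everyone_hom_alt(self):
        cfg = SimConfig(seed=2, n_amplicons=20, n_variant_sites=30, maf_values=(1.0,))
        panel = make_panel(cfg)
        truth = make_truth(panel, cfg)
        for per_site in truth.genotypes.values():
            for (chrom, pos), gt in per_site.items():
                v = next(s for s in truth.sites if s.pos == pos)
                assert gt == (v.alt_base, v.alt_base)

    def test_transmission_is_mendelian_by_construction(self, small_sim):
        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        for trio in truth.trios:
            for v in truth.sites:
                f = truth.genotypes[trio.father_id][v.site]
                m = truth.genotypes[trio.mother_id][v.site]
                c = truth.genotypes[trio.child_id][v.site]
                assert mendelian_consistent(f, m, c)

    def test_sites_lie_on_analyzable_bases(self, small_sim):
        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        for v in truth.sites:
            assert panel.contains_analyzable(v.chrom, v.pos)


class TestSamplePileup:
    def test_counts_sum_to_depth_conservation(self, small_sim):
        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        pileup, _ = simulate_sample_pileup(truth, panel, small_sim, "NA12003")
        assert len(pileup) == small_sim.n_variant_sites
        for s in pileup:
            assert sum(s.counts.values()) == s.depth

    def test_determinism_byte_identical(self, small_sim):
        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        p1, r1 = simulate_sample_pileup(truth, panel, small_sim, "NA12003")
        p2, r2 = simulate_sample_pileup(truth, panel, small_sim, "NA12003")
        assert p1 == p2
        assert r1.equals(r2)

    def test_samples_get_independent_depth_draws(self, small_sim):
        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        _, r1 = simulate_sample_pileup(truth, panel, small_sim, "NA12003")
        _, r2 = simulate_sample_pileup(truth, panel, small_sim, "NA12004")
        assert not r1.equals(r2)

    def test_error_free_hom_ref_sites_have_zero_nonref(self):
        cfg = SimConfig(
            seed=3, n_amplicons=20, n_variant_sites=40, mean_depth=200.0,
            per_base_error=0.0, maf_values=(0.0,),
        )
        panel = make_panel(cfg)
        truth = make_truth(panel, cfg)
        pileup, _ = simulate_sample_pileup(truth, panel, cfg, "NA10838")
        for s in pileup:
            assert s.counts[s.ref_base] == s.depth

    def test_het_sites_binomial_around_half(self):
        cfg = SimConfig(
            seed=5, n_amplicons=30, n_variant_sites=50, mean_depth=1000.0,
            per_base_error=0.0, depth_dispersion=0.1, maf_values=(0.5,),
        )
        panel = make_panel(cfg)
        truth = make_truth(panel, cfg)
        pileup, _ = simulate_sample_pileup(truth, panel, cfg, "NA12003")
        by_site = {s.pos: s for s in pileup}
        for v in truth.sites:
            gt = truth.genotypes["NA12003"][v.site]
            if nonref_dosage(gt, v.ref_base) != 1:
                continue
            s = by_site[v.pos]
            frac = s.counts[v.alt_base] / s.depth
            sigma = (0.25 / s.depth) ** 0.5
            assert abs(frac - 0.5) < 4 * sigma

    def test_error_rate_recovered_at_hom_ref_sites(self):
        """Mean observed non-reference fraction across hom-ref sites ~ per_base_error."""
        cfg = SimConfig(
            seed=6, n_amplicons=200, n_variant_sites=2000, mean_depth=500.0,
            depth_dispersion=0.2, per_base_error=0.01, maf_values=(0.0,),
        )
        panel = make_panel(cfg)
        truth = make_truth(panel, cfg)
        pileup, _ = simulate_sample_pileup(truth, panel, cfg, "NA12003")
        fracs = np.array([1 - s.counts[s.ref_base] / s.depth for s in pileup])
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - cfg.per_base_error) < 3 * se

    def test_tiling_reads_realise_amplicon_depths(self, small_sim):
        from tseq_eval.coverage_metrics import depth_profile

        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        pileup, reads = simulate_sample_pileup(truth, panel, small_sim, "NA12003")
        profile = depth_profile(reads, panel)
        by_site = {s.pos: s.depth for s in pileup}
        for amp in panel:
            depths = profile.depths[amp.id]
            assert depths.min() == depths.max()  # constant across the amplicon
            for v in truth.sites:
                if amp.analyzable_start <= v.pos < amp.analyzable_end:
                    assert by_site[v.pos] == depths[0]


class TestPoolPileup:
    def test_expected_fraction_one_het_member(self):
        cfg = SimConfig(
            seed=7, n_amplicons=50, n_variant_sites=200, mean_depth=5000.0,
            depth_dispersion=0.05, per_base_error=0.0, maf_values=(0.5,),
        )
        panel = make_panel(cfg)
        truth = make_truth(panel, cfg)
        spec = PoolSpec(tuple(truth.samples))
        fractions = truth.pooled_fractions(spec)
        pileup = simulate_pool_pileup(truth, spec, panel, cfg)
        for s in pileup:
            f = fractions[(s.chrom, s.pos)]
            if s.depth == 0:
                continue
            obs = 1 - s.counts[s.ref_base] / s.depth
            sigma = max((f * (1 - f) / s.depth) ** 0.5, 1e-3)
            assert abs(obs - f) < 5 * sigma

    def test_unknown_member_raises(self, small_sim):
        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        with pytest.raises(KeyError, match="GHOST"):
            simulate_pool_pileup(truth, PoolSpec(("GHOST",)), panel, small_sim)

    def test_dominant_hom_alt_member_drives_fraction_to_one(self, small_sim):
        cfg = SimConfig(seed=8, n_amplicons=20, n_variant_sites=30, maf_values=(1.0,))
        panel = make_panel(cfg)
        truth = make_truth(panel, cfg)
        spec = PoolSpec(("NA12003", "NA12004"), (0.999, 0.001))
        fractions = truth.pooled_fractions(spec)
        assert all(f == pytest.approx(1.0) for f in fractions.values())

    def test_replicates_differ_but_same_seed_repeats(self, small_sim):
        panel = make_panel(small_sim)
        truth = make_truth(panel, small_sim)
        spec = PoolSpec(tuple(truth.samples))
        a0 = simulate_pool_pileup(truth, spec, panel, small_sim, replicate=0)
        a0b = simulate_pool_pileup(truth, spec, panel, small_sim, replicate=0)
        a1 = simulate_pool_pileup(truth, spec, panel, small_sim, replicate=1)
        assert a0 == a0b
        assert a0 != a1
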