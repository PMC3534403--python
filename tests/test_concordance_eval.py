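"""Concordance summaries, Mendelian checks, correlation, positive-control inference."""

import pytest

from tseq_eval.concordance_eval import (
    concordance_summary,
    false_negative_rate,
    infer_positive_controls,
    mendelian_check,
    mendelian_consistent,
    pearson_r2,
)
from tseq_eval.genotype_caller import GenotypeCall
from tseq_eval.io_formats import ReferenceGenotype, Trio
from tseq_eval.util import round_half_up


def make_call(pos, klass, ref="C", alt="A", detected=True, chrom="chr1"):
    freq = {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0, "no_call": 0.0}[klass]
    return GenotypeCall(
        chrom, pos, ref, klass, alt if klass != "hom_ref" else alt,
        freq, 100, detected and klass != "no_call",
    )


def make_ref(pos, alleles, sample="S1", chrom="chr1"):
    return ReferenceGenotype(sample, chrom, pos, alleles)


class TestConcordanceSummary:
    def test_all_detected_and_concordant(self):
        calls = [make_call(i, "het") for i in range(10)]
        refs = [make_ref(i, ("A", "C")) for i in range(10)]
        rep = concordance_summary(calls, refs)
        assert rep.n_not_detected == 0
        assert rep.fn_rate == 0.0
        assert rep.concordance_overall == 100.0
        assert rep.concordance_het == 100.0
        assert rep.concordance_hom is None  # no hom reference sites

    def test_fn_rate_from_counts(self):
        # ten reference sites, three without a detected call
        calls = [make_call(i, "het", detected=(i >= 3)) for i in range(10)]
        refs = [make_ref(i, ("A", "C")) for i in range(10)]
        rep = concordance_summary(calls, refs)
        assert rep.n_reference_sites == 10
        assert rep.n_not_detected == 3
        assert rep.fn_rate == pytest.approx(30.0)
        assert rep.detection_rate == pytest.approx(70.0)

    def test_discordance_stratified_by_reference_zygosity(self):
        calls = [
            make_call(0, "het"),        # ref het -> concordant
            make_call(1, "hom_ref"),    # ref het -> discordant (het stratum)
            make_call(2, "hom_alt"),    # ref hom-ref -> discordant (hom stratum)
            make_call(3, "hom_ref"),    # ref hom-ref -> concordant
        ]
        refs = [
            make_ref(0, ("A", "C")),
            make_ref(1, ("A", "C")),
            make_ref(2, ("C", "C")),
            make_ref(3, ("C", "C")),
        ]
        rep = concordance_summary(calls, refs)
        assert rep.concordance_overall == pytest.approx(50.0)
        assert rep.concordance_het == pytest.approx(50.0)
        assert rep.concordance_hom == pytest.approx(50.0)

    def test_missing_reference_genotypes_excluded(self):
        calls = [make_call(0, "het")]
        refs = [make_ref(0, ("A", "C")), make_ref(1, None)]
        rep = concordance_summary(calls, refs)
        assert rep.n_reference_sites == 1

    def test_refs_must_be_single_sample(self):
        with pytest.raises(ValueError, match="multiple samples"):
            concordance_summary(
                [], [make_ref(0, ("A", "C"), "S1"), make_ref(1, ("A", "C"), "S2")]
            )

    def test_no_usable_reference_sites_is_error(self):
        with pytest.raises(ValueError, match="no non-missing"):
            concordance_summary([], [make_ref(0, None)])

    def test_printed_fn_rate_cells(self):
        assert round_half_up(false_negative_rate(274, 43)) == 15.7
        assert round_half_up(false_negative_rate(272, 9)) == 3.3


class TestMendelian:
    TRIO = Trio("F", "M", "C", "fam1")

    def test_impossible_transmission(self):
        assert not mendelian_consistent(("A", "A"), ("A", "A"), ("A", "G"))

    def test_het_parents_allow_all_child_genotypes(self):
        for child in [("A", "A"), ("A", "G"), ("G", "G")]:
            assert mendelian_consistent(("A", "G"), ("A", "G"), child)

    def test_error_listed_with_genotypes(self):
        father = [make_call(0, "hom_ref")]
        mother = [make_call(0, "hom_ref")]
        child = [make_call(0, "het")]
        res = mendelian_check(child, father, mother, self.TRIO)
        assert res.n_sites_tested == 1
        assert res.errors == [(("chr1", 0), ("C", "C"), ("C", "C"), ("A", "C"))]

    def test_sites_missing_in_any_member_not_tested(self):
        father = [make_call(0, "hom_ref"), make_call(1, "hom_ref")]
        mother = [make_call(0, "hom_ref")]
        child = [make_call(0, "hom_ref"), make_call(1, "het")]
        res = mendelian_check(child, father, mother, self.TRIO)
        assert res.n_sites_tested == 1
        assert res.n_errors == 0


class TestPearsonR2:
    def test_identity_and_affine(self):
        x = [0.1, 0.2, 0.3, 0.4]
        assert pearson_r2(x, x) == pytest.approx(1.0)
        assert pearson_r2(x, [3 * v + 0.1 for v in x]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # Sxy^2 / (Sxx * Syy) = 9 / (2 * 14/3) = 27/28
        assert pearson_r2([1, 2, 3], [1, 2, 4]) == pytest.approx(27 / 28)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r2([1, 1, 1], [1, 2, 3])


class TestPositiveControls:
    TRIOS = [Trio("F", "M", "C", "fam1")]

    def test_site_detected_everywhere_and_consistent_included(self):
        call_sets = {
            "F": [make_call(0, "het")],
            "M": [make_call(0, "hom_ref")],
            "C": [make_call(0, "het")],
        }
        (ctrl,) = infer_positive_controls(call_sets, self.TRIOS, min_samples=2)
        assert ctrl.site == ("chr1", 0)
        assert ctrl.genotypes == {"F": ("A", "C"), "M": ("C", "C"), "C": ("A", "C")}

    def test_single_sample_site_excluded(self):
        call_sets = {
            "F": [make_call(0, "het"), make_call(1, "het")],
            "M": [make_call(0, "hom_ref")],
            "C": [make_call(0, "het")],
        }
        controls = infer_positive_controls(call_sets, self.TRIOS, min_samples=2)
        assert [c.site for c in controls] == [("chr1", 0)]

    def test_mendelian_violation_excludes_site(self):
        call_sets = {
            "F": [make_call(0, "hom_ref")],
            "M": [make_call(0, "hom_ref")],
            "C": [make_call(0, "hom_alt")],
        }
        assert infer_positive_controls(call_sets, self.TRIOS, min_samples=2) == []

    def test_replicate_conflict_excludes_site(self):
        call_sets = {
            "F": [[make_call(0, "het")], [make_call(0, "hom_alt")]],  # two replicates
            "M": [[make_call(0, "het")]],
            "C": [[make_call(0, "het")]],
        }
        assert infer_positive_controls(call_sets, self.TRIOS, min_samples=2) == []

    def test_needs_at_least_two_samples(self):
        with pytest.raises(ValueError, match="two samples"):
            infer_positive_controls({"F": [make_call(0, "het")]})
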