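"""Dosage model: signal equivalents, layouts, declaration checks."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from polykasp.clusters import (
    DeclarationStatus,
    MissingOfftargetState,
    SnpClass,
    check_declaration,
    concordance_table,
    enumerate_compositions,
    predict_layout,
    signal_equivalents,
)
from polykasp import datasets
from oracles import count_signals, layout_by_enumeration


@pytest.mark.parametrize(
    "flat,green,red",
    [
        ("AATTGG", 4, 2),  # hexaploid A/G target on a T/T + G/G background
        ("GGTTGG", 2, 4),
        ("AAAAAA", 6, 0),
        ("CCCC", 0, 4),
    ],
)
def test_signal_equivalents(flat, green, red):
    pt = signal_equivalents(flat)
    assert (pt.green_equiv, pt.red_equiv) == (green, red)


def test_theta_undefined_at_zero_magnitude():
    with pytest.raises(ZeroDivisionError):
        signal_equivalents("").theta


@given(st.text(alphabet="ACGT", min_size=2, max_size=12).filter(lambda s: len(s) % 2 == 0))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_conservation_green_plus_red(flat):
    pt = signal_equivalents(flat)
    assert pt.green_equiv + pt.red_equiv == len(flat)
    assert (pt.green_equiv, pt.red_equiv) == count_signals(flat)


class TestEnumerate:
    def test_single_copy(self):
        comps = enumerate_compositions(1, ("A", "G"))
        assert [c.flattened for c in comps] == ["AA", "AG", "GG"]

    def test_three_copy_with_offtargets(self):
        comps = enumerate_compositions(3, ("A", "G"), ["TT", "GG"])
        assert [c.flattened for c in comps] == ["AATTGG", "AGTTGG", "GGTTGG"]

    def test_three_copy_uniform_offtargets(self):
        comps = enumerate_compositions(3, ("A", "G"), ["AA", "AA"])
        assert [c.flattened for c in comps] == ["AAAAAA", "AGAAAA", "GGAAAA"]

    def test_missing_offtarget_state_raises(self):
        with pytest.raises(MissingOfftargetState):
            enumerate_compositions(3, ("A", "G"), ["TT"])


class TestLayout:
    def test_simple_snp_three_clusters(self):
        lay = predict_layout(enumerate_compositions(1, ("A", "G")))
        assert lay.snp_class is SnpClass.SIMPLE
        pts = {(p.green_equiv, p.red_equiv) for p in lay.clusters}
        assert pts == {(2, 0), (1, 1), (0, 2)}

    def test_hemi_two_het_clusters(self):
        comps = enumerate_compositions(3, ("A", "G"), ["TT", "GG"])
        lay = predict_layout(comps)
        assert lay.snp_class is SnpClass.HEMI_TWO_HET
        homs = [lay.class_points["AA"], lay.class_points["GG"]]
        assert [(p.green_equiv, p.red_equiv) for p in homs] == [(4, 2), (2, 4)]
        assert all(p.is_heterozygous_position for p in homs)

    def test_hemi_one_het_cluster(self):
        comps = enumerate_compositions(3, ("A", "G"), ["AA", "AA"])
        lay = predict_layout(comps)
        assert lay.snp_class is SnpClass.HEMI_ONE_HET
        pts = {(p.green_equiv, p.red_equiv) for p in lay.clusters}
        assert pts == {(6, 0), (5, 1), (4, 2)}

    def test_polymorphic_offtarget_unclassified(self):
        from polykasp.clusters import AlleleComposition

        comps = [
            AlleleComposition("AA", ("t", "o"), (("A", "A"), ("T", "T")), 0),
            AlleleComposition("AG", ("t", "o"), (("A", "G"), ("C", "C")), 0),
            AlleleComposition("GG", ("t", "o"), (("G", "G"), ("T", "T")), 0),
        ]
        assert predict_layout(comps).snp_class is SnpClass.UNCLASSIFIED

    @pytest.mark.parametrize("copies", [1, 2, 3])
    def test_layout_matches_exhaustive_enumeration(self, copies):
        """Modelled genotype-class points agree with brute-force counting
        over every admissible off-target background."""
        for states in itertools.product("ACGT", repeat=copies - 1):
            comps = enumerate_compositions(copies, ("A", "C"), [s * 2 for s in states])
            lay = predict_layout(comps)
            oracle = layout_by_enumeration([c.flattened for c in comps])
            assert {
                (p.green_equiv, p.red_equiv): len(v) for p, v in lay.clusters.items()
            } == {pt: len(v) for pt, v in oracle.items()}

    def test_same_color_offtarget_swap_never_changes_layout(self):
        comps1 = enumerate_compositions(3, ("A", "G"), ["TT", "GG"])
        comps2 = enumerate_compositions(3, ("A", "G"), ["AA", "CC"])
        l1, l2 = predict_layout(comps1), predict_layout(comps2)
        assert set(l1.clusters) == set(l2.clusters)


class TestDeclaration:
    def test_triallelic_hemi_color_ambiguous(self):
        """The declared T/G hypothesis reproduces the identical layout as
        the true A/G polymorphism: ambiguous without Sanger data."""
        comps = enumerate_compositions(3, ("T", "G"), ["TT", "GG"])
        lay = predict_layout(comps)
        status = check_declaration(lay, comps, ("T", "G"))
        assert status is DeclarationStatus.COLOR_AMBIGUOUS
        assert lay.snp_class is SnpClass.HEMI_TRIALLELIC

    def test_sanger_contradicts_declaration(self):
        comps = enumerate_compositions(3, ("T", "G"), ["TT", "GG"])
        lay = predict_layout(comps)
        status = check_declaration(lay, comps, ("T", "G"), ("A", "G"))
        assert status is DeclarationStatus.CONTRADICTED

    def test_simple_snp_with_matching_sanger_confirmed(self):
        comps = enumerate_compositions(1, ("A", "G"))
        lay = predict_layout(comps)
        assert (
            check_declaration(lay, comps, ("A", "G"), ("A", "G"))
            is DeclarationStatus.CONFIRMED
        )

    def test_simple_snp_without_sanger_confirmed(self):
        comps = enumerate_compositions(1, ("A", "G"))
        lay = predict_layout(comps)
        assert check_declaration(lay, comps, ("A", "G")) is DeclarationStatus.CONFIRMED


class TestConcordance:
    def test_published_probe_set_has_one_contradiction(self):
        summary = concordance_table(
            datasets.reported_alleles(), datasets.sanger_alleles()
        )
        assert summary.contradicted == 1
        assert summary.contradicted_probes == ["Excalibur_c60554_394"]
        assert summary.confirmed == 14
        assert not summary.unmatched_probes

    def test_identical_inputs_no_contradiction(self):
        rep = datasets.reported_alleles()
        summary = concordance_table(rep, dict(rep))
        assert summary.contradicted == 0
        assert summary.confirmed == len(rep)

    def test_unmatched_and_unresolvable(self):
        rep = {"p1": ("A", "G"), "p2": ("T", "C")}
        sg = {"p1": None, "p3": ("A", "G")}
        summary = concordance_table(rep, sg)
        assert summary.unresolvable == 1
        assert sorted(summary.unmatched_probes) == ["p2", "p3"]
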