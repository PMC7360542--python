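"""Genotype calling, failure-mode model, and Null-haplotype collapse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polykasp.clusters import enumerate_compositions, predict_layout
from polykasp.qc import (
    NULL,
    AlleleTemplate,
    AmplificationScenario,
    DegenerateClusters,
    FluorescencePoint,
    HaplotypeRow,
    HaplotypeTable,
    TooFewPoints,
    artifact_report,
    call_genotypes,
    collapse_null_haplotypes,
    simulate_failure_mode,
)
from polykasp.simulate import simulate_signal_cloud
from oracles import low_frequency_scan


def _cloud(sigma, mixtures=(), seed=11, n=40):
    lay = predict_layout(enumerate_compositions(1, ("A", "G")))
    rng = np.random.default_rng(seed)
    return simulate_signal_cloud(lay, n_per_class=n, sigma=sigma,
                                 mixtures=mixtures, rng=rng)


EXPECTED = {"AA": "AA", "AG": "AB", "GG": "BB", "NTC": "missing"}


class TestCalling:
    def test_noise_free_calls_are_perfectly_concordant(self):
        points, labels = _cloud(sigma=0.0)
        calls = call_genotypes(points, seed=0)
        assert all(c.call == EXPECTED[l] for c, l in zip(calls, labels))

    def test_ntc_never_genotyped(self):
        points, labels = _cloud(sigma=0.02)
        calls = call_genotypes(points, seed=0)
        for c, l in zip(calls, labels):
            if l == "NTC":
                assert c.call == "missing" and c.cluster_index is None

    def test_mixture_series_called_heterozygous(self):
        """Artificial heterozygote mixtures across 1:9-9:1 template ratios
        must all land in the heterozygous cluster under documented noise."""
        ratios = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))
        points, labels = _cloud(sigma=0.03, mixtures=ratios)
        calls = call_genotypes(points, seed=0)
        mix_calls = [c.call for c, l in zip(calls, labels) if l.startswith("mix:")]
        assert mix_calls and set(mix_calls) == {"AB"}

    def test_concordance_degrades_monotonically_with_noise(self):
        rates = []
        for sigma in (0.0, 0.05, 0.30):
            points, labels = _cloud(sigma=sigma, seed=5, n=60)
            calls = call_genotypes(points, seed=0)
            ok = sum(
                c.call == EXPECTED[l] for c, l in zip(calls, labels)
            )
            rates.append(ok / len(calls))
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]

    def test_too_few_points(self):
        pts = [FluorescencePoint("s1", 10, 10)]
        with pytest.raises(TooFewPoints):
            call_genotypes(pts)

    def test_degenerate_clusters_detected(self):
        pts = [FluorescencePoint(f"s{i}", 100, 100) for i in range(10)]
        with pytest.raises(DegenerateClusters):
            call_genotypes(pts, k=2)

    def test_no_pipeline_path_emits_null(self):
        points, _ = _cloud(sigma=0.2, seed=3)
        calls = call_genotypes(points, seed=0)
        assert all(c.call in ("AA", "AB", "BB", "missing") for c in calls)


class TestFailureModes:
    def test_symmetric_scenario_keeps_heterozygote_centred(self):
        sc = AmplificationScenario(AlleleTemplate(), AlleleTemplate())
        pts = {p.genotype: p for p in simulate_failure_mode(sc)}
        assert pts["AB"].predicted_call == "AB"
        assert pts["AB"].theta == pytest.approx(0.5)

    def test_common_3prime_mismatch_drives_het_to_homozygous(self):
        """Preferential amplification of allele B after a 3'-terminal
        common-primer mismatch on the allele A product."""
        sc = AmplificationScenario(
            AlleleTemplate(common_3p_mismatches=1), AlleleTemplate()
        )
        pts = {p.genotype: p for p in simulate_failure_mode(sc)}
        assert pts["AB"].predicted_call == "BB"

    def test_5prime_deletion_drives_het_to_other_homozygous(self):
        """The 8 bp deletion at the common primer site suppresses the
        allele-B product: affected heterozygotes co-cluster with AA."""
        sc = AmplificationScenario(AlleleTemplate(), AlleleTemplate(deletion_5p=8))
        pts = {p.genotype: p for p in simulate_failure_mode(sc)}
        assert pts["AB"].predicted_call == "AA"

    def test_multilocus_common_primer_moves_homozygotes_to_het_position(self):
        sc = AmplificationScenario(
            AlleleTemplate(), AlleleTemplate(), offtarget_signal=(1.0, 0.0)
        )
        pts = {p.genotype: p for p in simulate_failure_mode(sc)}
        assert pts["BB"].predicted_call == "AB"

    def test_equal_factors_recover_layout_exactly(self):
        sc = AmplificationScenario(
            AlleleTemplate(amplicon_len=90), AlleleTemplate(amplicon_len=90)
        )
        for p in simulate_failure_mode(sc):
            assert p.predicted_call == p.genotype

    def test_factors_in_unit_interval(self):
        sc = AmplificationScenario(AlleleTemplate(), AlleleTemplate())
        for tmpl in (
            AlleleTemplate(),
            AlleleTemplate(common_3p_mismatches=2, deletion_5p=53, amplicon_len=200),
        ):
            f = sc.efficiency(tmpl, AlleleTemplate(amplicon_len=90))
            assert 0 < f <= 1


def _table(rows, probes=("p1", "p2", "p3")):
    return HaplotypeTable(
        "b", tuple(probes),
        [HaplotypeRow(f"h{i+1}", tuple(a), c) for i, (a, c) in enumerate(rows)],
    )


class TestCollapse:
    def test_unique_match_merges_counts(self):
        t = _table([
            (("A", "C", "G"), 90),
            (("T", "G", "G"), 8),
            (("A", NULL, "G"), 2),
        ])
        out = collapse_null_haplotypes(t)
        assert [r.name for r in out.rows] == ["h1", "h2"]
        assert out.rows[0].count == 92
        assert out.rows[0].merged_from == ("h3",)

    def test_no_match_retained_and_flagged(self):
        t = _table([
            (("A", "C", "G"), 90),
            ((NULL, "G", "T"), 5),
        ])
        out = collapse_null_haplotypes(t)
        flagged = [r for r in out.rows if r.needs_sequencing]
        assert len(flagged) == 1 and flagged[0].count == 5

    def test_ambiguous_match_recorded(self):
        t = _table([
            (("A", "C", "G"), 50),
            (("A", "C", "T"), 40),
            (("A", "C", NULL), 10),
        ])
        out = collapse_null_haplotypes(t)
        amb = [r for r in out.rows if r.ambiguous_matches]
        assert len(amb) == 1
        assert set(amb[0].ambiguous_matches) == {"h1", "h2"}

    def test_null_free_table_is_identity(self):
        t = _table([(("A", "C", "G"), 60), (("T", "G", "T"), 40)])
        out = collapse_null_haplotypes(t)
        assert [(r.name, r.count) for r in out.rows] == [("h1", 60), ("h2", 40)]

    @given(
        st.lists(
            st.tuples(
                st.lists(
                    st.sampled_from(["A", "C", "G", "T", NULL]),
                    min_size=4, max_size=4,
                ),
                st.integers(min_value=1, max_value=200),
            ),
            min_size=1, max_size=10,
        )
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_collapse_idempotent_and_count_conserving(self, raw):
        rows = [
            HaplotypeRow(f"h{i+1}", tuple(a), c) for i, (a, c) in enumerate(raw)
        ]
        t = HaplotypeTable("b", ("p1", "p2", "p3", "p4"), rows)
        once = collapse_null_haplotypes(t)
        twice = collapse_null_haplotypes(once)
        assert once.total_count == t.total_count
        assert [(r.alleles, r.count) for r in twice.rows] == [
            (r.alleles, r.count) for r in once.rows
        ]
        assert abs(sum(r.frequency for r in once.rows) - 100.0) <= 0.2

    @given(
        st.lists(
            st.tuples(
                st.lists(
                    st.sampled_from(["A", "G", NULL]), min_size=3, max_size=3
                ),
                st.floats(min_value=0.1, max_value=60.0),
            ),
            min_size=1, max_size=8,
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_artifact_report_matches_row_scan_oracle(self, raw):
        rows = [
            HaplotypeRow(f"h{i+1}", tuple(a), max(1, int(f * 2)))
            for i, (a, f) in enumerate(raw)
        ]
        t = HaplotypeTable("b", ("p1", "p2", "p3"), rows)
        rep = artifact_report(t)
        n_low, n_null = low_frequency_scan(
            [(r.alleles, r.frequency) for r in t.rows]
        )
        assert rep.low_frequency_rows == n_low
        assert rep.low_frequency_with_null == n_null


def test_haplotype_tsv_roundtrip(tmp_path):
    from polykasp.qc import read_haplotype_tsv, write_haplotype_tsv

    t = _table([(("A", "C", "G"), 90), (("A", NULL, "G"), 10)])
    p = tmp_path / "t.tsv"
    write_haplotype_tsv(t, p)
    # write emits extra columns; reread via the count column
    back = read_haplotype_tsv(p)
    assert back.probe_ids[:3] == ("p1", "p2", "p3")
    assert [r.count for r in back.rows] == [90, 10]
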