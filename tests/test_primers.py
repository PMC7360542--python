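"""Primer placement: constraints, off-target scoring, audit cross-checks."""

from polykasp.mapping import GenomeAssembly
from polykasp.pipeline import design_for_probe, profile_probe
from polykasp.primers import (
    FailureReason,
    PrimerParams,
    SpecificityClass,
    enumerate_allele_primers,
    enumerate_common_primers,
    specificity_audit,
)
from polykasp.simulate import SimConfig, simulate_polyploid_locus, simulate_probe_context
from oracles import scan_placements


def _fixture(cfg):
    assemblies, truth = simulate_polyploid_locus(cfg)
    record = simulate_probe_context(truth, rng=cfg.rng())
    decoded, profile = profile_probe(record, assemblies)
    return assemblies, truth, decoded, profile


class TestAllelePrimers:
    def test_end_on_snp_with_target_allele(self, hexaploid_profile):
        """The 3' base is the target allele expressed on the primer's own
        strand (complemented for reverse-orientation primers)."""
        from polykasp._dna import complement

        decoded, profile, truth, _ = hexaploid_profile
        for orientation in ("forward", "reverse"):
            cands = enumerate_allele_primers(profile, orientation=orientation)
            assert cands
            for c in cands:
                expected = c.allele if orientation == "forward" else complement(c.allele)
                assert c.sequence[-1] == expected
                assert c.allele in decoded.design_strand_alleles

    def test_single_copy_profile_has_empty_reports(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1200))
        from polykasp.probes import ProbeRecord, Strand

        alt = "A" if seq[600] != "A" else "C"
        ctx = f"{seq[550:600]}[{seq[600]}/{alt}]{seq[601:651]}"
        rec = ProbeRecord("p", ctx, Strand.TOP, Strand.TOP, (seq[600], alt))
        decoded, profile = profile_probe(rec, [GenomeAssembly("a", {"c": seq})])
        cands = enumerate_allele_primers(profile)
        assert cands and all(not c.offtarget_report for c in cands)

    def test_engineered_3prime_proximal_mismatch_reported(self):
        """An off-target substitution 3 bp from the SNP shows up in every
        candidate's 3'-proximal mismatch window."""
        cfg = SimConfig(seed=17, divergence=0.0, unique_site_offset=-3,
                        offtarget_states=("A", "A"))
        _, _, _, profile = _fixture(cfg)
        cands = enumerate_allele_primers(profile, orientation="forward")
        assert cands
        for c in cands:
            # both off-target copies carry the engineered mismatch near the 3' end
            assert all(
                rep.mismatches_3p5 >= 1
                for rep in c.offtarget_report.values()
                if not rep.absent
            )

    def test_deletion_under_window_flagged(self):
        cfg = SimConfig(seed=19, copy_deletions=((1, 5, 8),))
        _, _, _, profile = _fixture(cfg)
        cands = enumerate_allele_primers(profile, orientation="reverse")
        flagged = [
            c for c in cands
            if any(r.overlaps_indel for r in c.offtarget_report.values())
        ]
        assert flagged, "no candidate reports the haplotype deletion"


class TestCommonPrimers:
    def test_single_copy_top_candidate_unique_by_absence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1200))
        from polykasp.probes import ProbeRecord, Strand

        alt = "A" if seq[600] != "A" else "C"
        ctx = f"{seq[550:600]}[{seq[600]}/{alt}]{seq[601:651]}"
        rec = ProbeRecord("p", ctx, Strand.TOP, Strand.TOP, (seq[600], alt))
        _, profile = profile_probe(rec, [GenomeAssembly("a", {"c": seq})])
        cands = enumerate_common_primers(profile)
        assert cands and all(not c.offtarget_report for c in cands)

    def test_retained_candidates_overlap_discriminating_window(self):
        """With divergence off and a single engineered column at +35, every
        retained common primer must cover that column."""
        cfg = SimConfig(seed=23, divergence=0.0, unique_site_offset=35,
                        offtarget_states=("A", "A"))
        _, _, _, profile = _fixture(cfg)
        snp = profile.snp_column
        cands = enumerate_common_primers(profile, orientation="forward")
        assert cands
        for c in cands:
            assert c.columns[0] <= snp + 35 <= c.columns[1]

    def test_no_discriminating_window_yields_empty_list(self):
        cfg = SimConfig(seed=29, divergence=0.0, unique_site_offset=None,
                        offtarget_states=("A", "A"))
        _, _, _, profile = _fixture(cfg)
        for orientation in ("forward", "reverse"):
            assert enumerate_common_primers(profile, orientation=orientation) == []


class TestDesign:
    def test_locus_specific_design_audits_to_one_amplicon(self, hexaploid):
        cfg, assemblies, truth, record = hexaploid
        assay = design_for_probe(record, assemblies)
        assert not assay.failed
        assert assay.specificity_class is SpecificityClass.LOCUS_SPECIFIC
        report = specificity_audit(assay, assemblies)
        assert report.n_feasible == 1
        amp = report.amplicons[0]
        assert amp.chrom == truth.chroms[truth.target_copy]

    def test_identical_copies_fail_no_unique_site(self):
        cfg = SimConfig(seed=31, divergence=0.0, unique_site_offset=None,
                        offtarget_states=("A", "A"))
        assemblies, truth = simulate_polyploid_locus(cfg)
        record = simulate_probe_context(truth, rng=cfg.rng())
        assay = design_for_probe(record, assemblies)
        assert assay.failed
        assert assay.failure_reason is FailureReason.NO_UNIQUE_SITE

    def test_intron_blocks_only_window(self):
        """Introns flanking the SNP leave no reachable common-primer window:
        the assay fails with the intron-span reason."""
        cfg = SimConfig(seed=37, divergence=0.0, offtarget_states=("T", "G"),
                        unique_site_offset=None, introns=((40, 150), (58, 150)))
        assemblies, truth = simulate_polyploid_locus(cfg)
        record = simulate_probe_context(truth, rng=cfg.rng())
        assay = design_for_probe(record, assemblies)
        assert assay.failed
        assert assay.failure_reason is FailureReason.INTRON_SPAN

    def test_determinism(self, hexaploid):
        cfg, assemblies, truth, record = hexaploid
        a1 = design_for_probe(record, assemblies)
        a2 = design_for_probe(record, assemblies)
        assert a1.primer_a.sequence == a2.primer_a.sequence
        assert a1.common.sequence == a2.common.sequence
        assert a1.common.placement == a2.common.placement

    def test_adding_assembly_never_improves_specificity(self, hexaploid):
        """Monotonicity: a second assembly can only keep or worsen the
        specificity class."""
        order = {
            SpecificityClass.LOCUS_SPECIFIC: 0,
            SpecificityClass.SEMI_SPECIFIC: 1,
            SpecificityClass.NONSPECIFIC: 2,
        }
        cfg, assemblies, truth, record = hexaploid
        a1 = design_for_probe(record, assemblies)
        # second assembly: an exact duplicate of the target chromosome
        dup = GenomeAssembly(
            "dup", {"chrX": assemblies[0].sequences[truth.chroms[0]]}
        )
        a2 = design_for_probe(record, assemblies + [dup])
        if a2.failed:
            return  # design impossible counts as "worse"
        assert order[a2.specificity_class] >= order[a1.specificity_class]

    def test_tailed_primers_carry_configured_tails(self, hexaploid):
        cfg, assemblies, truth, record = hexaploid
        params = PrimerParams()
        assay = design_for_probe(record, assemblies, params)
        assert assay.primer_a_tailed == params.tail_a + assay.primer_a.sequence
        assert assay.primer_b_tailed == params.tail_b + assay.primer_b.sequence
        assert assay.amplicon_len_a == assay.amplicon_len_b


class TestAudit:
    def test_common_matching_two_copies_downgrades(self):
        """If the common primer sits in a window identical across copies,
        the audit finds >= 2 feasible amplicons."""
        cfg = SimConfig(seed=41, divergence=0.0, unique_site_offset=35,
                        offtarget_states=("T", "G"))
        assemblies, truth = simulate_polyploid_locus(cfg)
        record = simulate_probe_context(truth, rng=cfg.rng())
        decoded, profile = profile_probe(record, assemblies)
        assay = design_for_probe(record, assemblies)
        assert not assay.failed
        # sabotage: place the common primer in a downstream window that is
        # identical across copies (divergence 0, clear of the engineered
        # column at +35), so it primes every copy perfectly
        from dataclasses import replace as dc_replace
        from polykasp._dna import revcomp

        row = profile.msa[1]
        snp = profile.snp_column
        win = row.seq[snp + 45 : snp + 45 + 22]
        assert "-" not in win
        assay.common = dc_replace(assay.common, sequence=revcomp(win))
        report = specificity_audit(assay, assemblies)
        assert report.n_feasible >= 2
        assert report.classify() is SpecificityClass.SEMI_SPECIFIC

    def test_unplaceable_primer_flags_broken_design(self, hexaploid):
        cfg, assemblies, truth, record = hexaploid
        assay = design_for_probe(record, assemblies)
        from dataclasses import replace as dc_replace

        assay.primer_a = dc_replace(assay.primer_a, sequence="ACGT" * 6)
        assay.primer_b = dc_replace(assay.primer_b, sequence="TGCA" * 6)
        report = specificity_audit(assay, assemblies)
        assert report.broken_design

    def test_placement_scan_matches_naive_oracle(self, hexaploid):
        cfg, assemblies, truth, record = hexaploid
        assay = design_for_probe(record, assemblies)
        from polykasp.primers import _scan_primer

        primer = assay.common.sequence
        for chrom, seq in assemblies[0].sequences.items():
            assert _scan_primer(primer, seq, 3) == scan_placements(primer, seq, 3)
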