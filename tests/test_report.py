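"""Consequence annotation, diagnostic tiers and cohort accounting."""

import numpy as np
import pytest

import paramask as pm
from paramask.report import (
    AlleleCall,
    GeneVariant,
    parse_hgvs_c,
)

EXONS = [(1, 100), (201, 300), (401, 500), (601, 702)]  # toy transcript


def gene_seq_for(exons, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=exons[-1][1]))


class TestAnnotateConsequence:
    def test_inframe_deletion_counts_amino_acids(self):
        # 150 deleted coding bases -> 50 residues, frame preserved
        v = GeneVariant("exon_del", pos=201, end=450)
        ann = pm.annotate_consequence(v, [(201, 300), (401, 450), (601, 700)])
        assert ann.kind == "in_frame_indel"
        assert ann.details["deleted_nt"] == 150
        assert ann.details["deleted_aa"] == 50

    def test_whole_exon_deletion_frameshifts_when_not_multiple_of_three(self):
        v = GeneVariant("exon_del", pos=150, end=350)
        ann = pm.annotate_consequence(v, EXONS)  # removes the 100-nt exon 2
        assert ann.kind == "frameshift"
        assert ann.details["deleted_nt"] == 100

    def test_intronic_deletion_is_intronic(self):
        v = GeneVariant("exon_del", pos=110, end=160)
        assert pm.annotate_consequence(v, EXONS).kind == "intronic"

    def test_snv_codon_lookup(self):
        seq = list(gene_seq_for(EXONS))
        seq[0:6] = list("ATGTGG")  # Met, Trp
        seq = "".join(seq)
        stop = GeneVariant("snv", pos=5, ref="G", alt="A")  # TGG -> TGA
        assert pm.annotate_consequence(stop, EXONS, gene_seq=seq).kind == "stop_gain"
        syn = GeneVariant("snv", pos=3, ref="G", alt="A")  # ATG -> ATA? Ile: missense
        ann = pm.annotate_consequence(syn, EXONS, gene_seq=seq)
        assert ann.kind in ("missense", "synonymous")
        leu = list(seq)
        leu[6:9] = list("CTT")
        seq2 = "".join(leu)
        syn2 = GeneVariant("snv", pos=9, ref="T", alt="G")  # CTT -> CTG, both Leu
        assert pm.annotate_consequence(syn2, EXONS, gene_seq=seq2).kind == "synonymous"

    def test_splice_site_positions(self):
        donor = GeneVariant("snv", pos=101, ref="G", alt="A")
        acceptor = GeneVariant("snv", pos=200, ref="A", alt="C")
        deep = GeneVariant("snv", pos=150, ref="A", alt="C")
        outside = GeneVariant("snv", pos=800, ref="A", alt="C")
        assert pm.annotate_consequence(donor, EXONS).kind == "splice_site"
        assert pm.annotate_consequence(acceptor, EXONS).kind == "splice_site"
        assert pm.annotate_consequence(deep, EXONS).kind == "intronic"
        assert pm.annotate_consequence(outside, EXONS).kind == "non_coding"

    def test_frame_arithmetic_property(self):
        """deleted_aa*3 == deleted_nt and frameshift iff nt % 3 != 0."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = int(rng.integers(1, 700))
            b = int(rng.integers(a, 702))
            ann = pm.annotate_consequence(GeneVariant("exon_del", pos=a, end=b),
                                          EXONS)
            nt = sum(max(0, min(b, e) - max(a, s) + 1) for s, e in EXONS)
            if nt == 0:
                assert ann.kind in ("intronic", "non_coding")
            elif nt % 3:
                assert ann.kind == "frameshift"
            else:
                assert ann.kind == "in_frame_indel"
                assert ann.details["deleted_aa"] * 3 == nt


class TestAcceptorGain:
    def test_minus_39_retains_38_and_frameshifts(self):
        ann = pm.acceptor_gain_inclusion(-39)
        assert ann.details["retained_nt"] == 38
        assert ann.details["frameshift"] is True

    def test_minus_4_is_single_codon_inclusion(self):
        ann = pm.acceptor_gain_inclusion(-4)
        assert ann.details["retained_nt"] == 3
        assert ann.details["frameshift"] is False

    @pytest.mark.parametrize("offset", [-1, -2, 0, 5])
    def test_offsets_that_cannot_create_an_acceptor(self, offset):
        with pytest.raises(ValueError):
            pm.acceptor_gain_inclusion(offset)

    def test_intron_sequence_validation(self):
        intron = "T" * 30 + "AG" + "T" * 7 + "A"  # A at -1? craft: G at -39 needs A at -40
        with pytest.raises(ValueError):
            pm.acceptor_gain_inclusion(-5, intron_seq="TTTTTTTTTT")


class TestHgvsLite:
    @pytest.mark.parametrize("cdna,kind", [
        ("c.283C>T", "sub"),
        ("c.12444-1G>A", "sub"),
        ("c.6669+1G>A", "sub"),
        ("c.1529del", "del"),
        ("c.2419_2422del", "del"),
        ("c.3252dup", "dup"),
        ("c.8487_8489delinsCA", "delins"),
        ("c.15037_15048delinsGATGATATA", "delins"),
        ("c.5620-311_5788+1198del", "exon_del"),
        ("c.2376+752_2529+9004del", "exon_del"),
    ])
    def test_cohort_patterns_parse(self, cdna, kind):
        assert parse_hgvs_c(cdna)["kind"] == kind

    def test_intronic_offset_extracted(self):
        p = parse_hgvs_c("c.5789-39A>G")
        assert p["start_offset"] == -39 and p["intronic"]

    def test_unsupported_pattern_rejected(self):
        with pytest.raises(ValueError):
            parse_hgvs_c("c.100_200inv")


def mk(vid, zyg="het", stage="SR", locus="gene"):
    return AlleleCall(vid, locus, zyg, stage)


class TestAssembleStatus:
    def test_two_trans_variants_solved_by_short_reads(self):
        s = pm.assemble_status("s", [mk("v1"), mk("v2")], [],
                               {"phase": "trans"})
        assert s.tier == "solved_SR" and s.gene_alleles_found == 2

    def test_short_read_plus_longread_cnv_is_solved_LR(self):
        s = pm.assemble_status("s", [mk("v1")],
                               [mk("del36", stage="LR")], {"phase": "trans"})
        assert s.tier == "solved_LR"

    def test_single_het_is_partial(self):
        s = pm.assemble_status("s", [mk("v1")])
        assert s.tier == "partial" and s.gene_alleles_found == 1

    def test_homozygous_single_variant_solves(self):
        s = pm.assemble_status("s", [mk("v1", zyg="hom")])
        assert s.tier == "solved_SR" and s.phase_evidence == "homozygous"

    def test_cis_pair_is_not_biallelic(self):
        s = pm.assemble_status("s", [mk("v1"), mk("v2")], [], {"phase": "cis"})
        assert s.tier == "partial"
        assert s.warnings

    def test_pseudogene_variant_never_counts(self):
        s = pm.assemble_status("s", [mk("hom_gene", zyg="hom"),
                                     mk("dup_pseudo", locus="pseudo")])
        assert s.tier == "solved_SR"
        assert [c.variant_id for c in s.excluded] == ["dup_pseudo"]

    def test_longread_locus_reassignment_drops_allele(self):
        # the family-16 resolution: one of two "gene" variants is pseudogene
        s = pm.assemble_status(
            "s", [mk("v1", zyg="hom"), mk("v2")], [],
            {"locus_reassignments": {"v2": "pseudo"}})
        assert s.gene_alleles_found == 2
        assert [c.variant_id for c in s.excluded] == ["v2"]

    def test_tier_monotone_in_added_trans_allele(self):
        base = pm.assemble_status("s", [mk("v1")])
        more = pm.assemble_status("s", [mk("v1"), mk("v2")], [],
                                  {"phase": "trans"})
        order = {"unsolved": 0, "partial": 1, "solved_LR": 2, "solved_SR": 2}
        assert order[more.tier] >= order[base.tier]


class TestCohort:
    def test_fixture_reproduces_published_accounting(self):
        df = pm.load_families_fixture()
        statuses = pm.statuses_from_fixture(df)
        summary = pm.cohort_summary(statuses, n_referred=437,
                                    n_genetically_confirmed=242)
        assert summary["solved_SR"] == 15
        assert summary["solved_LR"] == 2
        assert summary["solved_total"] == 17
        assert summary["homozygous_families"] == 6
        assert summary["compound_het_families"] == 11
        assert summary["gene_positive_percent"] == 7

    def test_tier_counts_conserve_cohort_size(self):
        df = pm.load_families_fixture()
        statuses = pm.statuses_from_fixture(df)
        summary = pm.cohort_summary(statuses, 437, 242)
        total = sum(summary[k] for k in
                    ("solved_SR", "solved_LR", "partial", "unsolved"))
        assert total == summary["n_families"] == len(statuses)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            pm.cohort_summary([], 10, 5)

    def test_inconsistent_denominators_rejected(self):
        statuses = pm.statuses_from_fixture(pm.load_families_fixture())
        with pytest.raises(ValueError):
            pm.cohort_summary(statuses, n_referred=10,
                              n_genetically_confirmed=5)
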