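"""Long-read rescue: PSV binning, re-genotyping, deletions and phasing."""

import math

import numpy as np
import pytest

import paramask as pm
from paramask.longread import (
    misassignment_bound,
    phase_relation,
)
from paramask.mapper import Alignment
from paramask.reference import GENE, PSEUDO, PSV
from paramask.homology import HomologyMap, HomologyBlock
from paramask.workflow import (
    long_read_stage,
    masked_reference,
    unique_intervals,
)
from tests.conftest import alt_base, nonpsv_positions


def make_alignment(ref_seq, pos, length, substitutions=None):
    seq = list(ref_seq[pos - 1 : pos - 1 + length])
    for gp, base in (substitutions or {}).items():
        seq[gp - pos] = base
    return Alignment("r", "chrT", pos, [("M", length)], "".join(seq))


class TestBinning:
    def test_error_free_pseudo_read_votes_all_psvs(self, small_ref, small_hmap):
        first10 = small_hmap.psvs_in(small_ref.hom_start + 200,
                                     small_ref.hom_start + 1600)[:10]
        start, end = first10[0].gene_pos - 20, first10[9].gene_pos + 20
        spanned = small_hmap.psvs_in(start, end)
        aln = make_alignment(small_ref.gene_seq, start, end - start + 1,
                             {p.gene_pos: p.pseudo_base for p in spanned})
        bins = pm.bin_reads([aln], small_hmap, q=0.05)
        b = bins["r"]
        w = math.log(0.95 / 0.05)
        assert len(spanned) >= 10
        assert b.assigned_locus == "pseudo"
        assert b.log_odds == pytest.approx(-len(spanned) * w)

    def test_read_with_no_psvs_and_no_unique_overlap_unassigned(
            self, small_ref, small_hmap):
        # a 30bp read rarely spans a PSV; pick a PSV-free window
        psv = sorted(p.gene_pos for p in small_ref.psv_catalog)
        start = next(
            s for s in range(small_ref.hom_start + 10, small_ref.hom_end - 60)
            if not any(s <= p <= s + 30 for p in psv))
        aln = make_alignment(small_ref.gene_seq, start, 30)
        bins = pm.bin_reads([aln], small_hmap, q=0.05)
        assert bins["r"].assigned_locus == "unassigned"

    def test_unique_overlap_assigns_gene_directly(self, small_ref, small_hmap):
        aln = make_alignment(small_ref.gene_seq, 10, 150)  # unique exon 1
        bins = pm.bin_reads([aln], small_hmap, q=0.05,
                            unique_intervals=[(1, small_ref.hom_start - 1)])
        assert bins["r"].assigned_locus == "gene"

    def test_misassignment_bound_five_psvs(self):
        """With a 3-nat threshold, >=4 of 5 PSV bases must flip to misassign."""
        assert misassignment_bound(5, 0.05) < 1e-3

    def test_empirical_misassignment_below_bound(self, default_ref,
                                                 default_hmap, family11_lr):
        truth = {r.read_id: r.truth_origin[0] for r in family11_lr.reads.reads}
        informative = wrong = 0
        for rid, b in family11_lr.bins.items():
            if b.n_psv_informative >= 5 and b.assigned_locus != "unassigned":
                informative += 1
                if b.assigned_locus != truth[rid]:
                    wrong += 1
        assert informative > 100
        assert wrong == 0

    def test_relabelling_symmetry(self, small_ref, small_hmap):
        """Swapping gene/pseudo base in every PSV flips every assignment."""
        swapped = HomologyMap(
            blocks=small_hmap.blocks,
            psvs=[PSV(p.gene_pos, p.pseudo_base, p.gene_base)
                  for p in small_hmap.psvs],
            identity_observed=small_hmap.identity_observed)
        psvs = small_hmap.psvs_in(small_ref.hom_start + 200,
                                  small_ref.hom_start + 1600)[:8]
        start, end = psvs[0].gene_pos - 20, psvs[-1].gene_pos + 20
        aln = make_alignment(small_ref.gene_seq, start, end - start + 1)
        a = pm.bin_reads([aln], small_hmap, q=0.05)["r"]
        b = pm.bin_reads([aln], swapped, q=0.05)["r"]
        assert a.assigned_locus == "gene" and b.assigned_locus == "pseudo"
        assert a.log_odds == pytest.approx(-b.log_odds)

    def test_q_range_validated(self, small_hmap):
        with pytest.raises(ValueError):
            pm.bin_reads([], small_hmap, q=0.5)


class TestRegenotype:
    @pytest.mark.parametrize("alt,depth,expect", [
        (28, 30, "alt/alt"),   # errors account for the two reference reads
        (0, 30, "ref/ref"),
        (16, 30, "ref/alt"),
    ])
    def test_diploid_map_over_three_states(self, alt, depth, expect):
        assert pm.genotype_diploid(alt, depth, q=0.05)["genotype"] == expect

    def test_insufficient_binned_depth_is_no_call(self, small_hmap):
        out = pm.regenotype_per_locus({}, [], 100, "A", "T")
        assert out["genotype"] == "no_call"

    def test_homozygosity_confirmed_from_gene_binned_reads(
            self, default_ref, default_hmap):
        """The parental-testing-free confirmation: masked SR shows ~0.5,
        gene-binned long reads show ~1.0."""
        ref = default_ref
        pos = nonpsv_positions(ref, 6)[400]
        rb = ref.gene_seq[pos - 1]
        ab = alt_base(rb)
        truth = pm.SampleTruth("f8", small_variants=[
            (GENE, 1, pos, rb, ab, "snv"), (GENE, 2, pos, rb, ab, "snv")])
        haps = pm.simulate_sample(ref, truth)
        lr = long_read_stage(ref, default_hmap, haps, coverage=30, seed=61)
        gt = pm.regenotype_per_locus(
            lr.bins, lr.mapping.alignments, pos, rb, ab,
            ref_seq=lr.masked[ref.contig_name])
        assert gt["genotype"] == "alt/alt"
        assert gt["alt"] / gt["depth"] > 0.85


class TestDetectDeletions:
    def test_null_sample_has_no_calls(self, default_ref, default_hmap):
        haps = pm.simulate_sample(default_ref, pm.SampleTruth("null"))
        lr = long_read_stage(default_ref, default_hmap, haps, coverage=20,
                             seed=62)
        assert lr.sv_calls == []

    def test_het_1678_deletion_single_call(self, family11_lr,
                                           family11_deletion):
        calls = family11_lr.sv_calls
        assert len(calls) == 1
        c = calls[0]
        assert abs(c.length - 1678) <= 20
        assert c.locus == "gene"
        assert c.support >= 8  # roughly half of 30x spans the junction
        dstart, dend = family11_deletion["interval"]
        assert abs(c.start - dstart) <= 20 and abs(c.end - dend) <= 20

    def test_multi_exon_deletion_spans_target(self, default_ref, default_hmap):
        """Family-13 analogue: a 9918-bp deletion (the size implied by its
        reported breakpoints) removes several toy exons in one call."""
        ref = default_ref
        s8 = ref.gene_exons[7][0]
        dstart, dend = s8 - 500, s8 - 500 + 9918 - 1
        truth = pm.SampleTruth("f13", exon_deletions=[(GENE, 2, (dstart, dend))])
        haps = pm.simulate_sample(ref, truth)
        lr = long_read_stage(ref, default_hmap, haps, coverage=30, seed=63)
        assert len(lr.sv_calls) == 1
        c = lr.sv_calls[0]
        assert abs(c.length - 9918) <= 30
        assert c.locus == "gene"
        # the deleted exons fall inside the called interval
        for i in (8, 9):
            es, ee = ref.gene_exons[i - 1]
            assert c.start <= es and c.end >= ee

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            pm.detect_deletions([], min_sv_len=0)


class TestPhasing:
    def _two_site_sample(self, ref, cis: bool):
        p1 = nonpsv_positions(ref, 5)[300]
        p2 = nonpsv_positions(ref, 6)[600]
        r1, r2 = ref.gene_seq[p1 - 1], ref.gene_seq[p2 - 1]
        a1, a2 = alt_base(r1), alt_base(r2)
        haps = (1, 1) if cis else (1, 2)
        truth = pm.SampleTruth("ph", small_variants=[
            (GENE, haps[0], p1, r1, a1, "snv"),
            (GENE, haps[1], p2, r2, a2, "snv")])
        sites = [(p1, r1, a1, "snv"), (p2, r2, a2, "snv")]
        return truth, sites, p1, p2

    @pytest.mark.parametrize("cis", [False, True])
    def test_cis_trans_resolution(self, default_ref, default_hmap, cis):
        truth, sites, p1, p2 = self._two_site_sample(default_ref, cis)
        haps = pm.simulate_sample(default_ref, truth)
        lr = long_read_stage(default_ref, default_hmap, haps, coverage=30,
                             seed=64 + cis)
        blocks = pm.phase_variants(
            lr.mapping.alignments, sites, bins=lr.bins,
            ref_seq=lr.masked[default_ref.contig_name])
        expect = "cis" if cis else "trans"
        assert phase_relation(blocks, p1, p2) == expect

    def test_three_site_phase_recovery_over_replicates(self, default_ref,
                                                       default_hmap):
        """Read-backed phasing recovers a 3-site haplotype in every replicate."""
        ref = default_ref
        positions = [nonpsv_positions(ref, 5)[100],
                     nonpsv_positions(ref, 5)[900],
                     nonpsv_positions(ref, 6)[500]]
        hap_of = [1, 2, 1]
        variants, sites = [], []
        for pos, h in zip(positions, hap_of):
            rb = ref.gene_seq[pos - 1]
            variants.append((GENE, h, pos, rb, alt_base(rb), "snv"))
            sites.append((pos, rb, alt_base(rb), "snv"))
        truth = pm.SampleTruth("ph3", small_variants=variants)
        haps = pm.simulate_sample(ref, truth)
        ok = 0
        reps = 20
        for seed in range(70, 70 + reps):
            lr = long_read_stage(ref, default_hmap, haps, coverage=30,
                                 seed=seed)
            blocks = pm.phase_variants(
                lr.mapping.alignments, sites, bins=lr.bins,
                ref_seq=lr.masked[ref.contig_name])
            rel01 = phase_relation(blocks, positions[0], positions[1])
            rel02 = phase_relation(blocks, positions[0], positions[2])
            if rel01 == "trans" and rel02 == "cis":
                ok += 1
        assert ok == reps

    def test_unphasable_sites_split_blocks(self, small_ref, small_hmap):
        # no co-spanning reads at all -> singleton blocks, unphased relation
        blocks = pm.phase_variants([], [(100, "A", "T", "snv"),
                                        (3000, "C", "G", "snv")])
        assert phase_relation(blocks, 100, 3000) == "unphased"
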