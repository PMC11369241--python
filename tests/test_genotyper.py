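"""Four-copy allele-balance genotyping: oracle equivalence and recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paramask as pm
from paramask.genotyper import candidate_sensitivity, hypotheses
from paramask.homology import HOMOLOGY, UNIQUE
from paramask.reference import GENE, PSEUDO
from paramask.workflow import masked_reference, short_read_stage
from tests.conftest import alt_base, nonpsv_positions


def brute_force_map(alt, depth, region_type, epsilon):
    """Independent posterior oracle: lgamma-based binomial over the grid,
    with the documented default prior (flat over the three common states,
    0.01 on the rare three/four-copy alt states)."""
    def logpmf(k, n, p):
        return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                + k * math.log(p) + (n - k) * math.log(1 - p))

    if region_type == HOMOLOGY:
        grid = {0.0: 1.0, 0.25: 1.0, 0.5: 1.0, 0.75: 0.01, 1.0: 0.01}
    else:
        grid = {0.0: 1.0, 0.5: 1.0, 1.0: 1.0}
    lls, post = {}, {}
    for t, pri in grid.items():
        p = t * (1 - epsilon) + (1 - t) * epsilon / 3
        lls[t] = logpmf(alt, depth, p)
        post[t] = lls[t] + math.log(pri)
    return max(post, key=post.get), lls


class TestExpectedAltFraction:
    @pytest.mark.parametrize("zyg,nloci,region,expect", [
        ("het", 1, HOMOLOGY, 0.25),   # het skewed to a quarter of reads
        ("hom", 1, HOMOLOGY, 0.50),   # hom skewed to half of reads
        ("het", 2, HOMOLOGY, 0.50),
        ("hom", 2, HOMOLOGY, 1.00),
        ("het", 1, UNIQUE, 0.50),
        ("hom", 1, UNIQUE, 1.00),
    ])
    def test_collapsed_copy_arithmetic(self, zyg, nloci, region, expect):
        assert pm.expected_alt_fraction(zyg, nloci, region) == expect

    def test_unique_region_has_no_second_locus(self):
        with pytest.raises(ValueError):
            pm.expected_alt_fraction("het", 2, UNIQUE)


class TestGenotypeSite:
    def test_oracle_equivalence_exhaustive_to_depth_60(self):
        eps = 0.01
        for depth in range(1, 61):
            for alt in range(depth + 1):
                call = pm.genotype_site(alt, depth, HOMOLOGY, eps)
                oracle_theta, oracle_lls = brute_force_map(alt, depth,
                                                           HOMOLOGY, eps)
                assert call.theta_map == oracle_theta, (alt, depth)
                for h in hypotheses(HOMOLOGY):
                    assert call.log_likelihood[h.label] == pytest.approx(
                        oracle_lls[h.theta], abs=1e-9)

    def test_published_allelic_ratio_calls_homozygous(self):
        # 46%:54% C:T at a homozygous site under masking -> theta 0.5
        call = pm.genotype_site(54, 100, HOMOLOGY, 0.01)
        assert call.theta_map == 0.5
        assert call.map_hypothesis == "hom_one_locus_or_het_both"
        assert not call.ambiguous

    def test_quarter_fraction_calls_het(self):
        call = pm.genotype_site(25, 100, HOMOLOGY, 0.01)
        assert call.theta_map == 0.25

    def test_zero_alt_is_ref_and_zero_depth_is_no_call(self):
        assert pm.genotype_site(0, 100).map_hypothesis == "ref"
        nc = pm.genotype_site(0, 0)
        assert nc.no_call and nc.map_hypothesis == "no_call"

    def test_posteriors_normalised_and_prior_scale_invariant(self):
        call = pm.genotype_site(30, 100, HOMOLOGY)
        assert sum(call.posterior.values()) == pytest.approx(1.0, abs=1e-9)
        pri = {"ref": 5.0, "het_one_locus": 5.0,
               "hom_one_locus_or_het_both": 5.0,
               "three_copies": 0.05, "all_copies": 0.05}
        call2 = pm.genotype_site(30, 100, HOMOLOGY, prior=pri)
        assert call2.map_hypothesis == call.map_hypothesis
        for k in call.posterior:
            assert call2.posterior[k] == pytest.approx(call.posterior[k])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 200), st.integers(0, 199))
    def test_monotonicity_in_alt_count(self, depth, alt):
        alt = min(alt, depth - 1)
        lo = pm.genotype_site(alt, depth, HOMOLOGY).theta_map
        hi = pm.genotype_site(alt + 1, depth, HOMOLOGY).theta_map
        assert hi >= lo

    def test_parameter_recovery_accuracy(self):
        """>=99% class recovery at depth 100, eps 0.01, 500 sites per theta."""
        rng = np.random.default_rng(2024)
        eps = 0.01
        for theta in (0.0, 0.25, 0.5):
            p = theta * (1 - eps) + (1 - theta) * eps / 3
            alts = rng.binomial(100, p, size=500)
            correct = sum(
                pm.genotype_site(int(a), 100, HOMOLOGY, eps).theta_map == theta
                for a in alts)
            assert correct / 500 >= 0.99, theta

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pm.genotype_site(5, 3)
        with pytest.raises(ValueError):
            pm.genotype_site(1, 10, HOMOLOGY, epsilon=0.5)


class TestScanAndLocus:
    def test_null_sample_yields_no_candidates(self, small_ref, small_hmap):
        haps = pm.simulate_sample(small_ref, pm.SampleTruth("null"))
        res = short_read_stage(small_ref, small_hmap, haps, coverage=60,
                               seed=31, sub_error=0.0, call_cnv=False)
        assert res.site_calls == []

    def test_planted_variants_recovered_without_psv_false_positives(
            self, default_ref, default_hmap):
        """Six planted events (SNVs and small indels) -> six candidates."""
        ref = default_ref
        events = []
        expected = []
        for exon, hapset, kind in [(5, (1,), "snv"), (6, (1, 2), "snv"),
                                   (8, (1,), "snv"), (9, (2,), "snv"),
                                   (5, (2,), "del"), (9, (1,), "ins")]:
            pool = nonpsv_positions(ref, exon)
            pos = pool[500 if kind == "snv" else 300]
            while any(abs(pos - p) < 40 for p, _ in expected):
                pos += 53
            rb = ref.gene_seq[pos - 1]
            if kind == "snv":
                for h in hapset:
                    events.append((GENE, h, pos, rb, alt_base(rb), "snv"))
            elif kind == "del":
                for h in hapset:
                    events.append((GENE, h, pos, ref.gene_seq[pos - 1 : pos + 2],
                                   "", "del"))
            else:
                for h in hapset:
                    events.append((GENE, h, pos, rb, "TTAG", "ins"))
            expected.append((pos, kind))
        truth = pm.SampleTruth("six", small_variants=events)
        haps = pm.simulate_sample(ref, truth)
        res = short_read_stage(ref, default_hmap, haps, coverage=100, seed=32,
                               sub_error=0.0, call_cnv=False)
        called = {(c.pos, c.kind) for c in res.site_calls}
        assert called == set(expected)

    def test_candidate_threshold_catches_quarter_fraction_sites(self):
        assert candidate_sensitivity(0.25, 100, 0.12) >= 0.99

    def test_locus_assignment_from_full_simulation(self, default_ref,
                                                   default_hmap, snv_sample,
                                                   snv_sample_sr):
        """Het gene SNVs vote gene; pseudogene variants are excluded."""
        pos_het = snv_sample["het"][0]
        call = next(c for c in snv_sample_sr.site_calls if c.pos == pos_het)
        assert call.locus_assignment == "gene"
        assert call.locus_posterior > 0.99

    def test_pseudogene_only_variant_assigned_pseudo(self, default_ref,
                                                     default_hmap):
        # the family-16 pattern: a dup-like variant present only in the
        # pseudogene must not enter the gene's diagnostic list
        ref = default_ref
        ppos = ref.gene_to_pseudo(nonpsv_positions(ref, 6)[700])
        rb = ref.pseudo_seq[ppos - 1]
        truth = pm.SampleTruth("f16", small_variants=[
            (PSEUDO, 1, ppos, rb, alt_base(rb), "snv")])
        haps = pm.simulate_sample(ref, truth)
        res = short_read_stage(ref, default_hmap, haps, coverage=100, seed=33,
                               sub_error=0.0, call_cnv=False)
        gpos = ref.pseudo_to_gene(ppos)
        call = next(c for c in res.site_calls if c.pos == gpos)
        assert call.locus_assignment == "pseudo"

    def test_no_informative_reads_is_ambiguous(self, default_hmap):
        site = pm.SiteCall(pos=10, ref_allele="A", alt_allele="T", alt_count=5,
                           depth=20, region_type=HOMOLOGY)
        out = pm.assign_locus(site, [], default_hmap)
        assert out.locus_assignment == "ambiguous"
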