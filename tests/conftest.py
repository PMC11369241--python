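"""Shared fixtures: toy references and end-to-end simulated samples.

Expensive simulate-map rounds are session-scoped so module tests and the
acceptance suite reuse them.
"""

from __future__ import annotations

import pytest

import paramask as pm
from paramask.reference import GENE
from paramask.workflow import (
    long_read_stage,
    masked_reference,
    short_read_stage,
)


def alt_base(b: str) -> str:
    return "ACGT"[("ACGT".index(b) + 1) % 4]


def nonpsv_positions(ref, exon_index: int, skip: int = 50):
    """Positions inside a given exon that are not PSVs."""
    psv = {p.gene_pos for p in ref.psv_catalog}
    s, e = ref.gene_exons[exon_index - 1]
    return [p for p in range(s + skip, e - skip) if p not in psv]


@pytest.fixture(scope="session")
def small_ref():
    return pm.make_paralog_reference(
        n_exons=10, dup_first=2, dup_last=8, exon_len=200, intron_len=300,
        identity=0.98, seed=1,
    )


@pytest.fixture(scope="session")
def small_hmap(small_ref):
    return pm.derive_homology_map(small_ref.gene_seq, small_ref.pseudo_seq)


@pytest.fixture(scope="session")
def default_ref():
    return pm.make_paralog_reference(seed=3)


@pytest.fixture(scope="session")
def default_hmap(default_ref):
    return pm.derive_homology_map(default_ref.gene_seq, default_ref.pseudo_seq)


@pytest.fixture(scope="session")
def default_masked(default_ref):
    return masked_reference(default_ref)


@pytest.fixture(scope="session")
def snv_sample(default_ref):
    """Truth with one het and one hom gene SNV in homology exons."""
    ref = default_ref
    pos_het = nonpsv_positions(ref, 6)[100]
    pos_hom = nonpsv_positions(ref, 8)[100]
    rb_het, rb_hom = ref.gene_seq[pos_het - 1], ref.gene_seq[pos_hom - 1]
    truth = pm.SampleTruth(
        "snv_sample",
        small_variants=[
            (GENE, 1, pos_het, rb_het, alt_base(rb_het), "snv"),
            (GENE, 1, pos_hom, rb_hom, alt_base(rb_hom), "snv"),
            (GENE, 2, pos_hom, rb_hom, alt_base(rb_hom), "snv"),
        ],
    )
    return {
        "truth": truth,
        "het": (pos_het, rb_het, alt_base(rb_het)),
        "hom": (pos_hom, rb_hom, alt_base(rb_hom)),
    }


@pytest.fixture(scope="session")
def snv_sample_sr(default_ref, default_hmap, snv_sample):
    """Full masked short-read round at 100x over the SNV sample."""
    haps = pm.simulate_sample(default_ref, snv_sample["truth"])
    return short_read_stage(default_ref, default_hmap, haps, coverage=100,
                            seed=101, call_cnv=False)


@pytest.fixture(scope="session")
def family11_deletion(default_ref):
    """Het 1678-bp single-exon gene deletion (reported event size)."""
    ref = default_ref
    s, e = ref.gene_exons[6]
    center = (s + e) // 2
    dstart, dend = center - 839, center + 838
    truth = pm.SampleTruth("family11", exon_deletions=[(GENE, 1, (dstart, dend))])
    return {"truth": truth, "interval": (dstart, dend), "length": 1678,
            "exon_index": 7}


@pytest.fixture(scope="session")
def family11_lr(default_ref, default_hmap, family11_deletion):
    haps = pm.simulate_sample(default_ref, family11_deletion["truth"])
    return long_read_stage(default_ref, default_hmap, haps, coverage=30, seed=11)
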