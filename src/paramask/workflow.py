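"""Convenience orchestration of the pipeline stages.

These helpers wire the modules together the way the CLI, the examples and
the acceptance studies use them; every step remains available separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cnv import CopyNumberCall, DepthProfile, attribute_deleted_locus, call_combined_cn, depth_profile
from .genotyper import SiteCall, assign_locus, scan_candidates
from .homology import HomologyMap, derive_homology_map
from .longread import ReadBin, SVCall, bin_reads, detect_deletions
from .mapper import MappingResult, map_reads
from .masking import MaskSpec, mask_sequences
from .pileup import PileupTable, pileup
from .reference import ParalogReference, SampleTruth, simulate_sample
from .simulate import ReadSet, simulate_long_reads, simulate_short_reads


def masked_reference(ref: ParalogReference) -> dict[str, str]:
    """Single-contig reference with the pseudogene interval hard-masked."""
    return mask_sequences(
        {ref.contig_name: ref.contig_seq()}, MaskSpec([ref.mask_interval()])
    )


def unique_intervals(ref: ParalogReference) -> list[tuple[int, int]]:
    """Gene intervals outside the homology block (pseudogene has no copy)."""
    out = []
    if ref.hom_start > 1:
        out.append((1, ref.hom_start - 1))
    if ref.hom_end < ref.gene_len:
        out.append((ref.hom_end + 1, ref.gene_len))
    return out


@dataclass
class ShortReadResult:
    reads: ReadSet
    mapping: MappingResult
    table: PileupTable
    site_calls: list[SiteCall] = field(default_factory=list)
    profile: DepthProfile | None = None
    cnv_calls: list[CopyNumberCall] = field(default_factory=list)


def short_read_stage(
    ref: ParalogReference,
    hmap: HomologyMap,
    haplotypes: dict[tuple[str, int], str],
    coverage: float = 100.0,
    seed: int = 0,
    epsilon: float = 0.01,
    call_cnv: bool = True,
    overdispersion: float | None = None,
    **sim_kwargs,
) -> ShortReadResult:
    """Simulate, map, pile up, genotype and (optionally) call exon CNVs."""
    masked = masked_reference(ref)
    reads = simulate_short_reads(haplotypes, coverage=coverage, seed=seed,
                                 **sim_kwargs)
    mapping = map_reads(reads, masked)
    table = pileup(mapping.alignments, masked)
    calls = scan_candidates(table, masked, hmap, gene_len=ref.gene_len,
                            epsilon=epsilon)
    for c in calls:
        assign_locus(c, mapping.alignments, hmap)
    result = ShortReadResult(reads, mapping, table, calls)
    if call_cnv:
        result.profile = depth_profile(mapping.alignments, ref.gene_exons,
                                       hmap, contig_len=ref.gene_len)
        kwargs = {} if overdispersion is None else {"overdispersion": overdispersion}
        result.cnv_calls = call_combined_cn(result.profile, **kwargs)
        for c in result.cnv_calls:
            if c.called:
                attribute_deleted_locus(c, table, hmap)
    return result


@dataclass
class LongReadResult:
    reads: ReadSet
    mapping: MappingResult
    bins: dict[str, ReadBin]
    sv_calls: list[SVCall] = field(default_factory=list)
    masked: dict[str, str] = field(default_factory=dict)


def long_read_stage(
    ref: ParalogReference,
    hmap: HomologyMap,
    haplotypes: dict[tuple[str, int], str],
    coverage: float = 30.0,
    seed: int = 0,
    q: float = 0.05,
    min_sv_len: int = 50,
    **sim_kwargs,
) -> LongReadResult:
    """Simulate long reads, map, bin by PSVs and detect deletions."""
    masked = masked_reference(ref)
    reads = simulate_long_reads(haplotypes, coverage=coverage, seed=seed,
                                **sim_kwargs)
    mapping = map_reads(reads, masked)
    bins = bin_reads(mapping.alignments, hmap, q=q,
                     unique_intervals=unique_intervals(ref))
    svs = detect_deletions(mapping.alignments, min_sv_len=min_sv_len, bins=bins)
    return LongReadResult(reads, mapping, bins, svs, masked)


def simulate_and_derive(ref: ParalogReference, truth: SampleTruth):
    """Sample haplotypes plus a caller-side homology map (no generator truth)."""
    haps = simulate_sample(ref, truth)
    hmap = derive_homology_map(ref.gene_seq, ref.pseudo_seq)
    return haps, hmap
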