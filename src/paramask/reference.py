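"""Toy gene/pseudogene reference pair and diploid sample truths.

The geometry emulated here is a gene whose internal exon block has been
duplicated into a pseudogene at high (~98%) sequence identity.  All
positions where the two copies differ are paralogous sequence variants
(PSVs); everything downstream (masking, allele-balance genotyping,
read binning) keys off those fixed differences.

Coordinates are 1-based inclusive for variants and exon intervals
(VCF convention); BED output is 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = np.array(list("ACGT"))
GENE = "gene"
PSEUDO = "pseudo"
DEFAULT_SPACER = 500


@dataclass(frozen=True)
class PSV:
    """A fixed sequence difference between the gene and pseudogene copies."""

    gene_pos: int  # 1-based position on the gene
    gene_base: str
    pseudo_base: str

    def __post_init__(self) -> None:
        if self.gene_base == self.pseudo_base:
            raise ValueError("PSV bases must differ between the two loci")


@dataclass
class ParalogReference:
    """Two linked loci: a gene and the pseudogene copy of its internal exons.

    ``pseudo_seq`` is, by construction, the gene's homology interval with
    exactly the substitutions in ``psv_catalog`` applied.
    """

    gene_seq: str
    pseudo_seq: str
    gene_exons: list[tuple[int, int]]  # 1-based inclusive
    duplicated_exon_range: tuple[int, int]  # 1-based exon indices
    homology_interval_gene: tuple[int, int]  # 1-based inclusive on gene
    psv_catalog: list[PSV]
    identity: float
    spacer: int = DEFAULT_SPACER
    seed: int | None = None

    # -- geometry helpers -------------------------------------------------

    @property
    def gene_len(self) -> int:
        return len(self.gene_seq)

    @property
    def pseudo_len(self) -> int:
        return len(self.pseudo_seq)

    @property
    def hom_start(self) -> int:
        return self.homology_interval_gene[0]

    @property
    def hom_end(self) -> int:
        return self.homology_interval_gene[1]

    def gene_to_pseudo(self, pos: int) -> int:
        """Project a gene position inside the homology interval onto the pseudogene."""
        if not (self.hom_start <= pos <= self.hom_end):
            raise ValueError(f"position {pos} outside homology interval")
        return pos - self.hom_start + 1

    def pseudo_to_gene(self, pos: int) -> int:
        if not (1 <= pos <= self.pseudo_len):
            raise ValueError(f"position {pos} outside pseudogene")
        return pos + self.hom_start - 1

    def unique_exon_indices(self) -> list[int]:
        lo, hi = self.duplicated_exon_range
        return [i for i in range(1, len(self.gene_exons) + 1) if not lo <= i <= hi]

    def exon_region_type(self, exon_index: int) -> str:
        lo, hi = self.duplicated_exon_range
        return "homology" if lo <= exon_index <= hi else "unique"

    # -- single-contig layout ---------------------------------------------

    @property
    def contig_name(self) -> str:
        return "chrT"

    @property
    def pseudo_offset(self) -> int:
        """0-based offset of the pseudogene on the concatenated contig."""
        return self.gene_len + self.spacer

    def contig_seq(self) -> str:
        """Gene + N spacer + pseudogene on one contig, gene coordinates preserved."""
        return self.gene_seq + "N" * self.spacer + self.pseudo_seq

    def mask_interval(self) -> tuple[str, int, int]:
        """BED-convention interval covering the pseudogene on the contig."""
        return (self.contig_name, self.pseudo_offset, self.pseudo_offset + self.pseudo_len)

    # -- IO ----------------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA (single contig), mask/exon BED, PSV TSV and offset sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fasta",
            "mask_bed": outdir / "mask.bed",
            "exons_bed": outdir / "exons.bed",
            "psvs_tsv": outdir / "psvs.tsv",
            "offsets_json": outdir / "offsets.json",
        }
        seq = self.contig_seq()
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{self.contig_name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        contig, s, e = self.mask_interval()
        paths["mask_bed"].write_text(f"{contig}\t{s}\t{e}\n")
        with open(paths["exons_bed"], "w") as fh:
            for i, (s1, e1) in enumerate(self.gene_exons, 1):
                fh.write(f"{self.contig_name}\t{s1 - 1}\t{e1}\texon{i}\n")
        with open(paths["psvs_tsv"], "w") as fh:
            fh.write("gene_pos\tgene_base\tpseudo_base\n")
            for p in self.psv_catalog:
                fh.write(f"{p.gene_pos}\t{p.gene_base}\t{p.pseudo_base}\n")
        paths["offsets_json"].write_text(
            json.dumps(
                {
                    "contig": self.contig_name,
                    "gene": [0, self.gene_len],
                    "pseudo": [self.pseudo_offset, self.pseudo_offset + self.pseudo_len],
                    "homology_interval_gene": list(self.homology_interval_gene),
                },
                indent=2,
            )
        )
        return paths


@dataclass
class SampleTruth:
    """Diploid genotype specification consumed by the simulator.

    ``small_variants`` entries are ``(locus, haplotype, pos, ref, alt, kind)``
    with kind in {snv, ins, del}; positions are 1-based on the named locus.
    For ``ins`` the alt string is inserted after ``pos``; for ``del`` the
    ``ref`` string starting at ``pos`` is removed.  ``exon_deletions``
    entries are ``(locus, haplotype, (start, end))``, 1-based inclusive.
    """

    sample_id: str
    small_variants: list[tuple] = field(default_factory=list)
    exon_deletions: list[tuple] = field(default_factory=list)
    seed: int = 0

    def validate(self, ref: ParalogReference) -> None:
        seen = set()
        for locus, hap, pos, ref_allele, alt, kind in self.small_variants:
            if locus not in (GENE, PSEUDO) or hap not in (1, 2):
                raise ValueError(f"bad locus/haplotype: {locus}/{hap}")
            if kind not in ("snv", "ins", "del"):
                raise ValueError(f"unknown variant kind {kind!r}")
            key = (locus, hap, pos)
            if key in seen:
                raise ValueError(f"duplicate event at {key}")
            seen.add(key)
            seq = ref.gene_seq if locus == GENE else ref.pseudo_seq
            end = pos + (len(ref_allele) - 1 if kind == "del" else 0)
            if not (1 <= pos and end <= len(seq)):
                raise ValueError(f"position {pos} invalid on {locus}")
            if seq[pos - 1 : pos - 1 + len(ref_allele)] != ref_allele:
                raise ValueError(f"ref allele mismatch at {locus}:{pos}")
        for locus, hap, (dstart, dend) in self.exon_deletions:
            seq = ref.gene_seq if locus == GENE else ref.pseudo_seq
            if not (1 <= dstart <= dend <= len(seq)):
                raise ValueError(f"deletion {dstart}-{dend} outside {locus}")
            for vlocus, vhap, pos, ref_allele, alt, kind in self.small_variants:
                if (vlocus, vhap) == (locus, hap) and dstart <= pos <= dend:
                    raise ValueError(
                        f"deletion {dstart}-{dend} overlaps small variant at {pos}"
                    )


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=n))


def apply_psvs(gene_slice: str, psvs: list[PSV], hom_start: int) -> str:
    """Apply a PSV catalog to the gene's homology slice; yields the pseudogene."""
    seq = list(gene_slice)
    for p in psvs:
        idx = p.gene_pos - hom_start
        if seq[idx] != p.gene_base:
            raise ValueError(f"catalog inconsistent with gene at {p.gene_pos}")
        seq[idx] = p.pseudo_base
    return "".join(seq)


def make_paralog_reference(
    n_exons: int = 12,
    dup_first: int = 4,
    dup_last: int = 10,
    exon_len: int = 1250,
    intron_len: int = 1200,
    identity: float = 0.98,
    seed: int = 0,
    min_psv_per_exon: bool = True,
    spacer: int = DEFAULT_SPACER,
) -> ParalogReference:
    """Generate a gene plus a pseudogene copy of exons ``dup_first..dup_last``.

    PSVs are placed uniformly at random over the duplicated block at density
    ``1 - identity``; by default every duplicated exon is guaranteed at least
    one PSV so that each exon stays locus-resolvable.  Deterministic for a
    fixed seed.
    """
    if not (1 <= dup_first <= dup_last <= n_exons):
        raise ValueError("require 1 <= dup_first <= dup_last <= n_exons")
    if not (0.5 <= identity < 1.0):
        raise ValueError("identity must be in [0.5, 1.0)")
    rng = np.random.default_rng(seed)

    gene_len = n_exons * exon_len + (n_exons - 1) * intron_len
    gene_seq = _random_dna(gene_len, rng)
    exons = []
    for i in range(n_exons):
        start = i * (exon_len + intron_len) + 1
        exons.append((start, start + exon_len - 1))

    hom_start = exons[dup_first - 1][0]
    hom_end = exons[dup_last - 1][1]
    block_len = hom_end - hom_start + 1

    n_psv = int(round((1.0 - identity) * block_len))
    if n_psv == 0 and block_len > 0:
        raise ValueError(
            "identity too high: zero PSVs over a non-empty homology block"
        )
    positions = set(
        int(p) for p in rng.choice(block_len, size=n_psv, replace=False) + hom_start
    )
    if min_psv_per_exon:
        for i in range(dup_first, dup_last + 1):
            s, e = exons[i - 1]
            if not any(s <= p <= e for p in positions):
                positions.add(int(rng.integers(s, e + 1)))

    catalog = []
    for pos in sorted(positions):
        gene_base = gene_seq[pos - 1]
        alts = [b for b in "ACGT" if b != gene_base]
        catalog.append(PSV(pos, gene_base, str(rng.choice(alts))))

    pseudo_seq = apply_psvs(gene_seq[hom_start - 1 : hom_end], catalog, hom_start)
    return ParalogReference(
        gene_seq=gene_seq,
        pseudo_seq=pseudo_seq,
        gene_exons=exons,
        duplicated_exon_range=(dup_first, dup_last),
        homology_interval_gene=(hom_start, hom_end),
        psv_catalog=catalog,
        identity=identity,
        spacer=spacer,
        seed=seed,
    )


def simulate_sample(ref: ParalogReference, spec: SampleTruth) -> dict[tuple[str, int], str]:
    """Apply a sample's events to the reference, returning four haplotype sequences.

    Keys are ``(locus, haplotype)`` for locus in {gene, pseudo}, haplotype in {1, 2}.
    """
    spec.validate(ref)
    haps: dict[tuple[str, int], str] = {}
    for locus in (GENE, PSEUDO):
        base = ref.gene_seq if locus == GENE else ref.pseudo_seq
        for hap in (1, 2):
            events: list[tuple[int, int, str]] = []  # (start, end_excl_on_ref, replacement)
            for vlocus, vhap, pos, ref_allele, alt, kind in spec.small_variants:
                if (vlocus, vhap) != (locus, hap):
                    continue
                if kind == "snv":
                    events.append((pos, pos + 1, alt))
                elif kind == "del":
                    events.append((pos, pos + len(ref_allele), ""))
                elif kind == "ins":
                    events.append((pos + 1, pos + 1, alt))
            for vlocus, vhap, (dstart, dend) in spec.exon_deletions:
                if (vlocus, vhap) == (locus, hap):
                    events.append((dstart, dend + 1, ""))
            seq = base
            for start, end, repl in sorted(events, reverse=True):
                seq = seq[: start - 1] + repl + seq[end - 1 :]
            haps[(locus, hap)] = seq
    return haps
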