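"""Derive the homology map and PSV catalog from the unmasked reference pair.

The map is recovered by pairwise alignment of the pseudogene against the
gene, independently of the simulator's internal truth, so that downstream
callers never peek at generator state.  Mismatch columns become PSVs; gap
runs split the alignment into collinear blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .reference import PSV

HOMOLOGY = "homology"
UNIQUE = "unique"


@dataclass
class HomologyBlock:
    gene_interval: tuple[int, int]  # 1-based inclusive on gene
    pseudo_interval: tuple[int, int]  # 1-based inclusive on pseudogene
    orientation: str = "+"


@dataclass
class HomologyMap:
    blocks: list[HomologyBlock]
    psvs: list[PSV]
    identity_observed: float
    aligned_length: int = 0
    _psv_by_pos: dict[int, PSV] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._psv_by_pos = {p.gene_pos: p for p in self.psvs}

    def psv_at(self, gene_pos: int) -> PSV | None:
        return self._psv_by_pos.get(gene_pos)

    def gene_interval(self) -> tuple[int, int]:
        return (min(b.gene_interval[0] for b in self.blocks),
                max(b.gene_interval[1] for b in self.blocks))

    def psvs_in(self, start: int, end: int) -> list[PSV]:
        """PSVs with gene position in [start, end] (1-based inclusive)."""
        return [p for p in self.psvs if start <= p.gene_pos <= end]

    def write_psv_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("gene_pos\tgene_base\tpseudo_base\n")
            for p in self.psvs:
                fh.write(f"{p.gene_pos}\t{p.gene_base}\t{p.pseudo_base}\n")
        return path

    def write_blocks_bed(self, path: str | Path, contig: str = "chrT") -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for b in self.blocks:
                s, e = b.gene_interval
                fh.write(f"{contig}\t{s - 1}\t{e}\thomology_block\n")
        return path


def derive_homology_map(gene_seq: str, pseudo_seq: str, min_block: int = 30) -> HomologyMap:
    """Align the pseudogene into the gene and extract blocks + PSVs.

    Uses a banded edit-distance alignment (infix mode: the pseudogene is a
    near-exact copy of an internal slice of the gene).  At the substitution-
    dominated ~98% identity this problem lives at, the recovered PSV set is
    insensitive to the scoring scheme.  Pairs below 50% identity are
    rejected as not a paralog pair.
    """
    if not gene_seq or not pseudo_seq:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(pseudo_seq, gene_seq, task="path", mode="HW")
    if res["editDistance"] < 0 or not res["locations"]:
        raise ValueError("sequences do not align: not a paralog pair")
    # random DNA reaches ~0.54 column identity under an optimised alignment,
    # so relatedness is gated on normalised edit distance instead
    if res["editDistance"] / len(pseudo_seq) > 0.45:
        raise ValueError(
            "normalised edit distance "
            f"{res['editDistance'] / len(pseudo_seq):.2f} > 0.45: "
            "not a paralog pair")
    start0, end0 = res["locations"][0]  # 0-based inclusive on gene

    if end0 - start0 + 1 == len(pseudo_seq):
        # substitution-only divergence: column-wise comparison is exact and
        # avoids optimal-path ambiguity (a mismatch pair can tie with D+I)
        psvs = [
            PSV(start0 + 1 + j, gene_seq[start0 + j], pseudo_seq[j])
            for j in range(len(pseudo_seq))
            if gene_seq[start0 + j] != pseudo_seq[j]
        ]
        identity = 1.0 - len(psvs) / len(pseudo_seq)
        if identity < 0.5:
            raise ValueError(f"identity {identity:.2f} < 0.5: not a paralog pair")
        block = HomologyBlock((start0 + 1, end0 + 1), (1, len(pseudo_seq)))
        return HomologyMap(blocks=[block], psvs=psvs, identity_observed=identity,
                           aligned_length=len(pseudo_seq))

    # walk the alignment path
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""

    blocks: list[HomologyBlock] = []
    psvs: list[PSV] = []
    gpos, ppos = start0 + 1, 1  # 1-based cursors
    blk_g, blk_p = gpos, ppos
    aligned = 0
    mismatches = 0

    def close_block(gend: int, pend: int):
        if gend >= blk_g and (gend - blk_g + 1) >= min_block:
            blocks.append(HomologyBlock((blk_g, gend), (blk_p, pend)))

    for ch, ln in ops:
        if ch in ("=", "X"):
            if ch == "X":
                for j in range(ln):
                    psvs.append(PSV(gpos + j, gene_seq[gpos + j - 1],
                                    pseudo_seq[ppos + j - 1]))
                mismatches += ln
            aligned += ln
            gpos += ln
            ppos += ln
        elif ch == "D":  # gap in pseudo: gene bases skipped
            close_block(gpos - 1, ppos - 1)
            gpos += ln
            blk_g, blk_p = gpos, ppos
        elif ch == "I":  # gap in gene: pseudo bases skipped
            close_block(gpos - 1, ppos - 1)
            ppos += ln
            blk_g, blk_p = gpos, ppos
    close_block(gpos - 1, ppos - 1)

    if aligned == 0:
        raise ValueError("no aligned columns: not a paralog pair")
    identity = 1.0 - len(psvs) / aligned
    if identity < 0.5:
        raise ValueError(f"identity {identity:.2f} < 0.5: not a paralog pair")
    return HomologyMap(blocks=blocks, psvs=psvs, identity_observed=identity,
                       aligned_length=aligned)


def classify_region(pos_on_gene: int, hmap: HomologyMap, gene_len: int | None = None) -> str:
    """'homology' iff the gene position falls inside an aligned block."""
    if pos_on_gene < 1 or (gene_len is not None and pos_on_gene > gene_len):
        raise ValueError(f"position {pos_on_gene} out of range")
    for b in hmap.blocks:
        if b.gene_interval[0] <= pos_on_gene <= b.gene_interval[1]:
            return HOMOLOGY
    return UNIQUE


def project_pseudo_to_gene(pos_on_pseudo: int, hmap: HomologyMap) -> int | None:
    """Project a pseudogene position through the map (None when unaligned)."""
    for b in hmap.blocks:
        ps, pe = b.pseudo_interval
        if ps <= pos_on_pseudo <= pe:
            return b.gene_interval[0] + (pos_on_pseudo - ps)
    return None
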