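"""Per-position base counts from masked alignments.

The pileup is the readout that makes the collapsed allele balances visible:
a heterozygous gene variant in the homology region surfaces at ~25% of
reads, a homozygous one at ~50%, and PSV columns sit near 50% pseudogene
base in the null state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mapper import Alignment

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"
_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_IDX.items():
    _LUT[ord(_b)] = _i


@dataclass
class PileupColumn:
    contig: str
    pos: int  # 1-based
    counts: dict[str, int]
    deletion_count: int
    insertion_events: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.deletion_count

    @property
    def insertion_count(self) -> int:
        return sum(self.insertion_events.values())

    def fraction(self, base: str) -> float:
        d = self.depth
        return self.counts.get(base, 0) / d if d else 0.0


class PileupTable:
    """Dense per-contig count arrays with column access.

    ``counts[contig]`` has shape (L+1, 4) indexed by 1-based position;
    deletions in a read contribute to ``dels`` at every deleted position.
    """

    def __init__(self, lengths: dict[str, int]):
        self.lengths = lengths
        self.counts = {c: np.zeros((L + 2, 4), dtype=np.int32) for c, L in lengths.items()}
        self.dels = {c: np.zeros(L + 2, dtype=np.int32) for c, L in lengths.items()}
        self.ins: dict[str, dict[int, dict[str, int]]] = {c: {} for c in lengths}

    def add_alignment(self, aln: Alignment) -> None:
        cnt = self.counts[aln.contig]
        dels = self.dels[aln.contig]
        ins = self.ins[aln.contig]
        rpos, qpos = aln.pos, 0
        for op, ln in aln.cigar:
            if op == "M":
                idx = np.frombuffer(aln.seq[qpos : qpos + ln].encode(), dtype=np.uint8)
                bi = _LUT[idx]
                valid = bi >= 0
                np.add.at(cnt, (np.arange(rpos, rpos + ln)[valid], bi[valid]), 1)
                rpos += ln
                qpos += ln
            elif op == "D":
                dels[rpos : rpos + ln] += 1
                rpos += ln
            elif op == "I":
                seq = aln.seq[qpos : qpos + ln]
                col = ins.setdefault(rpos - 1, {})
                col[seq] = col.get(seq, 0) + 1
                qpos += ln
            elif op == "S":
                qpos += ln

    def column(self, contig: str, pos: int) -> PileupColumn:
        cnt = self.counts[contig][pos]
        return PileupColumn(
            contig=contig,
            pos=pos,
            counts={b: int(cnt[i]) for b, i in _BASE_IDX.items()},
            deletion_count=int(self.dels[contig][pos]),
            insertion_events=dict(self.ins[contig].get(pos, {})),
        )

    def columns(self, contig: str, start: int = 1, end: int | None = None):
        end = end if end is not None else self.lengths[contig]
        for pos in range(start, end + 1):
            yield self.column(contig, pos)

    def depth_array(self, contig: str) -> np.ndarray:
        """Depth per 1-based position (index 0 unused)."""
        return self.counts[contig].sum(axis=1) + self.dels[contig]


def pileup(
    alignments: list[Alignment] | "object",
    ref_seqs: dict[str, str],
    region: tuple[str, int, int] | None = None,
) -> PileupTable:
    """Build a pileup table from alignments over the masked reference."""
    table = PileupTable({c: len(s) for c, s in ref_seqs.items()})
    for aln in alignments:
        if region and aln.contig != region[0]:
            continue
        table.add_alignment(aln)
    return table


def write_pileup_tsv(table: PileupTable, contig: str, path: str | Path,
                     start: int = 1, end: int | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig\tpos\tdepth\tA\tC\tG\tT\tdel\tins\n")
        for col in table.columns(contig, start, end):
            fh.write(
                f"{col.contig}\t{col.pos}\t{col.depth}\t"
                f"{col.counts['A']}\t{col.counts['C']}\t{col.counts['G']}\t"
                f"{col.counts['T']}\t{col.deletion_count}\t{col.insertion_count}\n"
            )
    return path
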