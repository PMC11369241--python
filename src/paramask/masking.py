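"""Hard-masking of reference intervals (maskfasta semantics).

Bases inside each BED interval are replaced by 'N'; sequence length and all
other bases are untouched.  Masking the pseudogene collapses all four
homologous alleles onto the gene during mapping, which is the manoeuvre the
whole pipeline is built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta


@dataclass
class MaskSpec:
    """BED-convention (0-based half-open) intervals to hard-mask."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskSpec":
        ivs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end = line.split("\t")[:3]
            ivs.append((contig, int(start), int(end)))
        return cls(ivs)

    @classmethod
    def from_one_based(cls, intervals: list[tuple[str, int, int]]) -> "MaskSpec":
        """Accept 1-based inclusive intervals (the convention of HGVS and
        most human-readable interval notation)."""
        return cls([(c, s - 1, e) for c, s, e in intervals])

    def merged(self) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        for contig, start, end in sorted(self.intervals):
            if start < 0 or end < start:
                raise ValueError(f"bad interval {contig}:{start}-{end}")
            if out and out[-1][0] == contig and start <= out[-1][2]:
                out[-1] = (contig, out[-1][1], max(out[-1][2], end))
            else:
                out.append((contig, start, end))
        return out


def mask_sequences(seqs: dict[str, str], mask: MaskSpec) -> dict[str, str]:
    """Apply the mask to in-memory sequences."""
    out = dict(seqs)
    for contig, start, end in mask.merged():
        if contig not in out:
            raise KeyError(f"contig {contig!r} not in reference")
        seq = out[contig]
        if end > len(seq):
            raise ValueError(
                f"interval {contig}:{start}-{end} beyond contig length {len(seq)}"
            )
        out[contig] = seq[:start] + "N" * (end - start) + seq[end:]
    return out


def mask_reference(ref_fasta: str | Path, mask: MaskSpec, out_fasta: str | Path) -> Path:
    """maskfasta: write a copy of ``ref_fasta`` with masked intervals as 'N'."""
    fa = Fasta(str(ref_fasta))
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    masked = mask_sequences(seqs, mask)
    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fh:
        for name, seq in masked.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return out_fasta


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}
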