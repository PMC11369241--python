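"""Read simulators: paired-end short reads and ONT-like long reads.

Reads carry a ``truth_origin`` (locus, haplotype, 1-based start on that
haplotype) used only for scoring simulations; no caller reads it.

Coverage conventions
--------------------
Short reads: ``coverage`` is the expected collapsed depth over the homology
block, where reads from all four haplotypes pile up after masking; each
haplotype is therefore sequenced at ``coverage / 4``.

Long reads: ``coverage`` is the per-locus diploid depth (each locus at
``coverage``, i.e. each haplotype at ``coverage / 2``), mirroring a targeted
long-read run quoted as "30x over the gene".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import BASES

SHORT_QUAL = chr(30 + 33)  # constant Q30
LONG_QUAL = chr(12 + 33)  # constant Q12


@dataclass
class Read:
    read_id: str
    sequence: str
    qualities: str
    mate_info: str | None  # "R1"/"R2" for paired reads, None for long reads
    truth_origin: tuple[str, int, int]  # (locus, haplotype, 1-based start)


@dataclass
class ReadSet:
    platform: str  # "short_paired" | "long"
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, prefix: str | Path) -> list[Path]:
        """Write FASTQ; paired sets go to ``<prefix>_R1/_R2.fastq``.

        Truth origins are not written (they are simulation metadata).
        """
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        if self.platform == "short_paired":
            paths = [Path(f"{prefix}_R1.fastq"), Path(f"{prefix}_R2.fastq")]
            handles = [open(p, "w") for p in paths]
            try:
                for r in self.reads:
                    fh = handles[0] if r.mate_info == "R1" else handles[1]
                    fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")
            finally:
                for fh in handles:
                    fh.close()
            return paths
        path = Path(f"{prefix}.fastq")
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")
        return [path]


def _add_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        alts = [b for b in "ACGT" if b != cur]
        arr[i] = rng.choice(alts).encode()
    return arr.tobytes().decode()


def _add_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Sprinkle 1-bp insertions/deletions at the given per-base rate."""
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # 1-bp deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append(str(rng.choice(BASES)))  # 1-bp insertion
    return "".join(out)


def _hap_weights(haplotypes: dict[tuple[str, int], str]) -> tuple[list, np.ndarray]:
    keys = sorted(haplotypes)
    lens = np.array([len(haplotypes[k]) for k in keys], dtype=float)
    return keys, lens / lens.sum()


def simulate_short_reads(
    haplotypes: dict[tuple[str, int], str],
    coverage: float = 100.0,
    read_len: int = 150,
    frag_min: int = 150,
    frag_max: int = 300,
    sub_error: float = 0.002,
    seed: int = 0,
) -> ReadSet:
    """Paired-end fragments sampled uniformly over the pooled haplotypes.

    Fragment lengths are uniform on [frag_min, frag_max]; each fragment
    yields two ``read_len`` reads from its ends (both written in reference
    orientation).  Substitution errors are i.i.d. at ``sub_error``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_max < frag_min or read_len <= 0:
        raise ValueError("bad fragment/read length parameters")
    rng = np.random.default_rng(seed)
    keys, weights = _hap_weights(haplotypes)
    total_len = sum(len(s) for s in haplotypes.values())
    n_frags = int(round(coverage / 4.0 * total_len / (2.0 * read_len)))

    rs = ReadSet(platform="short_paired")
    hap_choice = rng.choice(len(keys), size=n_frags, p=weights)
    for i in range(n_frags):
        locus, hap = keys[hap_choice[i]]
        seq = haplotypes[(locus, hap)]
        frag_len = int(rng.integers(frag_min, frag_max + 1))
        frag_len = min(frag_len, len(seq))
        start = int(rng.integers(0, len(seq) - frag_len + 1))  # 0-based
        frag = seq[start : start + frag_len]
        r1 = frag[:read_len]
        r2 = frag[max(0, frag_len - read_len) :]
        rid = f"frag{i}:{locus}:{hap}"
        rs.reads.append(
            Read(f"{rid}/1", _add_substitutions(r1, sub_error, rng),
                 SHORT_QUAL * len(r1), "R1", (locus, hap, start + 1))
        )
        r2_start = start + max(0, frag_len - read_len)
        rs.reads.append(
            Read(f"{rid}/2", _add_substitutions(r2, sub_error, rng),
                 SHORT_QUAL * len(r2), "R2", (locus, hap, r2_start + 1))
        )
    return rs


def simulate_long_reads(
    haplotypes: dict[tuple[str, int], str],
    coverage: float = 30.0,
    len_mean: float = 6000.0,
    len_sd: float = 2000.0,
    sub_error: float = 0.03,
    indel_error: float = 0.02,
    seed: int = 0,
) -> ReadSet:
    """Long reads with log-normal lengths and substitution + 1-bp indel errors.

    Reads sampled from a haplotype carrying a deletion are contiguous on that
    haplotype, so reads spanning the event contain the novel junction.
    """
    if coverage <= 0 or len_mean <= 0:
        raise ValueError("coverage and len_mean must be positive")
    rng = np.random.default_rng(seed)
    keys, weights = _hap_weights(haplotypes)
    total_len = sum(len(s) for s in haplotypes.values())
    n_reads = int(round(coverage / 2.0 * total_len / len_mean))

    # lognormal parametrised by the desired arithmetic mean/sd
    sigma2 = np.log(1.0 + (len_sd / len_mean) ** 2)
    mu = np.log(len_mean) - sigma2 / 2.0

    rs = ReadSet(platform="long")
    hap_choice = rng.choice(len(keys), size=n_reads, p=weights)
    for i in range(n_reads):
        locus, hap = keys[hap_choice[i]]
        seq = haplotypes[(locus, hap)]
        length = max(200, int(rng.lognormal(mu, np.sqrt(sigma2))))
        start = int(rng.integers(0, max(1, len(seq) - length + 1)))
        raw = seq[start : start + length]
        obs = _add_indels(_add_substitutions(raw, sub_error, rng), indel_error, rng)
        rs.reads.append(
            Read(f"long{i}:{locus}:{hap}", obs, LONG_QUAL * len(obs), None,
                 (locus, hap, start + 1))
        )
    return rs
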