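"""Long-read rescue: PSV binning, per-locus re-genotyping, deletion
detection and read-backed phasing.

Long reads span many PSVs, so each read can be assigned to gene or
pseudogene by a log-odds vote over the PSV bases it carries.  Restricting
genotyping to gene-binned reads undoes the masking collapse: a variant that
sat at ~50% alt in the masked short-read pileup resolves to ~100% alt if it
is truly homozygous in the gene — homozygosity confirmed without parents.
Alignment gaps (D ops, or split alignments flanking a gap) yield exon-scale
deletion calls with breakpoints, and co-spanned heterozygous sites are
phased by a greedy read-backed vote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median

from .homology import HomologyMap, classify_region
from .mapper import Alignment

BIN_THRESHOLD_NATS = 3.0
MIN_SUPPORT = 3
# breakpoint scatter between supporting reads: a 1-bp sequencing indel next
# to the junction shifts a read's apparent breakpoints by tens of bases, so
# clustering is generous and the reported breakpoints are cluster medians
CLUSTER_TOL = 60
MIN_UNIQUE_OVERLAP = 100


@dataclass
class ReadBin:
    read_id: str
    assigned_locus: str  # gene | pseudo | unassigned
    log_odds: float
    n_psv_informative: int


@dataclass
class SVCall:
    start: int  # 1-based inclusive breakpoints on the gene
    end: int
    length: int
    support: int
    locus: str
    supporting_reads: list[str] = field(default_factory=list)
    frame_consequence: str = "unknown"


@dataclass
class HaplotypeBlock:
    block_id: int
    assignments: dict[int, int]  # site pos -> haplotype (1 or 2)
    supporting_reads: int
    conflicting_reads: int


def bin_reads(
    alignments: list[Alignment],
    hmap: HomologyMap,
    q: float = 0.05,
    threshold_lo: float = BIN_THRESHOLD_NATS,
    unique_intervals: list[tuple[int, int]] | None = None,
) -> dict[str, ReadBin]:
    """Assign each read to gene or pseudogene by PSV voting.

    Votes are +log[(1-q)/q] per gene-base match and the negative per
    pseudogene-base match; bases that are neither are ignored (sequencing
    error).  Reads overlapping gene-unique sequence by at least
    ``MIN_UNIQUE_OVERLAP`` bases are gene by construction — no pseudogene
    copy of that sequence exists.
    """
    if not (0 < q < 0.3):
        raise ValueError("q must be in (0, 0.3)")
    w = math.log((1 - q) / q)
    bins: dict[str, ReadBin] = {}
    for aln in alignments:
        votes = 0
        total = 0.0
        for p in hmap.psvs_in(aln.pos, aln.end):
            rb = aln.read_base_at(p.gene_pos)
            if rb == p.gene_base:
                total += w
                votes += 1
            elif rb == p.pseudo_base:
                total -= w
                votes += 1
        unique_overlap = 0
        if unique_intervals:
            for s, e in unique_intervals:
                unique_overlap += max(0, min(aln.end, e) - max(aln.pos, s) + 1)
        if unique_overlap >= MIN_UNIQUE_OVERLAP:
            locus = "gene"
            total += w  # direct evidence on top of any PSV votes
        elif abs(total) >= threshold_lo:
            locus = "gene" if total > 0 else "pseudo"
        else:
            locus = "unassigned"
        bins[aln.read_id] = ReadBin(aln.read_id, locus, total, votes)
    return bins


def misassignment_bound(n_psv: int, q: float, threshold_lo: float = BIN_THRESHOLD_NATS) -> float:
    """Exact binomial tail: P(votes push a read past the threshold wrongly).

    A read truly from the gene is misassigned to the pseudogene when enough
    of its ``n_psv`` PSV bases flip that the net log-odds crosses
    ``-threshold_lo``; with per-base error q that needs f flips where
    (n - 2f) log[(1-q)/q] <= -threshold_lo.
    """
    from scipy.stats import binom as _binom

    w = math.log((1 - q) / q)
    f_min = math.ceil((n_psv + threshold_lo / w) / 2.0)
    return float(_binom.sf(f_min - 1, n_psv, q))


def allele_at_realigned(
    aln: Alignment,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    ref_seq: str,
    kind: str = "snv",
    window: int = 25,
) -> int | None:
    """Call a read's allele at a site by local realignment.

    CIGAR-walk base extraction is brittle next to 1-bp sequencing indels
    (the aligner may phase the indel either side of the site), so the read's
    slice over a +-window context is compared against the reference and the
    alternate haplotype context by edit distance.  Returns 0 (ref),
    1 (alt) or None (window not covered, or tie).
    """
    import edlib

    s = max(1, pos - window)
    e = min(len(ref_seq), pos + window + max(0, len(ref_allele) - 1))
    sub = aln.read_slice(s, e)
    if sub is None or len(sub) < window:
        return None
    ctx_ref = ref_seq[s - 1 : e]
    off = pos - s  # 0-based index of the site inside the context
    if kind == "snv":
        ctx_alt = ctx_ref[:off] + alt_allele + ctx_ref[off + 1 :]
    elif kind == "del":
        ctx_alt = ctx_ref[:off] + ctx_ref[off + len(ref_allele) :]
    elif kind == "ins":
        ctx_alt = ctx_ref[: off + 1] + alt_allele + ctx_ref[off + 1 :]
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    d_ref = edlib.align(sub, ctx_ref, mode="NW")["editDistance"]
    d_alt = edlib.align(sub, ctx_alt, mode="NW")["editDistance"]
    if d_ref == d_alt:
        return None
    return 1 if d_alt < d_ref else 0


def regenotype_per_locus(
    bins: dict[str, ReadBin],
    alignments: list[Alignment],
    pos: int,
    ref_allele: str,
    alt_allele: str,
    kind: str = "snv",
    locus: str = "gene",
    q: float = 0.05,
    min_reads: int = 10,
    ref_seq: str | None = None,
) -> dict:
    """Diploid genotype at a site using only reads binned to one locus.

    The collapse is undone, so theta returns to the ordinary {0, 0.5, 1}
    grid; a truly homozygous gene variant now shows ~100% alt among
    gene-binned reads.  When ``ref_seq`` is supplied, alleles are extracted
    by local realignment (robust next to read indels).  Returns a dict with
    genotype in {ref/ref, ref/alt, alt/alt, no_call}, counts and
    log-likelihoods.
    """
    alt = ref_n = 0
    for aln in alignments:
        b = bins.get(aln.read_id)
        if b is None or b.assigned_locus != locus:
            continue
        if not (aln.pos <= pos <= aln.end):
            continue
        if ref_seq is not None:
            a = allele_at_realigned(aln, pos, ref_allele, alt_allele, ref_seq, kind)
            if a == 1:
                alt += 1
            elif a == 0:
                ref_n += 1
            continue
        rb = aln.read_base_at(pos)
        if kind == "snv":
            if rb == alt_allele:
                alt += 1
            elif rb == ref_allele:
                ref_n += 1
        elif kind == "del":
            if rb == "-":
                alt += 1
            elif rb is not None:
                ref_n += 1
    depth = alt + ref_n
    if depth < min_reads:
        return {"genotype": "no_call", "alt": alt, "depth": depth,
                "reason": f"only {depth} {locus}-binned reads (< {min_reads})"}
    gt = genotype_diploid(alt, depth, q)
    gt.update({"alt": alt, "depth": depth})
    return gt


def genotype_diploid(alt: int, depth: int, q: float = 0.05) -> dict:
    """Binomial MAP over theta in {0, 0.5, 1} with error-rate folding."""
    from scipy.stats import binom as _binom

    thetas = {"ref/ref": q, "ref/alt": 0.5, "alt/alt": 1.0 - q}
    ll = {g: float(_binom.logpmf(alt, depth, p)) for g, p in thetas.items()}
    best = max(ll, key=ll.get)
    ordered = sorted(ll.values(), reverse=True)
    return {"genotype": best, "log_likelihood": ll,
            "confidence_nats": ordered[0] - ordered[1]}


def detect_deletions(
    alignments: list[Alignment],
    min_sv_len: int = 50,
    min_support: int = MIN_SUPPORT,
    cluster_tol: int = CLUSTER_TOL,
    bins: dict[str, ReadBin] | None = None,
) -> list[SVCall]:
    """Cluster large deletion signals from CIGARs and split alignments.

    Deletion ops >= ``min_sv_len`` are collected; additionally, two
    alignments of one read flanking a reference gap (split alignment) are
    merged into one deletion signal when the read intervals are contiguous
    within ``cluster_tol``.  Signals cluster by breakpoint proximity and a
    cluster is reported when supported by ``min_support`` reads, with median
    breakpoints and the bin-majority locus.
    """
    if min_sv_len <= 0 or min_support <= 0:
        raise ValueError("thresholds must be positive")
    signals: list[tuple[int, int, str]] = []  # (start, end, read_id)
    by_read: dict[str, list[Alignment]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, []).append(aln)
        rpos = aln.pos
        for op, ln in aln.cigar:
            if op == "M":
                rpos += ln
            elif op == "D":
                if ln >= min_sv_len:
                    signals.append((rpos, rpos + ln - 1, aln.read_id))
                rpos += ln
    # split alignments: same read, two pieces flanking a reference gap
    for rid, alns in by_read.items():
        if len(alns) < 2:
            continue
        alns = sorted(alns, key=lambda a: a.pos)
        for a, b in zip(alns, alns[1:]):
            gap = b.pos - a.end - 1
            if gap >= min_sv_len:
                # read-side contiguity: clipped tail of a ~ clipped head of b
                a_read_end = sum(ln for op, ln in a.cigar if op in ("M", "I", "S"))
                a_tail_clip = a.cigar[-1][1] if a.cigar[-1][0] == "S" else 0
                b_head_clip = b.cigar[0][1] if b.cigar[0][0] == "S" else 0
                if abs((a_read_end - a_tail_clip) - b_head_clip) <= cluster_tol:
                    signals.append((a.end + 1, b.pos - 1, rid))

    clusters: list[list[tuple[int, int, str]]] = []
    for s in sorted(signals):
        placed = False
        for cl in clusters:
            ms = median(x[0] for x in cl)
            me = median(x[1] for x in cl)
            if abs(s[0] - ms) <= cluster_tol and abs(s[1] - me) <= cluster_tol:
                cl.append(s)
                placed = True
                break
        if not placed:
            clusters.append([s])

    calls = []
    for cl in clusters:
        reads = sorted({x[2] for x in cl})
        if len(reads) < min_support:
            continue
        start = int(median(x[0] for x in cl))
        end = int(median(x[1] for x in cl))
        locus = "unassigned"
        if bins:
            votes = [bins[r].assigned_locus for r in reads if r in bins]
            votes = [v for v in votes if v != "unassigned"]
            if votes:
                g = votes.count("gene")
                locus = "gene" if g > len(votes) / 2 else "pseudo"
        calls.append(SVCall(start=start, end=end, length=end - start + 1,
                            support=len(reads), locus=locus,
                            supporting_reads=reads))
    calls.sort(key=lambda c: c.start)
    return calls


def phase_variants(
    alignments: list[Alignment],
    het_sites: list[tuple[int, str, str, str]],  # (pos, ref, alt, kind)
    min_reads: int = 3,
    vote_margin: float = 0.8,
    bins: dict[str, ReadBin] | None = None,
    locus: str = "gene",
    ref_seq: str | None = None,
) -> list[HaplotypeBlock]:
    """Greedy read-backed phasing of heterozygous sites.

    Sites are connected when co-covered by enough reads; the majority
    orientation (cis/trans relative to the previous site) wins, blocks
    break where the vote margin drops below ``vote_margin``, and
    conflicting reads are counted rather than discarded.
    """
    def allele_of(aln: Alignment, site) -> int | None:
        pos, ref, alt, kind = site
        if ref_seq is not None:
            return allele_at_realigned(aln, pos, ref, alt, ref_seq, kind)
        b = aln.read_base_at(pos)
        if kind == "snv":
            if b == alt:
                return 1
            if b == ref:
                return 0
        elif kind == "del":
            if b == "-":
                return 1
            if b is not None and b != "-":
                return 0
        return None

    sites = sorted(het_sites)
    obs: dict[str, dict[int, int]] = {}
    for aln in alignments:
        if bins is not None:
            rb = bins.get(aln.read_id)
            if rb is None or rb.assigned_locus != locus:
                continue
        for site in sites:
            if aln.pos <= site[0] <= aln.end:
                a = allele_of(aln, site)
                if a is not None:
                    obs.setdefault(aln.read_id, {})[site[0]] = a

    blocks: list[HaplotypeBlock] = []
    current: HaplotypeBlock | None = None
    prev_pos: int | None = None
    for site in sites:
        pos = site[0]
        if current is None:
            current = HaplotypeBlock(len(blocks) + 1, {pos: 1}, 0, 0)
            prev_pos = pos
            continue
        cis = trans = 0
        for alleles in obs.values():
            if prev_pos in alleles and pos in alleles:
                if alleles[prev_pos] == alleles[pos]:
                    cis += 1
                else:
                    trans += 1
        total = cis + trans
        if total < min_reads or max(cis, trans) / total < vote_margin:
            blocks.append(current)
            current = HaplotypeBlock(len(blocks) + 1, {pos: 1}, 0, 0)
            prev_pos = pos
            continue
        prev_hap = current.assignments[prev_pos]
        same = cis >= trans
        current.assignments[pos] = prev_hap if same else (3 - prev_hap)
        current.supporting_reads += max(cis, trans)
        current.conflicting_reads += min(cis, trans)
        prev_pos = pos
    if current is not None:
        blocks.append(current)
    return blocks


def phase_relation(blocks: list[HaplotypeBlock], pos_a: int, pos_b: int) -> str:
    """'cis', 'trans' or 'unphased' for two heterozygous variant positions."""
    for b in blocks:
        if pos_a in b.assignments and pos_b in b.assignments:
            return "cis" if b.assignments[pos_a] == b.assignments[pos_b] else "trans"
    return "unphased"


def write_sv_tsv(calls: list[SVCall], path, contig: str = "chrT") -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tlength\tsupport\tlocus\tframe\n")
        for c in calls:
            fh.write(f"{contig}\t{c.start}\t{c.end}\t{c.length}\t{c.support}\t"
                     f"{c.locus}\t{c.frame_consequence}\n")


def write_phase_tsv(blocks: list[HaplotypeBlock], path) -> None:
    """Phased genotypes, pipe-separated by haplotype, one site per row."""
    with open(path, "w") as fh:
        fh.write("block\tpos\tgenotype\tsupport\tconflicts\n")
        for b in blocks:
            for pos, hap in sorted(b.assignments.items()):
                gt = "1|0" if hap == 1 else "0|1"
                fh.write(f"{b.block_id}\t{pos}\t{gt}\t{b.supporting_reads}\t"
                         f"{b.conflicting_reads}\n")
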