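"""Four-copy allele-balance genotyping of masked short-read pileups.

With the pseudogene hard-masked, every site in the homology region receives
reads from four collapsed copies: two gene haplotypes and two pseudogene
haplotypes.  A variant on ``a`` of those copies is therefore expected at an
alternate-allele fraction of ``a/4`` instead of the usual diploid ``a/2``:
a heterozygous gene variant sits at 0.25 and a homozygous one at 0.50.
Genotyping is a binomial likelihood over that hypothesis grid, and
locus-of-origin assignment sums per-read log-odds votes over PSVs carried
by alt-bearing reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .homology import HOMOLOGY, UNIQUE, HomologyMap, classify_region
from .mapper import Alignment
from .pileup import PileupColumn, PileupTable

AMBIGUITY_NATS = 2.0
LOCUS_LOG_ODDS = 3.0


@dataclass(frozen=True)
class GenotypeHypothesis:
    label: str
    theta: float  # expected alt fraction among collapsed copies
    prior: float


def hypotheses(region_type: str, priors: dict[str, float] | None = None):
    """Hypothesis grid: theta = a/4 in homology regions, a/2 in unique ones.

    The 0.75/1.0 homology states (hom in one locus + het/hom in the other)
    are rare but kept so the model is complete; they get small prior mass.
    """
    if region_type == HOMOLOGY:
        labels = [
            ("ref", 0.0), ("het_one_locus", 0.25),
            ("hom_one_locus_or_het_both", 0.5),
            ("three_copies", 0.75), ("all_copies", 1.0),
        ]
        default_prior = {"ref": 1.0, "het_one_locus": 1.0,
                         "hom_one_locus_or_het_both": 1.0,
                         "three_copies": 0.01, "all_copies": 0.01}
    elif region_type == UNIQUE:
        labels = [("ref", 0.0), ("het", 0.5), ("hom", 1.0)]
        default_prior = {"ref": 1.0, "het": 1.0, "hom": 1.0}
    else:
        raise ValueError(f"unknown region type {region_type!r}")
    pri = priors or default_prior
    z = sum(pri[l] for l, _ in labels)
    return [GenotypeHypothesis(l, t, pri[l] / z) for l, t in labels]


def expected_alt_fraction(zygosity: str, n_loci_carrying: int, region_type: str) -> float:
    """Expected alt read fraction under the collapsed-copies model.

    homology: (alt-bearing copies)/4; unique: /2.  A variant present in both
    loci cannot occur in a unique region (the pseudogene has no counterpart
    there).
    """
    if zygosity not in ("het", "hom") or n_loci_carrying not in (1, 2):
        raise ValueError("zygosity in {het,hom}, n_loci_carrying in {1,2}")
    copies = (1 if zygosity == "het" else 2) * n_loci_carrying
    if region_type == HOMOLOGY:
        return copies / 4.0
    if region_type == UNIQUE:
        if n_loci_carrying == 2:
            raise ValueError("no pseudogene copy exists in a unique region")
        return copies / 2.0
    raise ValueError(f"unknown region type {region_type!r}")


@dataclass
class SiteCall:
    pos: int
    ref_allele: str
    alt_allele: str
    alt_count: int
    depth: int
    region_type: str
    log_likelihood: dict[str, float] = field(default_factory=dict)
    posterior: dict[str, float] = field(default_factory=dict)
    map_hypothesis: str = "ref"
    theta_map: float = 0.0
    ambiguous: bool = False
    no_call: bool = False
    locus_assignment: str = "ambiguous"
    locus_posterior: float = 0.5
    locus_log_odds: float = 0.0
    kind: str = "snv"  # snv | del | ins

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


def genotype_site(
    alt_count: int,
    depth: int,
    region_type: str = HOMOLOGY,
    epsilon: float = 0.01,
    prior: dict[str, float] | None = None,
    pos: int = 0,
    ref_allele: str = "N",
    alt_allele: str = "N",
    kind: str = "snv",
) -> SiteCall:
    """Binomial MAP genotype over the collapsed hypothesis grid.

    Per-hypothesis success probability folds in the sequencing error rate:
    ``p = theta (1 - eps) + (1 - theta) eps/3`` (a symmetric substitution
    model; each wrong base is drawn uniformly from the three alternatives).
    A site is flagged ambiguous when the top two log-likelihoods are within
    2 nats; depth 0 yields an explicit no-call, never a reference call.
    """
    if not (0 <= alt_count <= depth):
        raise ValueError("require 0 <= alt_count <= depth")
    if not (0 < epsilon < 0.25):
        raise ValueError("epsilon must be in (0, 0.25)")
    call = SiteCall(pos=pos, ref_allele=ref_allele, alt_allele=alt_allele,
                    alt_count=alt_count, depth=depth, region_type=region_type,
                    kind=kind)
    if depth == 0:
        call.no_call = True
        call.map_hypothesis = "no_call"
        return call
    hyps = hypotheses(region_type, prior)
    lls = {}
    logpost = {}
    for h in hyps:
        p = h.theta * (1 - epsilon) + (1 - h.theta) * epsilon / 3.0
        ll = float(binom.logpmf(alt_count, depth, p))
        lls[h.label] = ll
        logpost[h.label] = ll + math.log(h.prior)
    m = max(logpost.values())
    z = sum(math.exp(v - m) for v in logpost.values())
    call.log_likelihood = lls
    call.posterior = {k: math.exp(v - m) / z for k, v in logpost.items()}
    call.map_hypothesis = max(logpost, key=logpost.get)
    call.theta_map = next(h.theta for h in hyps if h.label == call.map_hypothesis)
    ordered = sorted(lls.values(), reverse=True)
    call.ambiguous = len(ordered) > 1 and (ordered[0] - ordered[1]) < AMBIGUITY_NATS
    return call


def assign_locus(
    site: SiteCall,
    alignments: list[Alignment],
    hmap: HomologyMap,
    q: float = 0.01,
    min_votes: int = 2,
    threshold: float = LOCUS_LOG_ODDS,
) -> SiteCall:
    """Vote gene vs pseudogene origin using PSVs on alt-bearing reads.

    Each alt-carrying read contributes +log[(1-q)/q] per spanned PSV whose
    read base matches the gene base and -log[(1-q)/q] per pseudogene-base
    match; other bases are ignored.  Short reads rarely span a PSV, so this
    evidence is often inconclusive — the limitation that motivates
    escalating to the long-read stage.
    """
    w = math.log((1 - q) / q)
    total = 0.0
    informative = 0
    for aln in alignments:
        if not (aln.pos <= site.pos <= aln.end):
            continue
        b = aln.read_base_at(site.pos)
        if site.kind == "snv":
            carries_alt = b == site.alt_allele
        elif site.kind == "del":
            carries_alt = b == "-"
        else:  # insertion alleles: look for inserted bases at the site
            carries_alt = any(
                op == "I" and rp == site.pos
                for rp, _, op in aln.aligned_pairs() if op == "I"
            )
        if not carries_alt:
            continue
        read_votes = 0
        for p in hmap.psvs_in(aln.pos, aln.end):
            if p.gene_pos == site.pos:
                continue
            rb = aln.read_base_at(p.gene_pos)
            if rb == p.gene_base:
                total += w
                read_votes += 1
            elif rb == p.pseudo_base:
                total -= w
                read_votes += 1
        if read_votes:
            informative += 1
    site.locus_log_odds = total
    site.locus_posterior = 1.0 / (1.0 + math.exp(-total)) if abs(total) < 700 else (
        1.0 if total > 0 else 0.0)
    if informative < min_votes or abs(total) < threshold:
        site.locus_assignment = "ambiguous"
    else:
        site.locus_assignment = "gene" if total > 0 else "pseudo"
    return site


def scan_candidates(
    table: PileupTable,
    masked_ref: dict[str, str],
    hmap: HomologyMap,
    contig: str = "chrT",
    gene_len: int | None = None,
    min_alt_frac: float = 0.12,
    min_depth: int = 20,
    epsilon: float = 0.01,
    psv_margin: float = 0.2,
) -> list[SiteCall]:
    """Discover and genotype candidate sites from the pileup.

    PSV columns are expected near 50% pseudogene base in the null state and
    are suppressed unless their fraction departs from 0.5 by more than
    ``psv_margin`` (such departures are copy-number signals, consumed by the
    CNV caller, not small-variant candidates).
    """
    ref = masked_ref[contig]
    end = gene_len or len(ref)
    calls: list[SiteCall] = []
    depth_arr = table.depth_array(contig)
    for pos in range(1, end + 1):
        if depth_arr[pos] < min_depth:
            continue
        ref_base = ref[pos - 1]
        if ref_base == "N":
            continue
        col = table.column(contig, pos)
        depth = col.depth
        region = classify_region(pos, hmap) if hmap else UNIQUE
        psv = hmap.psv_at(pos) if hmap else None

        # substitution candidate: best non-reference base
        best_alt, best_n = None, 0
        for b, n in col.counts.items():
            if b == ref_base:
                continue
            if psv is not None and b == psv.pseudo_base:
                continue  # expected paralog state, not a sample variant
            if n > best_n:
                best_alt, best_n = b, n
        if best_alt and best_n / depth >= min_alt_frac:
            calls.append(
                genotype_site(best_n, depth, region, epsilon, pos=pos,
                              ref_allele=ref_base, alt_allele=best_alt, kind="snv")
            )
        # small deletion / insertion candidates
        if col.deletion_count / depth >= min_alt_frac:
            calls.append(
                genotype_site(col.deletion_count, depth, region, epsilon, pos=pos,
                              ref_allele=ref_base, alt_allele="-", kind="del")
            )
        if col.insertion_count and col.insertion_count / depth >= min_alt_frac:
            ins_seq = max(col.insertion_events, key=col.insertion_events.get)
            calls.append(
                genotype_site(col.insertion_events[ins_seq], depth, region, epsilon,
                              pos=pos, ref_allele=ref_base, alt_allele=ins_seq,
                              kind="ins")
            )
    # collapse runs of adjacent deletion columns into a single event call
    return _merge_deletion_runs(calls)


def _merge_deletion_runs(calls: list[SiteCall]) -> list[SiteCall]:
    out: list[SiteCall] = []
    for c in sorted(calls, key=lambda c: (c.pos, c.kind)):
        if (c.kind == "del" and out and out[-1].kind == "del"
                and out[-1].pos + len(out[-1].ref_allele) == c.pos
                and out[-1].map_hypothesis == c.map_hypothesis):
            prev = out[-1]
            prev.ref_allele += c.ref_allele
            continue
        out.append(c)
    return out


def candidate_sensitivity(theta: float, depth: int, min_alt_frac: float,
                          epsilon: float = 0.01) -> float:
    """P(candidate discovered) = binomial tail above the fraction threshold."""
    p = theta * (1 - epsilon) + (1 - theta) * epsilon / 3.0
    k = math.ceil(min_alt_frac * depth)
    return float(binom.sf(k - 1, depth, p))


def write_calls_tsv(calls: list[SiteCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tref\talt\tkind\talt_count\tdepth\tregion\t"
                 "THETA_MAP\tHYP\tLOCUS\tLOCUS_POST\tFLAG_AMBIG\n")
        for c in calls:
            fh.write(
                f"{c.pos}\t{c.ref_allele}\t{c.alt_allele}\t{c.kind}\t{c.alt_count}\t"
                f"{c.depth}\t{c.region_type}\t{c.theta_map}\t{c.map_hypothesis}\t"
                f"{c.locus_assignment}\t{c.locus_posterior:.4f}\t{int(c.ambiguous)}\n"
            )


def write_vcf(calls: list[SiteCall], contig: str, contig_len: int, path) -> None:
    """Minimal VCF 4.2 with the collapsed-model annotations as INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_len}>\n")
        fh.write('##INFO=<ID=THETA,Number=1,Type=Float,Description="MAP alt fraction">\n')
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=String,Description="Locus of origin">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if c.map_hypothesis in ("ref", "no_call"):
                continue
            if c.kind == "del":
                ref, alt = c.ref_allele, c.ref_allele[0]
            elif c.kind == "ins":
                ref, alt = c.ref_allele, c.ref_allele + c.alt_allele
            else:
                ref, alt = c.ref_allele, c.alt_allele
            flt = "AMBIG" if c.ambiguous else "PASS"
            fh.write(
                f"{contig}\t{c.pos}\t.\t{ref}\t{alt}\t.\t{flt}\t"
                f"THETA={c.theta_map};LOCUS={c.locus_assignment}\n"
            )
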