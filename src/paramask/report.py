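"""Variant consequence annotation and per-sample / cohort diagnostic tiers.

A recessive diagnosis needs two hits on the gene: two heterozygous variants
in trans, or one homozygous variant.  Variants assigned to the pseudogene
never count.  The tier records whether the second allele was resolvable
from masked short reads alone (solved_SR) or required the long-read stage
(solved_LR: an exon CNV, or locus/homozygosity resolution).

The packaged ``families17.tsv`` fixture transcribes a 17-family PCD cohort
(variant types, zygosities and resolution stage) so the cohort accounting
can be exercised without sequence data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

LOF_KINDS = {"stop_gain", "frameshift", "splice_site", "acceptor_gain"}


@dataclass
class GeneVariant:
    """A variant in gene (genomic, 1-based) coordinates for annotation."""

    kind: str  # snv | del | ins | exon_del
    pos: int
    ref: str = ""
    alt: str = ""
    end: int | None = None  # inclusive, for deletions


@dataclass
class ConsequenceAnnotation:
    kind: str  # stop_gain, frameshift, in_frame_indel, missense, synonymous,
    #            splice_site, acceptor_gain, intronic, non_coding
    details: dict = field(default_factory=dict)

    @property
    def is_lof(self) -> bool:
        return self.kind in LOF_KINDS


def _coding_pos(pos: int, exon_table: list[tuple[int, int]]) -> int | None:
    """1-based coding position of a genomic position, None if intronic/outside."""
    c = 0
    for s, e in exon_table:
        if s <= pos <= e:
            return c + (pos - s) + 1
        c += e - s + 1
    return None


def annotate_consequence(
    variant: GeneVariant,
    exon_table: list[tuple[int, int]],
    coding_frame: int = 0,
    gene_seq: str | None = None,
) -> ConsequenceAnnotation:
    """Classify a variant against the toy transcript (exons spliced in order).

    Deletions sum their deleted coding bases; the mod-3 test separates
    frameshift from in-frame (deleted_aa = nt/3).  SNVs in coding sequence
    are classified by codon lookup when the gene sequence is supplied;
    positions within 2 bases of a splice junction (intron side) are
    splice_site.
    """
    tx_start, tx_end = exon_table[0][0], exon_table[-1][1]

    if variant.kind in ("del", "exon_del"):
        end = variant.end if variant.end is not None else variant.pos + len(variant.ref) - 1
        if end < tx_start or variant.pos > tx_end:
            return ConsequenceAnnotation("non_coding")
        deleted_nt = sum(max(0, min(end, e) - max(variant.pos, s) + 1)
                         for s, e in exon_table)
        if deleted_nt == 0:
            return ConsequenceAnnotation("intronic", {"deleted_nt": 0})
        if deleted_nt % 3 != 0:
            return ConsequenceAnnotation(
                "frameshift", {"deleted_nt": deleted_nt, "net_nt": -deleted_nt})
        return ConsequenceAnnotation(
            "in_frame_indel",
            {"deleted_nt": deleted_nt, "deleted_aa": deleted_nt // 3})

    if variant.kind == "ins":
        inserted = len(variant.alt)
        if _coding_pos(variant.pos, exon_table) is None:
            return _intronic_or_splice(variant.pos, exon_table, tx_start, tx_end)
        if inserted % 3 != 0:
            return ConsequenceAnnotation("frameshift", {"net_nt": inserted})
        return ConsequenceAnnotation("in_frame_indel", {"inserted_nt": inserted})

    # SNV
    cpos = _coding_pos(variant.pos, exon_table)
    if cpos is None:
        return _intronic_or_splice(variant.pos, exon_table, tx_start, tx_end)
    if gene_seq is None:
        return ConsequenceAnnotation("missense", {"coding_pos": cpos})
    cds = "".join(gene_seq[s - 1 : e] for s, e in exon_table)[coding_frame:]
    ci = cpos - coding_frame - 1  # 0-based index into the framed CDS
    if ci < 0 or ci >= len(cds) - len(cds) % 3:
        return ConsequenceAnnotation("non_coding")
    codon_i = ci // 3
    codon = list(cds[codon_i * 3 : codon_i * 3 + 3])
    ref_aa = str(Seq("".join(codon)).translate())
    codon[ci % 3] = variant.alt
    alt_aa = str(Seq("".join(codon)).translate())
    details = {"coding_pos": cpos, "ref_aa": ref_aa, "alt_aa": alt_aa}
    if alt_aa == "*":
        return ConsequenceAnnotation("stop_gain", details)
    if alt_aa == ref_aa:
        return ConsequenceAnnotation("synonymous", details)
    return ConsequenceAnnotation("missense", details)


def _intronic_or_splice(pos, exon_table, tx_start, tx_end) -> ConsequenceAnnotation:
    if pos < tx_start or pos > tx_end:
        return ConsequenceAnnotation("non_coding")
    for s, e in exon_table:
        if e + 1 <= pos <= e + 2:
            return ConsequenceAnnotation("splice_site", {"side": "donor",
                                                         "offset": pos - e})
        if s - 2 <= pos <= s - 1:
            return ConsequenceAnnotation("splice_site", {"side": "acceptor",
                                                         "offset": pos - s})
    return ConsequenceAnnotation("intronic")


def acceptor_gain_inclusion(intronic_offset: int,
                            intron_seq: str | None = None) -> ConsequenceAnnotation:
    """Consequence of a novel splice acceptor created in an intron.

    ``intronic_offset`` is the (negative) position of the new acceptor's
    3' G relative to the downstream exon start (-1 is the last intronic
    base).  Splicing at the new AG retains the ``|offset| - 1`` intronic
    bases between it and the exon; the mod-3 test decides frameshift.
    Offsets of -1/-2 would disrupt, not create, the canonical acceptor.
    """
    if not isinstance(intronic_offset, int) or intronic_offset >= -2:
        raise ValueError("offset must be an integer <= -3 (inside the intron)")
    if intron_seq is not None:
        if len(intron_seq) < -intronic_offset:
            raise ValueError("intron sequence shorter than |offset|")
        if intron_seq[intronic_offset - 1] != "A":
            raise ValueError("no A immediately 5' of the new G: AG not created")
    retained = -intronic_offset - 1
    frameshift = retained % 3 != 0
    return ConsequenceAnnotation(
        "acceptor_gain",
        {"retained_nt": retained, "frameshift": frameshift,
         "offset": intronic_offset},
    )


# ---------------------------------------------------------------------------
# Diagnostic tiers


@dataclass
class AlleleCall:
    """One variant-level piece of evidence entering the diagnosis."""

    variant_id: str
    locus: str  # gene | pseudo | ambiguous
    zygosity: str  # het | hom
    stage: str  # SR | LR
    kind: str = "snv"
    acmg: str = ""


@dataclass
class DiagnosticStatus:
    sample_id: str
    gene_alleles_found: int
    tier: str  # solved_SR | solved_LR | partial | unsolved
    supporting: list[AlleleCall]
    excluded: list[AlleleCall]
    phase_evidence: str  # trans | cis | unphased | homozygous
    warnings: list[str] = field(default_factory=list)


def assemble_status(
    sample_id: str,
    sr_calls: list[AlleleCall],
    cnv_calls: list[AlleleCall] | None = None,
    lr_results: dict | None = None,
) -> DiagnosticStatus:
    """Combine SR and LR evidence into a diagnostic tier.

    ``lr_results`` may carry ``locus_reassignments`` (variant_id -> locus),
    ``homozygosity_confirmed`` (variant_id -> bool) and ``phase``
    (trans/cis/unphased) from the long-read stage.
    """
    lr_results = lr_results or {}
    calls = list(sr_calls) + list(cnv_calls or [])
    reassign = lr_results.get("locus_reassignments", {})
    for c in calls:
        if c.variant_id in reassign:
            c.locus = reassign[c.variant_id]

    supporting = [c for c in calls if c.locus == "gene"]
    excluded = [c for c in calls if c.locus != "gene"]
    warnings = []

    n_alleles = 0
    for c in supporting:
        n_alleles += 2 if c.zygosity == "hom" else 1
    n_alleles = min(n_alleles, 2)

    has_hom = any(c.zygosity == "hom" for c in supporting)
    hets = [c for c in supporting if c.zygosity == "het"]
    phase = lr_results.get("phase")
    if has_hom:
        phase_evidence = "homozygous"
    elif phase in ("trans", "cis"):
        phase_evidence = phase
    else:
        phase_evidence = "unphased"

    biallelic = False
    if has_hom:
        biallelic = True
    elif len(hets) >= 2:
        if phase_evidence == "trans":
            biallelic = True
        elif phase_evidence == "cis":
            warnings.append("two heterozygous variants are in cis: single allele")
            n_alleles = 1
        else:
            warnings.append("two heterozygous variants but phase unknown")

    if biallelic:
        tier = "solved_LR" if any(c.stage == "LR" for c in supporting) else "solved_SR"
    elif n_alleles == 1:
        tier = "partial"
    else:
        tier = "unsolved"
    return DiagnosticStatus(
        sample_id=sample_id, gene_alleles_found=n_alleles, tier=tier,
        supporting=supporting, excluded=excluded,
        phase_evidence=phase_evidence, warnings=warnings,
    )


def cohort_summary(
    statuses: list[DiagnosticStatus],
    n_referred: int,
    n_genetically_confirmed: int,
) -> dict:
    """Cohort accounting: tier counts and the gene-positive percentage."""
    if not statuses:
        raise ValueError("empty cohort")
    if n_genetically_confirmed <= 0 or n_referred <= 0:
        raise ValueError("denominators must be positive")
    tiers = {"solved_SR": 0, "solved_LR": 0, "partial": 0, "unsolved": 0}
    hom = comp_het = 0
    for s in statuses:
        tiers[s.tier] += 1
        if s.tier.startswith("solved"):
            if s.phase_evidence == "homozygous":
                hom += 1
            else:
                comp_het += 1
    solved = tiers["solved_SR"] + tiers["solved_LR"]
    if not (solved <= n_genetically_confirmed <= n_referred):
        raise ValueError("inconsistent counts: solved <= confirmed <= referred")
    return {
        "n_families": len(statuses),
        **tiers,
        "solved_total": solved,
        "homozygous_families": hom,
        "compound_het_families": comp_het,
        "n_referred": n_referred,
        "n_genetically_confirmed": n_genetically_confirmed,
        "gene_positive_percent": round(100.0 * solved / n_genetically_confirmed),
    }


# ---------------------------------------------------------------------------
# HGVS-lite and the packaged cohort fixture

_HGVS_RE = re.compile(
    r"^c\.(?P<start>\d+)(?P<soff>[+-]\d+)?"
    r"(?:_(?P<end>\d+)(?P<eoff>[+-]\d+)?)?"
    r"(?:(?P<ref>[ACGT])>(?P<alt>[ACGT])|delins(?P<dins>[ACGT]+)|(?P<del>del)|(?P<dup>dup))$"
)


def parse_hgvs_c(cdna: str) -> dict:
    """Parse the cDNA patterns appearing in the cohort fixture.

    Supports substitutions (with intronic offsets), del, dup, delins and
    intronic-range deletions; anything else is rejected.
    """
    m = _HGVS_RE.match(cdna.strip())
    if not m:
        raise ValueError(f"unsupported HGVS pattern: {cdna!r}")
    d = m.groupdict()
    out = {
        "start": int(d["start"]),
        "start_offset": int(d["soff"]) if d["soff"] else 0,
        "end": int(d["end"]) if d["end"] else None,
        "end_offset": int(d["eoff"]) if d["eoff"] else 0,
    }
    if d["alt"]:
        out["kind"] = "sub"
        out["ref"], out["alt"] = d["ref"], d["alt"]
    elif d["dins"]:
        out["kind"] = "delins"
        out["inserted"] = d["dins"]
    elif d["del"]:
        out["kind"] = "exon_del" if (out["start_offset"] or out["end_offset"]) else "del"
    else:
        out["kind"] = "dup"
    if out["kind"] == "sub" and out["start_offset"]:
        out["intronic"] = True
    return out


def load_families_fixture(path: str | Path | None = None) -> pd.DataFrame:
    if path is None:
        with resources.as_file(
            resources.files("paramask.data") / "families17.tsv"
        ) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def statuses_from_fixture(df: pd.DataFrame) -> list[DiagnosticStatus]:
    """Replay the fixture cohort through the tier logic, family by family."""
    statuses = []
    for fam, rows in df.groupby("family", sort=True):
        sr, cnv = [], []
        phase = None
        for _, r in rows.iterrows():
            parsed = parse_hgvs_c(r["cdna"])
            call = AlleleCall(
                variant_id=r["cdna"], locus=r["locus"], zygosity=r["zygosity"],
                stage=r["stage"], kind=parsed["kind"], acmg=str(r["acmg"]),
            )
            (cnv if r["stage"] == "LR" else sr).append(call)
            if r["phase"] in ("trans", "cis"):
                phase = r["phase"]
        statuses.append(
            assemble_status(f"family{fam}", sr, cnv, {"phase": phase})
        )
    return statuses


def write_report(statuses: list[DiagnosticStatus], summary: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\ttier\tgene_alleles\tphase\tsupporting\texcluded\n")
        for s in statuses:
            fh.write(
                f"{s.sample_id}\t{s.tier}\t{s.gene_alleles_found}\t{s.phase_evidence}\t"
                f"{';'.join(c.variant_id for c in s.supporting)}\t"
                f"{';'.join(c.variant_id for c in s.excluded)}\n"
            )
        fh.write("\n# cohort summary\n")
        for k, v in summary.items():
            fh.write(f"# {k}: {v}\n")
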