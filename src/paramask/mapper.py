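"""Built-in toy read mapper: exact k-mer seeds on the masked reference,
segment chaining and banded gap closure.

k-mers containing 'N' are never indexed, so nothing can be placed on a
hard-masked interval: reads from the pseudogene necessarily land on the
gene, with mismatches at PSV positions — the collapse the pipeline relies
on.  Chaining across a diagonal shift emits a single alignment containing
an insertion/deletion op, so multi-kilobase deletions spanned by long reads
surface as ``D`` CIGAR operations.

This is a desk-scale mapper, not a BWA/minimap2 replacement: forward strand
only, no paired-end rescue, deterministic leftmost tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pysam

from .simulate import Read, ReadSet

# chaining penalties: cost of opening a gap between chained segments and
# per-base cost of the diagonal shift it implies
GAP_OPEN_COST = 4.0
GAP_SHIFT_COST = 0.02
BREAKPOINT_OPT_MIN = 30  # net indel size above which the exact split is used
MAX_SEED_HITS = 8
# split same-diagonal anchor runs at gaps above this: a long anchor-free
# stretch can hide a balanced indel pair and must be re-aligned, not M-filled
SEGMENT_SPLIT_GAP = 50
DIAGONAL_FILL_MAX = 25  # equal-length gaps up to this are taken as substitutions


@dataclass
class Alignment:
    read_id: str
    contig: str
    pos: int  # 1-based leftmost reference position
    cigar: list[tuple[str, int]]  # ops among M (match/mismatch), I, D, S
    seq: str
    score: float = 0.0
    mapq: int = 60
    nm: int = 0
    is_supplementary: bool = False

    @property
    def ref_span(self) -> int:
        return sum(ln for op, ln in self.cigar if op in ("M", "D"))

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position."""
        return self.pos + self.ref_span - 1

    def aligned_pairs(self):
        """Yield (ref_pos 1-based, read_index 0-based, op) for M/D/I ops.

        For D, read_index is None; for I, ref_pos is the base *before* the
        insertion and read_index the first inserted base.
        """
        rpos, qpos = self.pos, 0
        for op, ln in self.cigar:
            if op == "M":
                for j in range(ln):
                    yield rpos + j, qpos + j, "M"
                rpos += ln
                qpos += ln
            elif op == "D":
                for j in range(ln):
                    yield rpos + j, None, "D"
                rpos += ln
            elif op == "I":
                yield rpos - 1, qpos, "I"
                qpos += ln
            elif op == "S":
                qpos += ln

    def read_slice(self, ref_start: int, ref_end: int) -> str | None:
        """Read bases aligned within [ref_start, ref_end] (1-based inclusive).

        Returns None unless the alignment's M ops cover both window edges,
        so partial overlaps never yield truncated slices.
        """
        first = last = None
        rpos, qpos = self.pos, 0
        covered_start = covered_end = False
        for op, ln in self.cigar:
            if op == "M":
                lo, hi = rpos, rpos + ln - 1
                if lo <= ref_start <= hi:
                    covered_start = True
                if lo <= ref_end <= hi:
                    covered_end = True
                if hi >= ref_start and lo <= ref_end:
                    q_lo = qpos + max(0, ref_start - lo)
                    q_hi = qpos + min(ln - 1, ref_end - lo)
                    if first is None:
                        first = q_lo
                    last = q_hi
                rpos += ln
                qpos += ln
            elif op == "D":
                if rpos <= ref_start <= rpos + ln - 1:
                    covered_start = True
                if rpos <= ref_end <= rpos + ln - 1:
                    covered_end = True
                rpos += ln
            elif op in ("I", "S"):
                qpos += ln
        if not (covered_start and covered_end) or first is None:
            return None
        return self.seq[first : last + 1]

    def read_base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to ``ref_pos``; '-' when deleted; None if not covered."""
        rpos, qpos = self.pos, 0
        for op, ln in self.cigar:
            if op == "M":
                if rpos <= ref_pos < rpos + ln:
                    return self.seq[qpos + (ref_pos - rpos)]
                rpos += ln
                qpos += ln
            elif op == "D":
                if rpos <= ref_pos < rpos + ln:
                    return "-"
                rpos += ln
            elif op in ("I", "S"):
                qpos += ln
        return None

    def cigar_string(self) -> str:
        return "".join(f"{ln}{op}" for op, ln in self.cigar)


@dataclass
class MappingResult:
    alignments: list[Alignment] = field(default_factory=list)
    unaligned: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self):
        return len(self.alignments)


def build_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _segments_from_anchors(anchors: list[tuple[int, int]], k: int):
    """Group anchors into maximal exact-diagonal runs -> (r_start, r_end, d)."""
    by_diag: dict[int, list[int]] = {}
    for i, p in anchors:
        by_diag.setdefault(p - i, []).append(i)
    segments = []
    for d, positions in by_diag.items():
        positions.sort()
        run_start = prev = positions[0]
        for i in positions[1:]:
            if i - prev > SEGMENT_SPLIT_GAP:
                segments.append((run_start, prev + k, d))
                run_start = i
            prev = i
        segments.append((run_start, prev + k, d))
    segments.sort()
    return segments


def _chain(segments, k: int):
    """DP chain maximising anchored coverage minus diagonal-shift penalties."""
    n = len(segments)
    score = [0.0] * n
    back = [-1] * n
    for j in range(n):
        rs_j, re_j, d_j = segments[j]
        score[j] = float(re_j - rs_j)
        for i in range(j):
            rs_i, re_i, d_i = segments[i]
            marginal = re_j - max(rs_j, re_i)  # read coverage j adds beyond i
            if marginal <= 0:
                continue
            if rs_j + d_j < re_i + d_i - 250:  # ref order violated beyond trim reach
                continue
            gc = 0.0 if d_i == d_j else GAP_OPEN_COST + GAP_SHIFT_COST * abs(d_j - d_i)
            cand = score[i] + marginal - gc
            if cand > score[j]:
                score[j] = cand
                back[j] = i
    best = max(range(n), key=lambda j: (score[j], -(segments[j][0] + segments[j][2])))
    chain = []
    j = best
    while j != -1:
        chain.append(segments[j])
        j = back[j]
    chain.reverse()
    in_chain = set(map(tuple, chain))
    second = max((score[j] for j in range(n) if tuple(segments[j]) not in in_chain),
                 default=0.0)
    return chain, score[best], second


def _edlib_ops(query: str, ref: str) -> list[tuple[str, int]]:
    if not query and not ref:
        return []
    if not query:
        return [("D", len(ref))]
    if not ref:
        return [("I", len(query))]
    cig = edlib.align(query, ref, task="path", mode="NW")["cigar"]
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            op = "M" if ch in "=X" else ch
            ops.append((op, int(num)))
            num = ""
    return ops


def _split_gap(read_gap: str, ref_gap: str) -> list[tuple[str, int]]:
    """Exact mismatch-minimising placement of one large indel inside a gap.

    The read gap aligns partly on the left diagonal and partly on the right
    one; every split point is scored by prefix/suffix mismatch counts and
    the leftmost optimum wins, so the same event gets the same breakpoints
    in every supporting read.
    """
    g, G = len(read_gap), len(ref_gap)
    if g == G:
        return [("M", g)] if g else []
    n = min(g, G)
    left_mm = [0] * (n + 1)
    for x in range(n):
        left_mm[x + 1] = left_mm[x] + (read_gap[x] != ref_gap[x])
    right_mm = [0] * (n + 1)
    for x in range(n):
        right_mm[x + 1] = right_mm[x] + (
            read_gap[g - 1 - x] != ref_gap[G - 1 - x])
    best_x, best_cost = 0, None
    for x in range(n + 1):
        cost = left_mm[x] + right_mm[n - x]
        if best_cost is None or cost < best_cost:
            best_x, best_cost = x, cost
    ops = []
    if best_x:
        ops.append(("M", best_x))
    if G > g:
        ops.append(("D", G - g))
    else:
        ops.append(("I", g - G))
    if n - best_x:
        ops.append(("M", n - best_x))
    return ops


def _extend_flank(read: str, ref: str, r_edge: int, p_edge: int, direction: int):
    """Greedy diagonal extension from an anchor edge toward a read end.

    Stops at contig bounds, at masked bases, or when the running mismatch
    count exceeds 0.3x the extension length + 2 (junk guard).  Returns the
    number of extended bases.
    """
    # direction == -1: extend left from read index r_edge-1 / ref p_edge-1
    # direction == +1: extend right from read index r_edge / ref p_edge
    ext = mism = 0
    best_ext = 0
    while True:
        if direction < 0:
            qi, pi = r_edge - 1 - ext, p_edge - 1 - ext
            if qi < 0 or pi < 0:
                break
        else:
            qi, pi = r_edge + ext, p_edge + ext
            if qi >= len(read) or pi >= len(ref):
                break
        if ref[pi] == "N":
            break
        if read[qi] != ref[pi]:
            mism += 1
        ext += 1
        if mism <= 0.3 * ext + 2:
            best_ext = ext
        if mism > 0.3 * ext + 6:
            break
    return best_ext


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def _align_read(read_seq: str, ref: str, index, k: int, band: int) -> Alignment | None:
    anchors = []
    for i in range(len(read_seq) - k + 1):
        hits = index.get(read_seq[i : i + k])
        if hits and len(hits) <= MAX_SEED_HITS:
            for p in hits:
                anchors.append((i, p))
    if not anchors:
        return None
    segments = _segments_from_anchors(anchors, k)
    chain, best, second = _chain(segments, k)

    # trim read/ref overlaps between consecutive chained segments
    trimmed = [list(chain[0])]
    for rs, re, d in chain[1:]:
        prev_rs, prev_re, prev_d = trimmed[-1]
        t = max(0, prev_re - rs, (prev_re + prev_d) - (rs + d))
        rs += t
        if re - rs >= 1:
            trimmed.append([rs, re, d])
    chain = trimmed

    rs0, re0, d0 = chain[0]
    head = _extend_flank(read_seq, ref, rs0, rs0 + d0, -1)
    ops: list[tuple[str, int]] = []
    if rs0 - head > 0:
        ops.append(("S", rs0 - head))
    ops.append(("M", head + (re0 - rs0)))
    aln_start0 = rs0 + d0 - head  # 0-based ref start

    prev_re, prev_d = re0, d0
    for rs, re, d in chain[1:]:
        rgap = rs - prev_re
        refgap = (rs + d) - (prev_re + prev_d)
        if rgap == 0 and refgap == 0:
            pass
        elif rgap == refgap and rgap <= DIAGONAL_FILL_MAX:
            ops.append(("M", rgap))
        elif rgap == 0:
            ops.append(("D", refgap))
        elif refgap == 0:
            ops.append(("I", rgap))
        elif abs(refgap - rgap) >= BREAKPOINT_OPT_MIN:
            ops.extend(
                _split_gap(read_seq[prev_re:rs],
                           ref[prev_re + prev_d : rs + d])
            )
        else:
            ops.extend(
                _edlib_ops(read_seq[prev_re:rs],
                           ref[prev_re + prev_d : rs + d])
            )
        ops.append(("M", re - rs))
        prev_re, prev_d = re, d

    tail = _extend_flank(read_seq, ref, prev_re, prev_re + prev_d, +1)
    if tail:
        ops.append(("M", tail))
    if prev_re + tail < len(read_seq):
        ops.append(("S", len(read_seq) - prev_re - tail))

    ops = _merge_ops(ops)
    aln = Alignment("", "", aln_start0 + 1, ops, read_seq)

    # count mismatches / indels for NM and score
    mism = 0
    rpos, qpos = aln_start0, 0
    indel = 0
    for op, ln in ops:
        if op == "M":
            for j in range(ln):
                if read_seq[qpos + j] != ref[rpos + j]:
                    mism += 1
            rpos += ln
            qpos += ln
        elif op == "D":
            rpos += ln
            indel += ln
        elif op == "I":
            qpos += ln
            indel += ln
        else:
            qpos += ln
    matched = sum(ln for op, ln in ops if op == "M")
    aln.nm = mism + indel
    aln.score = matched - 3 * mism - 0.1 * indel
    aln.mapq = 60 if best - second > 20 else max(0, int(best - second))
    return aln


def map_reads(
    reads: ReadSet | list[Read],
    masked_ref: dict[str, str] | str | Path,
    k: int = 15,
    band: int = 50,
) -> MappingResult:
    """Map reads to a hard-masked reference; unmappable reads are recorded.

    ``masked_ref`` may be a dict of contig sequences or a FASTA path.
    """
    if k < 11:
        raise ValueError("seed length k must be >= 11")
    if not isinstance(masked_ref, dict):
        from .masking import read_fasta

        masked_ref = read_fasta(masked_ref)
    read_list = reads.reads if isinstance(reads, ReadSet) else reads

    result = MappingResult()
    for contig, seq in masked_ref.items():
        index = build_index(seq, k)
        for read in read_list:
            aln = _align_read(read.sequence, seq, index, k, band)
            if aln is None:
                continue
            aln.read_id = read.read_id
            aln.contig = contig
            result.alignments.append(aln)
    aligned_ids = {a.read_id for a in result.alignments}
    result.unaligned = [r.read_id for r in read_list if r.read_id not in aligned_ids]
    result.alignments.sort(key=lambda a: (a.contig, a.pos))
    return result


# ---------------------------------------------------------------------------
# SAM interchange


def write_sam(alignments: list[Alignment], ref_lengths: dict[str, int],
              path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for a in alignments:
            flag = 2048 if a.is_supplementary else 0
            fh.write(
                "\t".join(
                    [
                        a.read_id, str(flag), a.contig, str(a.pos), str(a.mapq),
                        a.cigar_string(), "*", "0", "0", a.seq, "*",
                        f"NM:i:{a.nm}",
                    ]
                )
                + "\n"
            )
    return path


def read_sam(path: str | Path) -> list[Alignment]:
    """Load alignments from SAM (e.g. produced by an external aligner)."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            cigar = []
            for code, ln in rec.cigartuples or []:
                op = "MIDNSHP=XB"[code]
                if op in ("=", "X"):
                    op = "M"
                if op in ("H", "P", "N", "B"):
                    continue
                cigar.append((op, ln))
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    pos=rec.reference_start + 1,
                    cigar=_merge_ops(cigar),
                    seq=rec.query_sequence or "",
                    mapq=rec.mapping_quality,
                    nm=rec.get_tag("NM") if rec.has_tag("NM") else 0,
                    is_supplementary=rec.is_supplementary,
                )
            )
    return out
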