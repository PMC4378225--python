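"""ORF calling and translation-signal detection.

A deliberately transparent ORF caller replaces HMM-based gene finding:
maximal open reading frames on both strands, with the start codon chosen
by ribosome-binding-site evidence (Shine-Dalgarno match upstream).
High-GC genomes are riddled with long spurious open frames in the
non-coding frames of real genes, so the pipeline follows the caller with
an explicit overlap-resolution step (:func:`resolve_overlaps`) that keeps,
within each conflicting pair, the SD-supported and then the longer frame
-- the same arbitration gene finders perform internally.

Also here: detectors for the two Mu-hallmark translational features, the
-1 programmed-frameshift slippery heptamer (X XXY YYZ, canonically
T TTT TTC) inside tail genes, and SD-driven internal in-frame starts of
the protease/scaffolding type.
"""

from __future__ import annotations

import re
from bisect import insort
from dataclasses import dataclass

from .records import GenomeRecord, OrfRecord, assign_ranks, orf_from_span, revcomp

STOP_RE = re.compile(r"(?=(TAA|TAG|TGA))")
SD_CONSENSUS = "AGGAGG"
MIN_SPACER, MAX_SPACER = 4, 13
PURINES = frozenset("AG")


@dataclass
class SdHit:
    """An upstream Shine-Dalgarno match.

    ``sd_seq`` is the matched consensus window extended 3' over adjacent
    purines (6-8 nt); ``spacer_nt`` the gap between its 3' end and the
    start codon; ``score`` the number of consensus-matching positions in
    the 6-nt core.
    """

    sd_seq: str
    spacer_nt: int
    score: int

    def __post_init__(self) -> None:
        assert MIN_SPACER <= self.spacer_nt <= MAX_SPACER
        assert 6 <= len(self.sd_seq) <= 8


@dataclass
class SlipperySite:
    """A -1 frameshift candidate inside an ORF.

    ``codon_index_in_orf`` is the 1-based codon whose third base begins
    the heptamer; ``pos`` the forward-strand coordinate of the heptamer's
    5'-most base in reading direction.
    """

    genome_id: str
    heptamer: str
    codon_index_in_orf: int
    codons_before_stop: int
    host_orf_id: str
    downstream_orf_id: str
    pos: int
    strand: str


def _upstream_in_reading(genome: GenomeRecord, start_pos: int, strand: str,
                         n: int) -> str:
    """The <=n bases 5' of a start codon, in reading orientation."""
    if strand == "+":
        return genome.seq[max(0, start_pos - n) : start_pos]
    return revcomp(genome.seq[start_pos : start_pos + n])


def score_sd(
    genome: GenomeRecord,
    start_pos: int,
    strand: str = "+",
    min_match: int = 4,
) -> SdHit | None:
    """Best ungapped Shine-Dalgarno (AGGAGG) match upstream of a start.

    ``start_pos`` addresses the start codon in forward coordinates: its
    first base for + ORFs, the base *after* the span for - ORFs (i.e. the
    reading-direction 5' end). Spacers of 4-13 nt are scanned; a hit needs
    >= ``min_match`` of 6 consensus positions. Ties prefer the smaller
    spacer. Windows reaching past the genome edge are skipped, so a start
    near the boundary simply yields None.
    """
    up = _upstream_in_reading(genome, start_pos, strand, MAX_SPACER + 6)
    best: tuple[int, int] | None = None  # (score, spacer)
    for spacer in range(MIN_SPACER, MAX_SPACER + 1):
        lo = len(up) - spacer - 6
        if lo < 0:
            continue
        window = up[lo : lo + 6]
        score = sum(a == b for a, b in zip(window, SD_CONSENSUS))
        if score >= min_match and (best is None or score > best[0]):
            best = (score, spacer)
    if best is None:
        return None
    score, spacer = best
    lo = len(up) - spacer - 6
    hi = lo + 6
    # extend 3' over adjacent purines (up to 8 nt total), as the printed
    # SD sequences of this phage group are 7-mers like ACGAGGA
    while hi - lo < 8 and spacer > MIN_SPACER and up[hi] in PURINES:
        hi += 1
        spacer -= 1
    return SdHit(sd_seq=up[lo:hi], spacer_nt=spacer, score=score)


def _stop_positions_by_frame(seq: str) -> dict[int, list[int]]:
    by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for m in STOP_RE.finditer(seq):
        p = m.start()
        by_frame[p % 3].append(p)
    return by_frame


def _scan_strand(
    genome: GenomeRecord,
    seq: str,
    strand: str,
    min_codons: int,
    starts: frozenset[str],
) -> list[OrfRecord]:
    """Maximal ORFs on one strand of ``seq`` (already in reading direction)."""
    n = len(seq)
    out = []
    stops = _stop_positions_by_frame(seq)
    for frame in range(3):
        prev_end = frame
        for stop in stops[frame]:
            region_start, region_end = prev_end, stop + 3
            prev_end = stop + 3
            max_start = stop - 3 * min_codons  # leaves >= min_codons of coding
            if max_start < region_start:
                continue
            candidates = [
                p
                for p in range(region_start, max_start + 1, 3)
                if seq[p : p + 3] in starts
            ]
            if not candidates:
                continue
            chosen, chosen_hit = None, None
            for p in candidates:
                fwd_start = p if strand == "+" else n - p
                hit = score_sd(genome, fwd_start, strand)
                if hit is not None and (chosen_hit is None or hit.score > chosen_hit.score):
                    chosen, chosen_hit = p, hit
            if chosen is None:
                chosen = candidates[0]
            if strand == "+":
                f_start, f_end = chosen, region_end
            else:
                f_start, f_end = n - region_end, n - chosen
            orf = orf_from_span(
                genome, f_start, f_end, strand,
                f"{genome.id}_{f_start + 1}_{f_end}_{strand}",
            )
            if chosen_hit is not None:
                orf.sd_seq = chosen_hit.sd_seq
                orf.sd_spacer = chosen_hit.spacer_nt
                orf.extra["sd_score"] = chosen_hit.score
            out.append(orf)
    return out


def find_orfs(
    genome: GenomeRecord,
    min_codons: int = 34,
    starts: frozenset[str] = frozenset({"ATG", "GTG", "TTG"}),
) -> list[OrfRecord]:
    """All maximal ORFs of >= min_codons amino acids on both strands.

    Within each stop-to-stop frame the reported start is the candidate
    with the strongest Shine-Dalgarno support (ties: most upstream), or
    the most upstream start when none has SD support. Overlapping ORFs,
    including opposite-strand ones, are all reported; arbitration between
    them is a separate, later step (:func:`resolve_overlaps`).
    """
    if genome.length_bp < 3:
        return []
    fwd = _scan_strand(genome, genome.seq, "+", min_codons, starts)
    rev = _scan_strand(genome, revcomp(genome.seq), "-", min_codons, starts)
    return sorted(fwd + rev, key=lambda o: (o.start, o.end, o.strand))


def resolve_overlaps(
    orfs: list[OrfRecord],
    max_overlap_frac: float = 0.45,
    min_sd_score: int = 5,
) -> list[OrfRecord]:
    """Greedy arbitration of heavily overlapping ORF calls.

    Candidates are ranked by (strong SD support, length); each is kept
    unless the union of already-kept ORFs covers more than
    ``max_overlap_frac`` of its span. Genuine overlapping gene pairs -- a
    -1 frameshift partner entering its host's 3' region -- sit well below
    the threshold and survive; frame-shifted "shadow" open frames inside
    (or straddling) real genes, which rarely carry a strong SD, are
    almost entirely covered by kept genes and are discarded.
    """

    def sd_rank(o: OrfRecord) -> int:
        # scores below min_sd_score carry no weight: a weak chance match
        # should not outrank a longer frame
        score = o.extra.get("sd_score", 0)
        return score if score >= min_sd_score else 0

    ranked = sorted(
        orfs,
        key=lambda o: (-sd_rank(o), -(o.end - o.start), o.start, o.strand),
    )
    def union_overlap(cand: OrfRecord, spans: list[tuple[int, int]]) -> int:
        hits = sorted(
            (max(s, cand.start), min(e, cand.end))
            for s, e in spans
            if s < cand.end and e > cand.start
        )
        covered, cursor = 0, cand.start
        for s, e in hits:
            s = max(s, cursor)
            if e > s:
                covered += e - s
                cursor = e
        return covered

    kept: list[OrfRecord] = []
    rejected: list[OrfRecord] = []
    intervals: list[tuple[int, int]] = []  # kept spans, sorted by start
    for cand in ranked:
        if union_overlap(cand, intervals) <= max_overlap_frac * (cand.end - cand.start):
            kept.append(cand)
            insort(intervals, (cand.start, cand.end))
        else:
            rejected.append(cand)

    # local improvement: a single spurious frame can outrank and block two
    # adjacent genuine genes; if the SD-supported candidates one kept ORF
    # blocked are mutually compatible and jointly longer, swap them in
    for k in list(kept):
        others = [(o.start, o.end) for o in kept if o is not k]
        block = [
            r
            for r in rejected
            if sd_rank(r) >= max(min_sd_score, sd_rank(k))
            and min(r.end, k.end) > max(r.start, k.start)
            and union_overlap(r, others) <= max_overlap_frac * (r.end - r.start)
        ]
        chosen: list[OrfRecord] = []
        for r in sorted(block, key=lambda o: -(o.end - o.start)):
            spans = others + [(c.start, c.end) for c in chosen]
            if union_overlap(r, spans) <= max_overlap_frac * (r.end - r.start):
                chosen.append(r)
        # a single longer equally-supported candidate would have won the
        # greedy pass already; only a jointly-longer pair is evidence that
        # the incumbent is the spurious frame
        if len(chosen) >= 2 and sum(c.end - c.start for c in chosen) >= (k.end - k.start):
            kept.remove(k)
            kept.extend(chosen)
            rejected = [r for r in rejected if r not in chosen] + [k]
    return sorted(kept, key=lambda o: (o.start, o.end))


def annotate_genome(genome: GenomeRecord, min_codons: int = 34) -> list[OrfRecord]:
    """The pipeline's ORF annotation: call, arbitrate overlaps, rank."""
    return assign_ranks(resolve_overlaps(find_orfs(genome, min_codons)))


def find_internal_starts(
    genome: GenomeRecord,
    orf: OrfRecord,
    min_score: int = 4,
) -> list[tuple[int, SdHit]]:
    """SD-supported in-frame ATG/GTG codons strictly inside an ORF.

    Returns 1-based codon indices with their SD evidence; the annotated
    start itself (codon 1) and the stop are excluded.
    """
    cds = orf.cds(genome)
    hits = []
    for codon_index in range(2, orf.n_codons):  # strictly internal
        r = (codon_index - 1) * 3
        if cds[r : r + 3] not in ("ATG", "GTG"):
            continue
        if orf.strand == "+":
            fwd_pos = orf.start + r
        else:
            fwd_pos = orf.end - r
        hit = score_sd(genome, fwd_pos, orf.strand, min_match=min_score)
        if hit is not None:
            hits.append((codon_index, hit))
    return hits


def find_slippery_sites(
    genome: GenomeRecord,
    orfs: list[OrfRecord],
    window_nt: int = 200,
) -> list[SlipperySite]:
    """Scan annotated ORFs for -1 frameshift slippery heptamers.

    A site is reported when an X XXY YYZ heptamer sits in-frame (first
    base = third base of a codon) inside an ORF *and* a -1-frame ORF on
    the same strand starts within ``window_nt`` downstream, overlapping
    the host ORF's 3' region -- the configuration of overlapping tail
    assembly genes.
    """
    n = genome.length_bp
    sites = []
    by_strand: dict[str, list[OrfRecord]] = {"+": [], "-": []}
    for o in orfs:
        by_strand[o.strand].append(o)
    for host in orfs:
        cds = host.cds(genome)
        read_start = host.start if host.strand == "+" else n - host.end
        n_trans = host.n_codons - 1
        for codon in range(1, n_trans - 1):
            r = (codon - 1) * 3 + 2
            hept = cds[r : r + 7]
            if len(hept) < 7:
                break
            if not (hept[0] == hept[1] == hept[2] and hept[3] == hept[4] == hept[5]):
                continue
            hept_read = read_start + r
            partner = None
            for cand in by_strand[host.strand]:
                if cand.orf_id == host.orf_id:
                    continue
                c_read = cand.start if cand.strand == "+" else n - cand.end
                if not (hept_read < c_read <= hept_read + window_nt):
                    continue
                if (c_read - read_start) % 3 != 2:  # -1 frame relative to host
                    continue
                if c_read < read_start + len(cds):  # overlaps host 3' region
                    partner = cand
                    break
            if partner is None:
                continue
            pos = host.start + r if host.strand == "+" else host.end - r - 7
            sites.append(
                SlipperySite(
                    genome_id=genome.id,
                    heptamer=hept,
                    codon_index_in_orf=codon,
                    codons_before_stop=n_trans - (codon + 2),
                    host_orf_id=host.orf_id,
                    downstream_orf_id=partner.orf_id,
                    pos=pos,
                    strand=host.strand,
                )
            )
    return sites


def rescue_overlooked_orfs(
    genome: GenomeRecord,
    existing: list[OrfRecord],
    pangenome,
    ref_orf_sets: dict[str, list[OrfRecord]],
    evalue_max: float = 1e-05,
    min_gap: int = 100,
    min_codons: int = 34,
) -> list[OrfRecord]:
    """Recover ORFs missing from an annotation, using family synteny.

    For every annotation gap of >= ``min_gap`` nt whose flanking ORFs
    belong to core ortholog groups, candidate ORFs called inside the gap
    are aligned against the ORFs that reference genomes carry in the
    syntenic slot (between their own members of the two flanking groups).
    Candidates matching at e-value <= ``evalue_max`` are returned flagged
    ``rescued``. A candidate overlapping an existing same-strand
    annotation by more than 30 nt is never emitted.
    """
    from .align import evalue, sw_protein

    existing = sorted(existing, key=lambda o: o.start)
    group_of = pangenome.group_of
    group_size = {
        g.group_id: len(g.members) for g in pangenome.groups
    }

    candidates = find_orfs(genome, min_codons=min_codons)
    rescued: list[OrfRecord] = []
    for left, right in zip(existing, existing[1:]):
        gap_start, gap_end = left.end, right.start
        if gap_end - gap_start < min_gap:
            continue
        gl, gr = group_of(left.orf_id), group_of(right.orf_id)
        # flanks must have homologs elsewhere, or no syntenic slot exists
        if group_size.get(gl, 0) < 2 or group_size.get(gr, 0) < 2:
            continue
        # reference ORFs occupying the syntenic slot in other genomes
        slot_refs: list[OrfRecord] = []
        for rid, rorfs in ref_orf_sets.items():
            if rid == genome.id:
                continue
            lm = next((o for o in rorfs if group_of(o.orf_id) == gl), None)
            rm = next((o for o in rorfs if group_of(o.orf_id) == gr), None)
            if lm is None or rm is None:
                continue
            lo, hi = sorted((lm.end, rm.start))
            slot_refs.extend(
                o for o in rorfs if lo - 30 <= o.start and o.end <= hi + 30
            )
        if not slot_refs:
            continue
        db_len = sum(len(o.translation) for o in slot_refs)
        for cand in candidates:
            if not (gap_start - 30 <= cand.start and cand.end <= gap_end + 30):
                continue
            clash = any(
                o.strand == cand.strand
                and min(cand.end, o.end) - max(cand.start, o.start) > 30
                for o in existing
            )
            if clash:
                continue
            best_e = min(
                (
                    evalue(
                        sw_protein(cand.translation, ref.translation).score,
                        len(cand.translation),
                        db_len,
                    )
                    for ref in slot_refs
                ),
                default=float("inf"),
            )
            if best_e <= evalue_max:
                cand.rescued = True
                rescued.append(cand)
    # deduplicate (a candidate can sit in one gap only, but be safe)
    seen = set()
    out = []
    for o in rescued:
        if o.orf_id not in seen:
            seen.add(o.orf_id)
            out.append(o)
    return out
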