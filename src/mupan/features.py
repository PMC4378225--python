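"""Genome-architecture feature detectors.

Transposable phages package their genomes with the conserved triplet
5'-TGT at both ends, three tandem imperfect 22-bp transposase-binding
repeats just inside each terminus (the innermost right-end repeat
inverted), and a stretch of random host DNA outside the TGT boundaries
-- a relic of replication by transposition. The detectors here locate
the TGT boundaries (by cross-genome terminal agreement when a family is
given), trim the host flanks, find the repeat triples against a family
consensus, flag incomplete deposits, and profile GC content to relate
low-GC valleys to accessory insertions.

All detectors treat the right end by reverse-complementing and reusing
the left-end logic, which makes reverse-complement symmetry (swap of
L/R roles with preserved offsets) hold by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GenomeRecord, OrfRecord, revcomp

REPEAT_LEN = 22
TGT_RE = re.compile(r"(?=TGT)")


@dataclass
class Termini:
    genome_id: str
    left_tgt: bool
    right_tgt: bool
    left_pos: int          # start of the left TGT (0 if absent)
    right_pos: int         # end of the packaged genome (len if absent)
    flank_left: str
    flank_right: str


@dataclass
class RepeatSite:
    genome_id: str
    name: str              # L1..L3 / R1..R3
    offset_bp: int         # genome end to the repeat's nearest edge
    length_bp: int
    orientation: str       # {"direct", "inverted"}
    mismatches_vs_consensus: int
    start: int             # forward-strand span, for verification
    end: int


@dataclass
class GcProfile:
    genome_id: str
    window_bp: int
    step_bp: int
    values: np.ndarray     # GC fraction per window
    starts: np.ndarray     # window start coordinates


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _left_candidates(seq: str, window: int) -> list[int]:
    return [m.start() for m in TGT_RE.finditer(seq[:window])]


def _left_boundary(
    seq: str,
    other_windows: list[str],
    window: int = 200,
    probe_len: int = 40,
    max_mismatch_frac: float = 0.2,
) -> int | None:
    """Left TGT boundary by cross-genome terminal agreement.

    Scans TGT occurrences in the first ``window`` bp; the boundary is the
    candidate whose following ``probe_len`` bp match (<=20% mismatches) a
    TGT-candidate region in the largest number of other genomes. Host
    flanks are genome-specific noise and cannot win. With no other
    genomes the rule degenerates to an exact end match (boundary 0).
    """
    if not other_windows:
        return 0 if seq.startswith("TGT") else None
    limit = int(probe_len * max_mismatch_frac)
    best: tuple[int, int] | None = None  # (score, -pos)
    for p in _left_candidates(seq, window):
        probe = seq[p : p + probe_len]
        if len(probe) < probe_len:
            continue
        score = 0
        for ow in other_windows:
            for q in _left_candidates(ow, window):
                if _hamming(probe, ow[q : q + probe_len]) <= limit:
                    score += 1
                    break
        if score and (best is None or score > best[0] or
                      (score == best[0] and -p > best[1])):
            best = (score, -p)
    return -best[1] if best else None


def detect_termini(
    genome: GenomeRecord,
    family: list[GenomeRecord] | None = None,
    window: int = 200,
) -> Termini:
    """Locate the 5'-TGT packaging boundaries and any host flanks.

    The right end is analysed as the left end of the reverse complement.
    Absent boundaries set the flag false and leave that end untrimmed.
    """
    others = [g for g in (family or []) if g.id != genome.id]
    fwd_windows = [g.seq[: window + 60] for g in others]
    rev_windows = [revcomp(g.seq)[: window + 60] for g in others]

    left = _left_boundary(genome.seq, fwd_windows, window)
    rc = revcomp(genome.seq)
    right_rc = _left_boundary(rc, rev_windows, window)

    n = genome.length_bp
    left_pos = left if left is not None else 0
    right_pos = n - right_rc if right_rc is not None else n
    return Termini(
        genome_id=genome.id,
        left_tgt=left is not None,
        right_tgt=right_rc is not None,
        left_pos=left_pos,
        right_pos=right_pos,
        flank_left=genome.seq[:left_pos] if left is not None else "",
        flank_right=genome.seq[right_pos:] if right_rc is not None else "",
    )


def trim_host_flanks(genome: GenomeRecord, termini: Termini) -> GenomeRecord:
    """Cut the genome to its packaging boundaries (starts with TGT).

    With both boundary flags false the input is returned unchanged (a
    warning case for the caller); trimming is idempotent.
    """
    if not (termini.left_tgt or termini.right_tgt):
        return genome
    seq = genome.seq[termini.left_pos : termini.right_pos]
    return GenomeRecord(
        id=genome.id,
        seq=seq,
        source=genome.source,
        complete_left=genome.complete_left,
        complete_right=genome.complete_right,
    )


# ---------------------------------------------------------------------------
# terminal transposase-binding repeats


def _best_triple(window_seq: str, motif_len: int, max_mismatch: int):
    """Mutually similar non-overlapping 22-mer triple (orientation-free).

    Returns (positions, oriented sequences) minimising total pairwise
    distance, or None. Distance between two sites is the better of the
    direct and reverse-complement comparison.
    """
    kmers = [
        window_seq[i : i + motif_len]
        for i in range(len(window_seq) - motif_len + 1)
    ]
    n = len(kmers)
    if n == 0:
        return None

    def dist(i: int, j: int) -> tuple[int, bool]:
        d_dir = _hamming(kmers[i], kmers[j])
        d_inv = _hamming(kmers[i], revcomp(kmers[j]))
        return (d_dir, False) if d_dir <= d_inv else (d_inv, True)

    best = None
    # pairs first: cubic enumeration over qualifying pairs stays tiny
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + motif_len, n)
        if dist(i, j)[0] <= max_mismatch
    ]
    for i, j in pairs:
        for k in range(j + motif_len, n):
            dij, dik, djk = dist(i, j)[0], dist(i, k)[0], dist(j, k)[0]
            if dik <= max_mismatch and djk <= max_mismatch:
                total = dij + dik + djk
                if best is None or total < best[0]:
                    best = (total, (i, j, k))
    if best is None:
        return None
    i, j, k = best[1]
    seqs = [kmers[i]]
    for idx in (j, k):
        _, inv = dist(i, idx)
        seqs.append(revcomp(kmers[idx]) if inv else kmers[idx])
    return (i, j, k), seqs


def _column_consensus(seqs: list[str]) -> str:
    cols = []
    for col in zip(*seqs):
        counts = sorted(
            ((col.count(b), b) for b in "ACGT"), key=lambda t: (-t[0], t[1])
        )
        cols.append(counts[0][1])
    return "".join(cols)


def repeat_consensus(
    genomes: list[GenomeRecord],
    motif_len: int = REPEAT_LEN,
    search_window: int = 200,
    max_mismatch: int = 6,
) -> str | None:
    """Family consensus of the terminal repeat motif.

    Every terminal window's mutually-similar triple proposes a candidate
    (its column-majority consensus); the candidate explaining the family
    best -- most qualifying sites over all terminal windows, then fewest
    total mismatches -- wins. A coincidentally self-consistent *shifted*
    triple in one window loses this vote because it misfits every other
    window by a full register. Finally the winner is oriented so the
    majority of family sites (in forward-strand sense) read it directly.
    """
    windows = []
    for g in genomes:
        windows.append(("left", g.seq[:search_window]))
        windows.append(("right", revcomp(g.seq)[:search_window]))

    candidates: dict[str, None] = {}
    for _, window_seq in windows:
        triple = _best_triple(window_seq, motif_len, max_mismatch)
        if triple:
            cons = _column_consensus(triple[1])
            candidates[min(cons, revcomp(cons))] = None
    if not candidates:
        return None

    _score_cache: dict[str, tuple[int, int, int]] = {}

    def score(cand: str):
        if cand in _score_cache:
            return _score_cache[cand]
        n_sites = 0
        total_mm = 0
        direct_votes = 0
        for end, window_seq in windows:
            for _, orient, mm in _scan_end(window_seq, cand, motif_len, max_mismatch):
                n_sites += 1
                total_mm += mm
                # forward-strand sense: right windows are scanned on the
                # reverse strand, so their orientation flips in reporting
                if (orient == "direct") == (end == "left"):
                    direct_votes += 1
        _score_cache[cand] = (n_sites, total_mm, direct_votes)
        return n_sites, total_mm, direct_votes

    best = max(
        sorted(candidates),
        key=lambda c: (score(c)[0], -score(c)[1], c),
    )
    n_sites, _, direct_votes = score(best)
    if direct_votes * 2 < n_sites:
        best = revcomp(best)
    return best


def _scan_end(
    window_seq: str,
    consensus: str,
    motif_len: int,
    max_mismatch: int,
) -> list[tuple[int, str, int]]:
    """Qualifying sites in one terminal window: (offset, orientation, mm)."""
    sites = []
    for i in range(len(window_seq) - motif_len + 1):
        w = window_seq[i : i + motif_len]
        d_dir = _hamming(w, consensus)
        d_inv = _hamming(revcomp(w), consensus)
        d = min(d_dir, d_inv)
        if d <= max_mismatch:
            sites.append((i, "direct" if d_dir <= d_inv else "inverted", d))
    # suppress overlapping shifted self-matches: keep local best
    sites.sort(key=lambda t: (t[2], t[0]))
    chosen: list[tuple[int, str, int]] = []
    for s in sites:
        if all(abs(s[0] - c[0]) >= motif_len for c in chosen):
            chosen.append(s)
    return sorted(chosen)[:3]


def find_terminal_repeats(
    genome: GenomeRecord,
    family: list[GenomeRecord] | None = None,
    motif_len: int = REPEAT_LEN,
    search_window: int = 200,
    max_mismatch: int = 6,
    consensus: str | None = None,
) -> tuple[list[RepeatSite], dict[str, bool]]:
    """Terminal repeat triples of one (trimmed) genome.

    Returns the sites (L1..L3 numbered outside-in on the left end, R1..R3
    on the right) and per-end flags that are False when fewer than three
    qualifying sites were found ("incomplete-repeat-set").
    """
    if consensus is None:
        consensus = repeat_consensus(
            family or [genome], motif_len, search_window, max_mismatch
        )
    if consensus is None:
        return [], {"left": False, "right": False}

    n = genome.length_bp
    out: list[RepeatSite] = []
    flags = {}
    left_sites = _scan_end(genome.seq[:search_window], consensus, motif_len, max_mismatch)
    flags["left"] = len(left_sites) == 3
    for idx, (off, orient, mm) in enumerate(left_sites, start=1):
        out.append(
            RepeatSite(genome.id, f"L{idx}", off, motif_len, orient, mm,
                       start=off, end=off + motif_len)
        )
    right_sites = _scan_end(
        revcomp(genome.seq)[:search_window], consensus, motif_len, max_mismatch
    )
    flags["right"] = len(right_sites) == 3
    for idx, (off, orient, mm) in enumerate(right_sites, start=1):
        # the scan reads the reverse strand; report forward-strand sense
        fwd_orient = "inverted" if orient == "direct" else "direct"
        out.append(
            RepeatSite(genome.id, f"R{idx}", off, motif_len, fwd_orient, mm,
                       start=n - off - motif_len, end=n - off)
        )
    return out, flags


def flag_completeness(
    genome: GenomeRecord,
    termini: Termini,
    repeats: list[RepeatSite],
) -> tuple[bool, bool]:
    """An end is complete iff its TGT is present and >=2 repeats found."""
    n_left = sum(r.name.startswith("L") for r in repeats)
    n_right = sum(r.name.startswith("R") for r in repeats)
    return (termini.left_tgt and n_left >= 2, termini.right_tgt and n_right >= 2)


# ---------------------------------------------------------------------------
# GC profiling


def gc_profile(genome: GenomeRecord, window: int = 500, step: int = 50) -> GcProfile:
    """Sliding-window GC fractions; N excluded from both numerator and
    denominator."""
    n = genome.length_bp
    if window > n:
        raise ValueError(f"window {window} exceeds genome length {n}")
    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
    is_acgt = (arr != ord("N")).astype(np.int32)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])
    starts = np.arange(0, n - window + 1, step)
    gc = cum_gc[starts + window] - cum_gc[starts]
    ok = cum_ok[starts + window] - cum_ok[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(ok > 0, gc / np.maximum(ok, 1), 0.0)
    return GcProfile(genome.id, window, step, values, starts)


def detect_valleys(profile: GcProfile, threshold: float = 0.55) -> list[tuple[int, int]]:
    """Maximal runs of below-threshold windows, as nt intervals."""
    below = profile.values < threshold
    valleys = []
    run_start = None
    for i, flag in enumerate(below):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            valleys.append((int(profile.starts[run_start]),
                            int(profile.starts[i - 1]) + profile.window_bp))
            run_start = None
    if run_start is not None:
        valleys.append((int(profile.starts[run_start]),
                        int(profile.starts[-1]) + profile.window_bp))
    return valleys


def rgp_gc_overlap(
    rgps,
    valleys_by_genome: dict[str, list[tuple[int, int]]],
    orf_sets: dict[str, list[OrfRecord]],
) -> pd.DataFrame:
    """Per RGP per genome: does the locus interval intersect a GC valley?"""
    orf_by_id = {o.orf_id: o for orfs in orf_sets.values() for o in orfs}
    rows = []
    for locus in rgps:
        for gid, oids in locus.content.items():
            if not oids:
                continue
            lo = min(orf_by_id[o].start for o in oids)
            hi = max(orf_by_id[o].end for o in oids)
            overlap = any(
                lo < ve and vs < hi for vs, ve in valleys_by_genome.get(gid, [])
            )
            rows.append(
                {"locus": locus.label, "genome_id": gid, "start": lo,
                 "end": hi, "valley_overlap": overlap}
            )
    return pd.DataFrame(rows, columns=["locus", "genome_id", "start", "end",
                                       "valley_overlap"])
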