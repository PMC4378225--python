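"""Pairwise alignment engines behind all homology calls.

Protein local alignment uses BLOSUM62 with BLAST-style affine gaps
(open 11, extend 1; a gap of length k costs 11 + k) via Biopython's
PairwiseAligner, with Karlin-Altschul statistics at the standard gapped
BLOSUM62 parameters (K=0.041, lambda=0.267) supplying e-values. The X
residue scores 0 against everything, so ambiguity neither helps nor
hurts a hit.

Whole-genome nucleotide identity follows the anchored-alignment recipe
of MUMmer-class tools: unique shared k-mers (k=15) are chained
colinearly, inter-anchor gaps up to 2 kb are closed by global alignment
(edlib), and identity is computed over the aligned columns of the chain.
Unaligned regions are excluded from identity but reported through
``aligned_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import GenomeRecord, revcomp

KA_K = 0.041
KA_LAMBDA = 0.267
GAP_OPEN = 11
GAP_EXTEND = 1

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    query_cov: float
    subject_cov: float
    evalue: float
    aligned_cols: int = 0


@dataclass
class GenomeIdentity:
    genome_a: str
    genome_b: str
    ani_pct: float
    aligned_fraction: float


@lru_cache(maxsize=1)
def _blosum62_x0():
    m = substitution_matrices.load("BLOSUM62")
    m = m.copy()
    xi = m.alphabet.index("X")
    m[xi, :] = 0.0
    m[:, xi] = 0.0
    return m


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _blosum62_x0()
    # BLAST convention: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)!r}")


def sw_score(a: str, b: str) -> float:
    """Optimal local alignment score only (cheaper than a full traceback)."""
    _check_protein(a, "query")
    _check_protein(b, "subject")
    return _aligner().score(a, b)


def sw_protein(a: str, b: str, query_id: str = "query",
               subject_id: str = "subject") -> AlignmentHit:
    """Optimal local protein alignment with identity and coverage.

    The e-value field is filled with the pairwise statistic
    ``evalue(score, len(a), len(b))``; screening against a database
    should recompute it with the database length as ``n``.
    """
    _check_protein(a, "query")
    _check_protein(b, "subject")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    aligned_cols = counts.aligned + counts.gaps
    identities = counts.identities
    qa = sum(e - s for s, e in aln.aligned[0])
    sa = sum(e - s for s, e in aln.aligned[1])
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=aln.score,
        identity_pct=100.0 * identities / aligned_cols if aligned_cols else 0.0,
        query_cov=qa / len(a),
        subject_cov=sa / len(b),
        evalue=evalue(aln.score, len(a), len(b)),
        aligned_cols=aligned_cols,
    )


def evalue(score: float, m: int, n: int, K: float = KA_K,
           lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expected number of chance hits, E = K m n e^(-lam S).

    ``m`` and ``n`` are the effective query and subject/database lengths;
    when screening a set, pass n = sum of subject lengths.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return float(K * m * n * np.exp(-lam * score))


# ---------------------------------------------------------------------------
# whole-genome anchored identity


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def _colinear_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing positions in both genomes.

    Patience-sorting LIS on the second coordinate after sorting by the
    first; O(n log n), deterministic.
    """
    if not pairs:
        return []
    pairs = sorted(pairs)
    import bisect

    tails: list[int] = []          # smallest possible tail b-coordinate
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_, b) in enumerate(pairs):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(pairs[i])
        i = parent[i]
    return chain[::-1]


def _gap_alignment_stats(a: str, b: str) -> tuple[int, int]:
    """(identical columns, total columns) of a global alignment of a vs b."""
    if not a and not b:
        return 0, 0
    if not a or not b:
        return 0, max(len(a), len(b))
    res = edlib.align(a, b, mode="NW", task="path")
    matches = cols = 0
    for num, op in __import__("re").findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
    return matches, cols


def genome_identity(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    k: int = 15,
    max_gap: int = 2000,
) -> GenomeIdentity:
    """Average nucleotide identity over an anchored colinear alignment.

    Unique shared k-mers anchor a longest colinear chain; inter-anchor
    gaps of <= ``max_gap`` nt (and the terminal overhangs) are closed by
    global alignment, larger ones are excluded from the identity but
    depress ``aligned_fraction`` (fraction of the shorter genome inside
    aligned columns). No shared anchors yields identity 0, not an error.

    The computation canonicalises the input pair (order by id, orientation
    by the first genome), so the statistic is symmetric and invariant
    under reverse-complementing both genomes.
    """
    if min(genome_a.length_bp, genome_b.length_bp) < k:
        raise ValueError(f"genomes must be at least k={k} bp")
    ga, gb = sorted((genome_a, genome_b), key=lambda g: (g.id, g.seq))
    sa, sb = ga.seq, gb.seq
    if revcomp(sa) < sa:
        sa, sb = revcomp(sa), revcomp(sb)

    ka = _unique_kmer_positions(sa, k)
    kb = _unique_kmer_positions(sb, k)
    pairs = [(ia, kb[km]) for km, ia in ka.items() if km in kb]
    chain = _colinear_chain(pairs)
    if not chain:
        return GenomeIdentity(genome_a.id, genome_b.id, 0.0, 0.0)

    # thin the chain to non-overlapping anchors; the inter-anchor closure
    # below restores continuity for anchors that overlapped on a diagonal
    thinned: list[tuple[int, int]] = []
    for ia, ib in chain:
        if not thinned or (ia >= thinned[-1][0] + k and ib >= thinned[-1][1] + k):
            thinned.append((ia, ib))

    matches = 0
    cols = 0
    covered_short = 0
    short_len = min(len(sa), len(sb))

    def close_gap(a_lo, a_hi, b_lo, b_hi):
        nonlocal matches, cols, covered_short
        if a_hi - a_lo > max_gap or b_hi - b_lo > max_gap:
            return
        m, c = _gap_alignment_stats(sa[a_lo:a_hi], sb[b_lo:b_hi])
        matches += m
        cols += c
        covered_short += min(a_hi - a_lo, b_hi - b_lo)

    first_a, first_b = thinned[0]
    close_gap(max(0, first_a - max_gap), first_a, max(0, first_b - max_gap), first_b)
    prev_a = prev_b = None
    for ia, ib in thinned:
        if prev_a is not None:
            close_gap(prev_a, ia, prev_b, ib)
        matches += k
        cols += k
        covered_short += k
        prev_a, prev_b = ia + k, ib + k
    close_gap(prev_a, min(len(sa), prev_a + max_gap),
              prev_b, min(len(sb), prev_b + max_gap))

    ani = 100.0 * matches / cols if cols else 0.0
    return GenomeIdentity(
        genome_a.id, genome_b.id, ani, min(1.0, covered_short / short_len)
    )
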