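"""Synthetic Mu-like phage families with planted architecture and truth tables.

The generator emits families of ~37 kb genomes that reproduce the
architecture of *P. aeruginosa* transposable (Mu-like) phages:

* a conserved ORF backbone (core genome) at ~64% GC, split into two
  similarity clades descended from a common ancestor;
* regions of genomic plasticity (RGPs) between fixed backbone anchors,
  carrying short (34-100 codon) accessory ORFs, some at ~46% GC;
* 5'-TGT triplets at both packaged termini, with 50-100 nt of random
  host DNA outside them;
* three tandem imperfect 22-bp transposase-binding repeats per end
  (offsets 10/93/124 bp on the left, 4/46/93 bp on the right, the
  innermost right repeat inverted);
* one -1 programmed frameshift cassette: a T TTT TTC slippery heptamer
  at codons 116-118 of a designated tail gene, 43 codons before its
  stop, with an overlapping -1-frame partner ORF;
* one internal in-frame start (GTG = Val) at codon 177 of a designated
  head-protease gene, preceded by the Shine-Dalgarno ACGAGGA at a 9-nt
  spacer.

Every emitted ORF, repeat, flank, slippery site and internal start is
recorded in a :class:`TruthSet` so downstream stages have exact
parameter-recovery targets. Functional sites (start/stop codons, SD
motifs, the heptamer, terminal repeats, termini) are exempt from
substitution, and substitutions that would create premature in-frame
stops are reverted -- the generator's stand-in for purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import GenomeRecord, OrfRecord, assign_ranks, revcomp, translate_cds

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}

#: default 22-bp transposase-binding repeat motif (64% GC)
DEFAULT_REPEAT_MOTIF = "TGCAGCCGGTTAACGGCGCATC"

LEFT_REPEAT_OFFSETS = (10, 93, 124)
RIGHT_REPEAT_OFFSETS = (4, 46, 93)
REPEAT_LEN = 22

SD_CORE = "AGGAGG"


class ConfigError(ValueError):
    pass


@dataclass
class RgpSpec:
    """One region of genomic plasticity in the planted layout.

    ``anchor_after`` is the 1-based core backbone index the locus follows
    (it sits between core ``anchor_after`` and ``anchor_after + 1``).
    When a genome carries the locus (probability ``p_insert``) it receives
    between ``k_range[0]`` and ``k_range[1]`` accessory ORF types drawn
    from the locus pool of ``n_types`` types.
    """

    label: str
    anchor_after: int
    n_types: int = 1
    p_insert: float = 0.5
    low_gc: bool = False
    k_range: tuple[int, int] | None = None

    def effective_k_range(self) -> tuple[int, int]:
        if self.k_range is not None:
            return self.k_range
        return (1, min(5, self.n_types))


def study_rgp_layout() -> list[RgpSpec]:
    """The nine-locus A-I layout emulating the published pangenome map.

    28 accessory ORF types in total; loci C and G are multi-ORF clusters,
    F and G carry low-GC (recently acquired) cargo; the H locus sits
    between the protease-scaffold and major-head backbone genes.
    """
    return [
        RgpSpec("A", anchor_after=2, n_types=1, p_insert=0.5),
        RgpSpec("B", anchor_after=5, n_types=1, p_insert=0.5),
        RgpSpec("C", anchor_after=10, n_types=6, p_insert=0.9, k_range=(1, 4)),
        RgpSpec("D", anchor_after=15, n_types=2, p_insert=0.5, k_range=(1, 2)),
        RgpSpec("E", anchor_after=20, n_types=1, p_insert=0.5),
        RgpSpec("F", anchor_after=23, n_types=4, p_insert=0.5, low_gc=True,
                k_range=(1, 2)),
        RgpSpec("G", anchor_after=25, n_types=9, p_insert=0.9, low_gc=True,
                k_range=(1, 4)),
        RgpSpec("H", anchor_after=27, n_types=1, p_insert=0.5),
        RgpSpec("I", anchor_after=40, n_types=3, p_insert=0.5, k_range=(1, 2)),
    ]


@dataclass
class GroupSplit:
    """Two-level divergence model: a balanced two-clade family tree.

    ``within_rate`` is the per-site substitution rate on each leaf branch,
    ``between_rate`` the rate on each clade-ancestor branch. The defaults
    put the anchored-alignment nucleotide identity of an intra-clade
    genome pair (substitutions plus the indel columns of their accessory
    differences) at ~87%, the value reported for the family's index
    pair, and between-clade identity near 75-80%.
    """

    within_rate: float = 0.048
    between_rate: float = 0.06


@dataclass
class FamilyConfig:
    n_genomes: int = 12
    n_core: int = 47
    rgp_layout: list[RgpSpec] = field(default_factory=study_rgp_layout)
    core_codons_range: tuple[int, int] = (130, 340)
    accessory_codons_range: tuple[int, int] = (34, 100)
    backbone_gc: float = 0.64
    accessory_gc: float = 0.46
    group_split: GroupSplit = field(default_factory=GroupSplit)
    repeat_motif: str = DEFAULT_REPEAT_MOTIF
    flank_len_range: tuple[int, int] = (50, 100)
    seed: int = 0
    #: 1-based core index of the tail gene carrying the slippery site;
    #: its -1-frame partner is the next core index.
    slippery_core_index: int = 35
    #: 1-based core index of the protease gene with the internal start.
    internal_start_core_index: int = 27
    #: genome indices (0-based) to truncate at the left end, emulating
    #: incompletely deposited prophages.
    truncate_left: tuple[int, ...] = ()
    truncate_bp: int = 2000

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        if self.n_core < 1:
            raise ConfigError("n_core must be >= 1")
        for spec in self.rgp_layout:
            if not (0.0 <= spec.p_insert <= 1.0):
                raise ConfigError(f"RGP {spec.label}: p_insert outside [0,1]")
            if not (1 <= spec.anchor_after < self.n_core):
                raise ConfigError(
                    f"RGP {spec.label}: anchor_after {spec.anchor_after} "
                    f"not between two core indices (n_core={self.n_core})"
                )
            if spec.anchor_after == self.effective_slippery_index():
                raise ConfigError(
                    f"RGP {spec.label}: cannot insert inside the overlapping "
                    "frameshift gene pair"
                )
        for rate in (self.group_split.within_rate, self.group_split.between_rate):
            if rate < 0:
                raise ConfigError("substitution rates must be >= 0")
        if len(self.repeat_motif) != REPEAT_LEN:
            raise ConfigError(f"repeat_motif must be {REPEAT_LEN} bp")

    def effective_slippery_index(self) -> int | None:
        """Core index hosting the slippery site, fitted to small backbones."""
        if self.n_core < 4:
            return None
        return min(self.slippery_core_index, self.n_core - 1)

    def effective_internal_index(self) -> int | None:
        if self.n_core < 4:
            return None
        idx = min(self.internal_start_core_index, self.n_core - 3)
        slip = self.effective_slippery_index()
        if idx in (slip, slip + 1):
            idx = max(1, slip - 2)
        return idx


@dataclass
class TruthSet:
    """Ground truth for one simulated family."""

    orfs: list[dict]                    # genome_id, orf_id, start, end, strand, label, kind
    rgp_loci: list[tuple[str, int, int]]  # label, left core index, right core index
    rgp_content: dict                   # (genome_id, label) -> list of type labels
    repeats: list[dict]                 # genome_id, name, offset_bp, orientation, start, end
    slippery: dict | None               # genome-invariant planted coordinates
    internal_start: dict | None
    flanks: dict                        # genome_id -> (left flank seq, right flank seq)
    clades: tuple[list[str], list[str]]
    tree_newick: str
    trimmed_span: dict                  # genome_id -> (start, end) of the packaged genome


# ---------------------------------------------------------------------------
# low-level sequence sampling


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _compensate_gc(target: float, rates: tuple[float, ...]) -> float:
    """Ancestral GC that yields ``target`` GC at the leaves.

    Uniform substitution relaxes composition toward 0.5: one round at rate
    r maps g -> g(1 - 4r/3) + 2r/3. Inverting that map along the
    root-to-leaf rate sequence keeps emitted genomes at the configured GC.
    """
    g = target
    for r in reversed(rates):
        denom = 1.0 - 4.0 * r / 3.0
        g = (g - 2.0 * r / 3.0) / denom
    return min(max(g, 0.0), 1.0)


_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_base_probs(gc))])


def random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n random non-stop codons at the target GC."""
    out = []
    while len(out) < n:
        chunk = [
            "".join(c)
            for c in _BASES[rng.choice(4, size=(n, 3), p=_base_probs(gc))]
        ]
        out.extend(c for c in chunk if c not in STOPS)
    return "".join(out[:n])


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
) -> str:
    """Independent per-site substitution to a uniformly chosen other base.

    ``protected`` is an optional boolean mask of sites exempt from
    substitution. N sites are never mutated.
    """
    if not (0.0 <= rate <= 0.75):
        raise ValueError(f"substitution rate {rate} outside [0, 0.75]")
    if rate == 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if protected is not None:
        hit &= ~protected
    hit &= arr != "N"
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return seq
    # replacement = one of the three other bases, uniformly
    offsets = rng.integers(1, 4, size=idx.size)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, off in zip(idx, offsets):
        arr[i] = _BASES[(base_index[arr[i]] + off) % 4]
    return "".join(arr)


def _repair_stops(child: list[str], parent: str, frames: list[tuple[int, int]]) -> None:
    """Revert substitutions that created premature in-frame stop codons.

    ``frames`` lists codon-aligned half-open spans whose reading frame must
    stay open except for the final codon of the span (the real stop).
    Overlapping spans in different frames share bases, so a revert in one
    frame can compose a new chimeric stop in the other; iterating to a
    fixpoint terminates because every revert moves the child toward the
    (stop-free) parent.
    """
    changed = True
    while changed:
        changed = False
        for s, e in frames:
            for i in range(s, e - 3, 3):
                if "".join(child[i : i + 3]) in STOPS:
                    child[i : i + 3] = list(parent[i : i + 3])
                    changed = True


# ---------------------------------------------------------------------------
# piece construction


@dataclass
class _Piece:
    name: str
    seq: str
    mask: np.ndarray                       # True = protected from mutation
    orf_defs: list[tuple[int, int, str]]   # rel start, rel end, label
    frames: list[tuple[int, int]]          # codon-aligned spans kept stop-free
    locus: str | None = None               # RGP label for accessory pieces
    type_label: str | None = None


def _mask(n: int) -> np.ndarray:
    return np.zeros(n, dtype=bool)


def _build_linker(rng: np.random.Generator, gc: float) -> str:
    """Intergenic linker placed immediately before an ORF start.

    Layout (3' to 5' of the downstream gene): a Shine-Dalgarno AGGAGG at a
    6-10 nt spacer, and an in-frame stop codon upstream of it so the ORF
    caller's maximal open reading frame begins inside the linker. All
    in-frame start triplets between that stop and the true start are
    scrubbed, making the planted start the most upstream SD-bearing
    candidate.
    """
    spacer_len = int(rng.integers(6, 11))
    tail_len = len(SD_CORE) + spacer_len
    mid_len = int(rng.integers(3, 9))
    mid_len += (-(mid_len + tail_len)) % 3  # stop codon must sit in frame
    front_len = int(rng.integers(3, 10))
    # leading TC: pyrimidine start prevents 3' SD extension, and cannot
    # complete a GTG start codon across the SD boundary (which the start
    # scrub below would otherwise repair by mutating the SD itself)
    spacer = "TC" + random_dna(rng, spacer_len - 2, gc)
    linker = list(
        random_dna(rng, front_len, gc)
        + "TAA"
        + random_dna(rng, mid_len, gc)
        + SD_CORE
        + spacer
    )
    n = len(linker)
    # scrub in-frame starts between the planted stop and the ORF start
    for p in range(front_len + 3, n - 2):
        if (n - p) % 3 == 0 and "".join(linker[p : p + 3]) in STARTS:
            linker[p] = "C"
    return "".join(linker)


#: N-terminal guard codons (Leu-Thr-Asp/Glu) planted after every start:
#: they place stop codons at offsets +4 (+1 frame) and +8 (+2 frame), so
#: a shifted open frame borrowing the gene's Shine-Dalgarno terminates at
#: once instead of shadowing the real gene.
_GUARD_CODONS = "CTAACTGA"  # + one free base completes codon 4 ("GAx")


def _orf_seq(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    free = random_dna(rng, 1, gc)
    body = random_codons(rng, n_codons - 4, gc)
    return "ATG" + _GUARD_CODONS + free + body + "TAA"


def _gene_piece(
    rng: np.random.Generator,
    name: str,
    label: str,
    n_codons: int,
    gc: float,
    locus: str | None = None,
    type_label: str | None = None,
) -> _Piece:
    linker = _build_linker(rng, gc)
    orf = _orf_seq(rng, n_codons, gc)
    seq = linker + orf
    mask = _mask(len(seq))
    mask[: len(linker)] = True                         # regulatory cassette
    mask[len(linker) : len(linker) + 11] = True        # start + guard codons
    mask[-3:] = True                                   # stop codon
    span = (len(linker), len(seq))
    return _Piece(name, seq, mask, [(span[0], span[1], label)], [span],
                  locus=locus, type_label=type_label)


def _set(seq: list[str], pos: int, bases: str) -> None:
    seq[pos : pos + len(bases)] = list(bases)


# planted coordinates of the -1 frameshift cassette, relative to the host
# ORF start: heptamer T TTT TTC occupying codons 116-118 (first base = third
# base of codon 116), partner ATG 3 nt downstream in the -1 frame.
SLIP_HOST_CODONS = 161
SLIP_CODON = 116
SLIP_HEPT_OFF = (SLIP_CODON - 1) * 3 + 2        # 347
SLIP_PARTNER_OFF = SLIP_HEPT_OFF + 9            # 356, ≡ -1 frame
SLIP_PARTNER_CODONS = 120

# planted internal translational start: GTG (Val) at codon 177 preceded by
# ACGAGGA at a 9-nt spacer.
INT_HOST_CODONS = 250
INT_CODON = 177
INT_GTG_OFF = (INT_CODON - 1) * 3               # 528
INT_SD_OFF = INT_GTG_OFF - 9 - 7                # 512


def _frameshift_piece(rng: np.random.Generator, gc: float,
                      host_label: str, partner_label: str) -> _Piece:
    """Tail-gene pair joined by a -1 programmed frameshift.

    The host ORF carries the slippery heptamer at codons 116-118; the
    partner ORF starts 3 nt past the heptamer in the -1 frame, overlapping
    the host's 3' region, and runs past the host stop. A stop codon and a
    Shine-Dalgarno are planted in the partner frame inside the host so the
    ORF caller recovers the partner start exactly.
    """
    linker = _build_linker(rng, gc)
    host_span = (SLIP_HOST_CODONS + 1) * 3       # 486, stop included
    partner_end = SLIP_PARTNER_OFF + SLIP_PARTNER_CODONS * 3 + 3  # 719
    tail_codons = -(-(partner_end - host_span) // 3)  # ceil; truncated below
    orf = list(_orf_seq(rng, SLIP_HOST_CODONS, gc)
               + random_codons(rng, tail_codons, gc))
    orf = orf[:partner_end]

    _set(orf, 334, "TGA")                # +1-frame stop: blocks shifted
                                         # frames from shadowing the partner
    _set(orf, 337, SD_CORE)              # partner SD, spacer 13
    _set(orf, 343, "C")                  # pyrimidine: blocks 3' SD extension
    _set(orf, 344, "TGA")                # partner-frame stop before its start
    _set(orf, 347, "TTTTTTC")            # slippery heptamer, codons 116-118
    _set(orf, 354, "GC")                 # codon 119 = GCA-safe junction
    _set(orf, 356, "ATG")                # partner start, -1 frame
    _set(orf, 359, "C")                  # codon 120 = TGC (no TGA)
    # host codons after the cassette must not have been turned into stops
    for i in range(333, 360, 3):
        if "".join(orf[i : i + 3]) in STOPS:
            orf[i + 2] = "C"
    # keep the partner frame open through the overlap and the tail
    for p in range(SLIP_PARTNER_OFF + 3, partner_end - 3, 3):
        if "".join(orf[p : p + 3]) in STOPS:
            orf[p] = "C"  # C never yields a stop in either frame
    _set(orf, partner_end - 3, "TAA")
    # the partner stop must not break the host frame (it lies past the host)
    seq = linker + "".join(orf)
    mask = _mask(len(seq))
    mask[: len(linker)] = True
    lo = len(linker)
    mask[lo : lo + 11] = True  # start + guard codons
    mask[lo + 333 : lo + 362] = True     # SD + stop + heptamer + partner start
    mask[lo + host_span - 3 : lo + host_span] = True
    mask[lo + partner_end - 3 : lo + partner_end] = True
    host = (lo, lo + host_span, host_label)
    partner = (lo + SLIP_PARTNER_OFF, lo + partner_end, partner_label)
    frames = [(host[0], host[1]), (partner[0], partner[1])]
    return _Piece("frameshift_unit", seq, mask, [host, partner], frames)


def _internal_start_piece(rng: np.random.Generator, gc: float, label: str) -> _Piece:
    """Protease-like gene with an internal SD-driven in-frame start."""
    piece = _gene_piece(rng, f"core_{label}", label, INT_HOST_CODONS, gc)
    lo = piece.orf_defs[0][0]
    seq = list(piece.seq)
    _set(seq, lo + 510, "C")             # codon 171 ends in A: avoid TAA/TGA
    _set(seq, lo + INT_SD_OFF, "ACGAGGA")
    # two pyrimidines open the spacer: no 3' SD extension, and no shifted
    # window can tie the planted match score
    _set(seq, lo + 519, "CT")
    # no in-frame start codons inside the spacer: the planted codon is
    # the unique internal start served by this SD
    for i in (lo + 522, lo + 525):
        if "".join(seq[i : i + 3]) in STARTS:
            seq[i] = "C"
    _set(seq, lo + INT_GTG_OFF, "GTG")   # Val codon 177
    for i in range(lo + 510, lo + 532, 3):
        if "".join(seq[i : i + 3]) in STOPS:
            seq[i + 2] = "C"
    piece.seq = "".join(seq)
    piece.mask[lo + 510 : lo + 532] = True
    return piece


#: palindromic 12-mer carrying stop codons in all six reading frames;
#: interleaved with the terminal repeats so the (conserved, non-coding)
#: terminus cannot present a long open frame to the ORF caller
STOP_WALL = "TTAATTAATTAA"


def _terminus_pieces(rng: np.random.Generator, cfg: FamilyConfig,
                     gc: float) -> tuple[_Piece, _Piece]:
    motif = cfg.repeat_motif
    left = list(
        "TGT" + random_dna(rng, 7, gc) + motif
        + random_dna(rng, 24, gc) + STOP_WALL + random_dna(rng, 25, gc)
        + motif + random_dna(rng, 9, gc) + motif
        + random_dna(rng, 4, gc) + STOP_WALL + random_dna(rng, 4, gc)
    )
    lmask = _mask(len(left))
    lmask[0:3] = True
    lmask[56:68] = True                      # stop wall between L1 and L2
    lmask[150:162] = True                    # stop wall after L3
    for off in LEFT_REPEAT_OFFSETS:
        lmask[off : off + REPEAT_LEN] = True
    right = list(
        random_dna(rng, 4, gc) + STOP_WALL + random_dna(rng, 4, gc) + motif
        + random_dna(rng, 6, gc) + STOP_WALL + random_dna(rng, 7, gc) + motif
        + random_dna(rng, 20, gc) + revcomp(motif) + random_dna(rng, 1, gc) + "ACA"
    )
    rmask = _mask(len(right))
    rmask[-3:] = True
    rmask[4:16] = True                       # stop wall before R3
    rmask[48:60] = True                      # stop wall between R3 and R2
    n = len(right)
    for off in RIGHT_REPEAT_OFFSETS:
        rmask[n - off - REPEAT_LEN : n - off] = True
    return (
        _Piece("left_terminus", "".join(left), lmask, [], []),
        _Piece("right_terminus", "".join(right), rmask, [], []),
    )


# ---------------------------------------------------------------------------
# family assembly


def _evolve(piece: _Piece, rate: float, rng: np.random.Generator) -> _Piece:
    child = mutate_sequence(piece.seq, rate, rng, protected=piece.mask)
    arr = list(child)
    _repair_stops(arr, piece.seq, piece.frames)
    return replace(piece, seq="".join(arr))


def simulate_family(
    config: FamilyConfig,
) -> tuple[list[GenomeRecord], dict[str, list[OrfRecord]], TruthSet]:
    """Simulate one phage family; returns genomes, true ORF sets and truth.

    Byte-identical output for a fixed config (including seed).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gids = [f"g{i+1:02d}" for i in range(cfg.n_genomes)]
    half = (cfg.n_genomes + 1) // 2
    clades = (gids[:half], gids[half:])

    slip_idx = cfg.effective_slippery_index()
    int_idx = cfg.effective_internal_index()

    # sample the ancestor hot so the mutated leaves land on the target GC
    rates = (cfg.group_split.between_rate, cfg.group_split.within_rate)
    bb_gc = _compensate_gc(cfg.backbone_gc, rates)
    acc_gc = _compensate_gc(cfg.accessory_gc, rates)

    # --- ancestral pieces, in genome order ---------------------------------
    left_term, right_term = _terminus_pieces(rng, cfg, bb_gc)
    pieces: list[_Piece] = [left_term]
    layout_by_anchor = {s.anchor_after: s for s in cfg.rgp_layout}
    rgp_truth: list[tuple[str, int, int]] = []
    core_i = 1
    while core_i <= cfg.n_core:
        label = f"core_{core_i}"
        if core_i == slip_idx:
            pieces.append(_frameshift_piece(rng, bb_gc, label,
                                            f"core_{core_i + 1}"))
            core_i += 2
        elif core_i == int_idx:
            pieces.append(_internal_start_piece(rng, bb_gc, label))
            core_i += 1
        else:
            lo_c, hi_c = cfg.core_codons_range
            n_cod = int(rng.integers(lo_c, hi_c + 1))
            pieces.append(_gene_piece(rng, label, label, n_cod, bb_gc))
            core_i += 1
        last_core = core_i - 1
        spec = layout_by_anchor.get(last_core)
        if spec is not None and last_core < cfg.n_core:
            rgp_truth.append((spec.label, last_core, last_core + 1))
            gc = acc_gc if spec.low_gc else bb_gc
            for t in range(1, spec.n_types + 1):
                lo_a, hi_a = cfg.accessory_codons_range
                n_cod = int(rng.integers(lo_a, hi_a + 1))
                tlab = f"{spec.label.lower()}{t}"
                pieces.append(
                    _gene_piece(rng, f"acc_{tlab}", tlab, n_cod, gc,
                                locus=spec.label, type_label=tlab)
                )
    pieces.append(right_term)

    # --- accessory presence draws (fixed order for determinism) ------------
    presence: dict[tuple[str, str], bool] = {}
    for spec in cfg.rgp_layout:
        lo, hi = spec.effective_k_range()
        for gid in gids:
            occupied = rng.random() < spec.p_insert
            if not occupied:
                chosen: set[int] = set()
            else:
                k = int(rng.integers(lo, hi + 1))
                chosen = set(rng.choice(spec.n_types, size=k, replace=False) + 1)
            for t in range(1, spec.n_types + 1):
                presence[(gid, f"{spec.label.lower()}{t}")] = t in chosen

    # --- evolve every piece down the two-clade tree ------------------------
    w, b = cfg.group_split.within_rate, cfg.group_split.between_rate
    leaf_pieces: dict[str, list[_Piece]] = {gid: [] for gid in gids}
    for piece in pieces:
        for clade in clades:
            clade_anc = _evolve(piece, b, rng)
            for gid in clade:
                leaf_pieces[gid].append(_evolve(clade_anc, w, rng))

    # --- assemble genomes and record truth ---------------------------------
    genomes: list[GenomeRecord] = []
    orf_sets: dict[str, list[OrfRecord]] = {}
    truth_orfs: list[dict] = []
    repeats: list[dict] = []
    flanks: dict[str, tuple[str, str]] = {}
    trimmed_span: dict[str, tuple[int, int]] = {}
    rgp_content: dict[tuple[str, str], list[str]] = {}
    slippery_truth: dict | None = None
    internal_truth: dict | None = None
    host_gc = 0.66

    for g_index, gid in enumerate(gids):
        fl = random_dna(
            rng, int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1)),
            host_gc,
        )
        fr = random_dna(
            rng, int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1)),
            host_gc,
        )
        parts: list[str] = [fl]
        pos = len(fl)
        trim_start = pos
        orfs: list[OrfRecord] = []
        n_orf = 0
        for piece in leaf_pieces[gid]:
            if piece.type_label is not None and not presence[(gid, piece.type_label)]:
                continue
            if piece.type_label is not None:
                rgp_content.setdefault((gid, piece.locus), []).append(piece.type_label)
            for rel_s, rel_e, label in piece.orf_defs:
                n_orf += 1
                oid = f"{gid}_orf{n_orf:03d}"
                start, end = pos + rel_s, pos + rel_e
                nt = piece.seq[rel_s:rel_e]
                orfs.append(
                    OrfRecord(gid, oid, start, end, "+", translate_cds(nt))
                )
                truth_orfs.append(
                    {
                        "genome_id": gid, "orf_id": oid, "start": start,
                        "end": end, "strand": "+", "label": label,
                        "kind": "core" if label.startswith("core_") else "accessory",
                        "locus": piece.locus,
                    }
                )
                if label == f"core_{slip_idx}" and slip_idx is not None:
                    slippery_truth = {
                        "heptamer": "TTTTTTC",
                        "codon_index": SLIP_CODON,
                        "codons_before_stop": SLIP_HOST_CODONS - (SLIP_CODON + 2),
                        "host_label": f"core_{slip_idx}",
                        "partner_label": f"core_{slip_idx + 1}",
                    }
                if label == f"core_{int_idx}" and int_idx is not None:
                    internal_truth = {
                        "codon_index": INT_CODON,
                        "sd_seq": "ACGAGGA",
                        "spacer_nt": 9,
                        "host_label": f"core_{int_idx}",
                    }
            parts.append(piece.seq)
            pos += len(piece.seq)
        parts.append(fr)
        seq = "".join(parts)
        trim_end = pos
        for name, off in zip(("L1", "L2", "L3"), LEFT_REPEAT_OFFSETS):
            repeats.append(
                {"genome_id": gid, "name": name, "offset_bp": off,
                 "orientation": "direct",
                 "start": trim_start + off, "end": trim_start + off + REPEAT_LEN}
            )
        for name, off in zip(("R1", "R2", "R3"), RIGHT_REPEAT_OFFSETS):
            repeats.append(
                {"genome_id": gid, "name": name, "offset_bp": off,
                 "orientation": "inverted" if name == "R1" else "direct",
                 "start": trim_end - off - REPEAT_LEN, "end": trim_end - off}
            )

        if g_index in cfg.truncate_left:
            cut = len(fl) + cfg.truncate_bp
            seq = seq[cut:]
            fl = ""
            orfs = [o for o in orfs if o.start >= cut]
            for o in orfs:
                o.start -= cut
                o.end -= cut
            truth_orfs = [
                t for t in truth_orfs
                if t["genome_id"] != gid or t["start"] >= cut
            ]
            for t in truth_orfs:
                if t["genome_id"] == gid:
                    t["start"] -= cut
                    t["end"] -= cut
            repeats = [
                r for r in repeats
                if r["genome_id"] != gid or r["name"].startswith("R")
            ]
            for r in repeats:
                if r["genome_id"] == gid:
                    r["start"] -= cut
                    r["end"] -= cut
            trim_start, trim_end = 0, trim_end - cut

        flanks[gid] = (fl, fr)
        trimmed_span[gid] = (trim_start, trim_end)
        genomes.append(GenomeRecord(id=gid, seq=seq, source="simulated"))
        orf_sets[gid] = assign_ranks(orfs)

    truth = TruthSet(
        orfs=truth_orfs,
        rgp_loci=rgp_truth,
        rgp_content=rgp_content,
        repeats=repeats,
        slippery=slippery_truth,
        internal_start=internal_truth,
        flanks=flanks,
        clades=clades,
        tree_newick="((%s),(%s));" % (",".join(clades[0]), ",".join(clades[1])),
        trimmed_span=trimmed_span,
    )
    return genomes, orf_sets, truth
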