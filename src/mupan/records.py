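"""Canonical in-memory records for genomes and coding regions.

Coordinate convention, used everywhere inside the package: 0-based,
half-open, on the forward strand. Files we emit (GFF3, TSV) are 1-based
inclusive; the conversion happens only at the I/O boundary in
:mod:`mupan.sequence_io`.

Reverse-strand ORFs are stored by their forward-strand footprint with a
strand flag; the translation is computed from the reverse complement.
An ORF span always includes its stop codon, so a span of ``3*(n+1)``
nucleotides translates to ``n`` amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(nt: str) -> str:
    """Translate a CDS (stop codon included) to protein, stop stripped.

    Codons containing N become 'X'.
    """
    aa = str(Seq(nt).translate())
    return aa[:-1] if aa.endswith("*") else aa


def gc_fraction(seq: str) -> float:
    """GC fraction with N excluded from numerator and denominator."""
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class GenomeRecord:
    """One phage genome sequence plus completeness metadata.

    ``complete_left`` / ``complete_right`` report whether the packaged
    genome terminus (5'-TGT boundary plus transposase-binding repeats) is
    present at that end; they start as ``None`` and are filled in by the
    feature detectors.
    """

    id: str
    seq: str
    source: str = "file"  # {"simulated", "file"}
    complete_left: bool | None = None
    complete_right: bool | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r} "
                "(allowed: A,C,G,T,N)"
            )
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.seq)

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        s = self.seq[start:end]
        return s if strand == "+" else revcomp(s)


@dataclass
class OrfRecord:
    """A coding region on a genome.

    ``start``/``end`` are 0-based half-open forward-strand coordinates
    spanning start codon through stop codon. ``rank`` is the left-to-right
    order index of the ORF within its genome (0-based).
    """

    genome_id: str
    orf_id: str
    start: int
    end: int
    strand: str
    translation: str
    rank: int = -1
    rescued: bool = False
    sd_seq: str | None = None
    sd_spacer: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"ORF {self.orf_id}: bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"ORF {self.orf_id}: end <= start")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"ORF {self.orf_id}: span not divisible by 3")
        if (self.end - self.start) < 9:
            raise ValueError(f"ORF {self.orf_id}: shorter than 3 codons")

    @property
    def n_codons(self) -> int:
        """Number of codons including the stop codon."""
        return (self.end - self.start) // 3

    def cds(self, genome: GenomeRecord) -> str:
        """Coding sequence 5'->3' (reverse-complemented on the - strand)."""
        return genome.subsequence(self.start, self.end, self.strand)


def assign_ranks(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Assign left-to-right rank indices (by start, then end) in place."""
    for rank, orf in enumerate(sorted(orfs, key=lambda o: (o.start, o.end))):
        orf.rank = rank
    return sorted(orfs, key=lambda o: o.rank)


def orf_from_span(
    genome: GenomeRecord,
    start: int,
    end: int,
    strand: str,
    orf_id: str,
    **kwargs,
) -> OrfRecord:
    """Build an OrfRecord from a forward-strand span, translating it."""
    nt = genome.subsequence(start, end, strand)
    return OrfRecord(
        genome_id=genome.id,
        orf_id=orf_id,
        start=start,
        end=end,
        strand=strand,
        translation=translate_cds(nt),
        **kwargs,
    )
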