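"""Reading and writing genomes, annotations and analysis outputs.

External files follow community conventions: FASTA for sequences, GFF3
(1-based inclusive) for annotations, TSV with a header row for tables,
Newick for trees. Everything is converted to the package's internal
0-based half-open coordinates on the way in and back on the way out.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import DNA_ALPHABET, GenomeRecord, OrfRecord, assign_ranks, translate_cds


class FastaFormatError(ValueError):
    pass


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into GenomeRecords.

    Sequences are uppercased; N is allowed; record order is preserved.
    Raises :class:`FastaFormatError` on an empty file or non-IUPAC
    characters, naming the offending record.
    """
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FastaFormatError(
                    f"record {rec.id!r}: non-IUPAC characters {sorted(bad)!r}"
                )
            records.append(GenomeRecord(id=rec.id, seq=seq, source="file"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(genomes: list[GenomeRecord], path: str | os.PathLike) -> None:
    SeqIO.write(
        [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes],
        str(path),
        "fasta",
    )


def _orf_from_1based(
    genome_id: str,
    orf_id: str,
    start1: int,
    end1: int,
    strand: str,
    genome_len: int | None,
    attrs: dict | None = None,
) -> OrfRecord:
    if end1 < start1:
        raise FastaFormatError(f"ORF {orf_id}: end < start in annotation")
    start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
    if start < 0 or (genome_len is not None and end > genome_len):
        raise IndexError(f"ORF {orf_id}: coordinates out of genome range")
    attrs = attrs or {}
    span = end - start
    translation = attrs.get("translation", "X" * max(1, span // 3 - 1))
    return OrfRecord(
        genome_id=genome_id,
        orf_id=orf_id,
        start=start,
        end=end,
        strand=strand,
        translation=translation,
        rescued=attrs.get("rescued", "false") == "true",
    )


def read_annotation(
    path: str | os.PathLike,
    format: str = "gff3",
    genomes: dict[str, GenomeRecord] | None = None,
) -> dict[str, list[OrfRecord]]:
    """Read CDS annotations (GFF3 or TSV) into per-genome ORF lists.

    Input coordinates are 1-based inclusive. Ranks are assigned by start
    coordinate per genome. When ``genomes`` is given, translations are
    recomputed from the sequence; otherwise placeholder translations of
    the right length are used.
    """
    if format == "gff3":
        per_genome = _read_gff3(path)
    elif format == "tsv":
        per_genome = _read_tsv(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    out: dict[str, list[OrfRecord]] = {}
    for gid, orfs in per_genome.items():
        if genomes is not None and gid in genomes:
            g = genomes[gid]
            for o in orfs:
                if o.end > g.length_bp:
                    raise IndexError(f"ORF {o.orf_id}: beyond end of {gid}")
                o.translation = translate_cds(o.cds(g))
        out[gid] = assign_ranks(orfs)
    return out


def _read_gff3(path) -> dict[str, list[OrfRecord]]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    per_genome: dict[str, list[OrfRecord]] = {}
    for feat in db.features_of_type("CDS"):
        attrs = {k: v[0] for k, v in feat.attributes.items()}
        orf_id = attrs.get("ID", f"{feat.seqid}_{feat.start}_{feat.end}")
        orf = _orf_from_1based(
            feat.seqid, orf_id, feat.start, feat.end, feat.strand, None, attrs
        )
        per_genome.setdefault(feat.seqid, []).append(orf)
    return per_genome


def _read_tsv(path) -> dict[str, list[OrfRecord]]:
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "orf_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FastaFormatError(f"annotation TSV missing columns {sorted(missing)}")
    per_genome: dict[str, list[OrfRecord]] = {}
    for row in df.itertuples(index=False):
        orf = _orf_from_1based(
            row.genome_id, row.orf_id, int(row.start), int(row.end),
            row.strand, None,
        )
        per_genome.setdefault(row.genome_id, []).append(orf)
    return per_genome


def write_annotation_tsv(orf_sets: dict[str, list[OrfRecord]], path) -> None:
    """Write ORFs as TSV with 1-based inclusive coordinates."""
    rows = [
        {
            "genome_id": o.genome_id,
            "orf_id": o.orf_id,
            "start": o.start + 1,
            "end": o.end,
            "strand": o.strand,
        }
        for orfs in orf_sets.values()
        for o in orfs
    ]
    cols = ["genome_id", "orf_id", "start", "end", "strand"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_gff3(genome: GenomeRecord, orfs: list[OrfRecord], path) -> None:
    """Emit one genome's ORFs as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length_bp}\n")
        for o in sorted(orfs, key=lambda o: o.start):
            attrs = [f"ID={o.orf_id}", f"rescued={'true' if o.rescued else 'false'}"]
            if o.sd_seq:
                attrs.append(f"sd_seq={o.sd_seq};sd_spacer={o.sd_spacer}")
            for k, v in o.extra.items():
                attrs.append(f"{k}={v}")
            fh.write(
                "\t".join(
                    [
                        genome.id, "mupan", "CDS",
                        str(o.start + 1), str(o.end), ".", o.strand, "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_outputs(pangenome, rgps, tree, outdir, orf_sets=None, genomes=None) -> None:
    """Write the full analysis output set into ``outdir``.

    Emits a presence/absence pangenome matrix TSV (groups x genomes), an
    RGP table TSV, a Newick tree, and, when genomes and ORFs are given,
    one GFF3 per genome. All emitted coordinates are 1-based inclusive.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome_ids = list(pangenome.genome_ids) if pangenome is not None else []
    groups = list(pangenome.groups) if pangenome is not None else []
    matrix = pd.DataFrame(
        [
            {
                "group": grp.label,
                "status": grp.status,
                **{gid: int(gid in grp.members) for gid in genome_ids},
            }
            for grp in groups
        ],
        columns=["group", "status", *genome_ids],
    )
    matrix.to_csv(outdir / "pangenome_matrix.tsv", sep="\t", index=False)

    rgp_rows = []
    for locus in rgps or []:
        for gid in genome_ids:
            content = locus.content.get(gid, [])
            rgp_rows.append(
                {
                    "locus": locus.label,
                    "left_anchor": locus.left_anchor,
                    "right_anchor": locus.right_anchor,
                    "genome_id": gid,
                    "orf_ids": ",".join(content) if content else ".",
                }
            )
    pd.DataFrame(
        rgp_rows,
        columns=["locus", "left_anchor", "right_anchor", "genome_id", "orf_ids"],
    ).to_csv(outdir / "rgp_table.tsv", sep="\t", index=False)

    if tree is not None:
        (outdir / "tree.nwk").write_text(tree.newick() + "\n")

    if genomes and orf_sets:
        for g in genomes:
            if g.id in orf_sets:
                write_gff3(g, orf_sets[g.id], outdir / f"{g.id}.gff3")
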