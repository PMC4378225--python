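"""Parameter-recovery scoring of an analysis against a simulation truth.

Used for validation studies: run :func:`mupan.pipeline.analyze_family`
on a simulated family and measure how much of the planted architecture
the pipeline recovered -- ortholog group labels, RGP loci and their
anchor pairs, terminal repeat offsets and orientations, the slippery
cassette, the internal start, and the two-clade tree.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .phylogeny import _canonical_split
from .pipeline import FamilyAnalysis
from .simulate import TruthSet


@dataclass
class RecoveryReport:
    label_recovery: float            # fraction of planted ORFs in a group
                                     # whose majority label is their own
    n_planted_orfs: int
    loci_planted: int
    loci_recovered: int              # planted loci found with exact anchors
    repeats_exact: bool              # all offsets+orientations, all genomes
    slippery_recovery: float         # fraction of genomes, exact coordinates
    internal_recovery: float
    clade_split_found: bool
    clade_split_support: int | None
    core_count: int
    accessory_types_recovered: int   # accessory clusters holding planted ORFs
    accessory_fraction_mean: float
    accessory_count_mean: float


def _trim_shift(truth: TruthSet) -> dict[str, int]:
    return {gid: span[0] for gid, span in truth.trimmed_span.items()}


def score_recovery(truth: TruthSet, result: FamilyAnalysis) -> RecoveryReport:
    shift = _trim_shift(truth)
    span_label = {
        (r["genome_id"], r["start"] - shift[r["genome_id"]],
         r["end"] - shift[r["genome_id"]]): r["label"]
        for r in truth.orfs
    }

    # --- group labels ------------------------------------------------------
    votes: dict[str, Counter] = defaultdict(Counter)
    orf_label: dict[str, str] = {}
    for gid, orfs in result.orf_sets.items():
        for o in orfs:
            lab = span_label.get((gid, o.start, o.end))
            if lab is None:
                continue
            orf_label[o.orf_id] = lab
            votes[result.pangenome.group_of(o.orf_id)][lab] += 1
    group_major = {g: c.most_common(1)[0][0] for g, c in votes.items()}
    n_ok = sum(
        group_major.get(result.pangenome.group_of(oid)) == lab
        for oid, lab in orf_label.items()
    )
    label_recovery = n_ok / len(span_label) if span_label else 1.0

    # --- RGP loci ----------------------------------------------------------
    found_anchors = {
        (locus.left_anchor, locus.right_anchor)
        for locus in result.rgps
        if not locus.flagged_terminal
    }
    loci_recovered = sum(
        (str(left), str(right)) in found_anchors
        for _, left, right in truth.rgp_loci
    )

    # --- terminal repeats --------------------------------------------------
    truth_sites = {
        (r["genome_id"], r["name"]): (r["offset_bp"], r["orientation"])
        for r in truth.repeats
    }
    repeats_exact = True
    for gid, sites in result.repeats.items():
        got = {s.name: (s.offset_bp, s.orientation) for s in sites}
        for (tg, name), val in truth_sites.items():
            if tg == gid and got.get(name) != val:
                repeats_exact = False

    # --- slippery cassette and internal start ------------------------------
    slip = truth.slippery
    n_slip = 0
    if slip:
        for gid, sites in result.slippery.items():
            n_slip += any(
                s.heptamer == slip["heptamer"]
                and s.codon_index_in_orf == slip["codon_index"]
                and s.codons_before_stop == slip["codons_before_stop"]
                for s in sites
            )
    internal = truth.internal_start
    n_int = 0
    if internal:
        host_spans = {
            (r["genome_id"], r["start"] - shift[r["genome_id"]],
             r["end"] - shift[r["genome_id"]])
            for r in truth.orfs
            if r["label"] == internal["host_label"]
        }
        orf_by_id = {
            o.orf_id: o for orfs in result.orf_sets.values() for o in orfs
        }
        for gid, found in result.internal_starts.items():
            ok = False
            for oid, codon, hit in found:
                o = orf_by_id[oid]
                if (gid, o.start, o.end) in host_spans and codon == internal[
                    "codon_index"
                ]:
                    ok = True
            n_int += ok
    n_genomes = len(result.genomes)

    # --- tree --------------------------------------------------------------
    all_leaves = frozenset(truth.clades[0] + truth.clades[1])
    target = _canonical_split(frozenset(truth.clades[0]), all_leaves)
    split_support = None
    for node in result.tree.internal_nodes():
        side = frozenset(node.leaves())
        if (
            1 < len(side) < len(all_leaves) - 1
            and _canonical_split(side, all_leaves) == target
        ):
            split_support = node.support
    clade_split_found = split_support is not None

    # --- accessory types ---------------------------------------------------
    planted_types_recovered = len(
        {
            group_major[g]
            for g, c in votes.items()
            if not group_major[g].startswith("core_")
            and next(
                grp.status
                for grp in result.pangenome.groups
                if grp.group_id == g
            )
            == "accessory"
        }
    )

    pan = result.pangenome
    return RecoveryReport(
        label_recovery=label_recovery,
        n_planted_orfs=len(span_label),
        loci_planted=len(truth.rgp_loci),
        loci_recovered=loci_recovered,
        repeats_exact=repeats_exact,
        slippery_recovery=n_slip / n_genomes if slip else 1.0,
        internal_recovery=n_int / n_genomes if internal else 1.0,
        clade_split_found=clade_split_found,
        clade_split_support=split_support,
        core_count=pan.core_count,
        accessory_types_recovered=planted_types_recovered,
        accessory_fraction_mean=(
            sum(pan.accessory_fraction.values()) / n_genomes
        ),
        accessory_count_mean=sum(pan.accessory_counts.values()) / n_genomes,
    )
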