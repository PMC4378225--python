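"""Core/accessory pangenome construction.

Orthology follows the family's operational definition: two ORFs of
different genomes are homologous when their protein alignment reaches
e-value <= 1e-05 *and* they are syntenic -- their positions, expressed
as ranks relative to mutual-best-hit anchor pairs, differ by at most a
small window. Groups are connected components of that graph, with at
most one member per genome (best-scoring paralog kept, the rest split
off).

Core groups are those present in every *complete* genome -- genomes
flagged as missing a packaged end are exempt, following the observation
that prophage-derived deposits can lack ~2 kb of one end. Everything
else is accessory, and the intervals between adjacent core backbone
genes where accessory ORFs insert are the regions of genomic plasticity
(RGPs), labelled A, B, ... left to right; accessory ORFs are typed
across genomes by the same e-value rule and named a1, g3, ... after
their locus.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .align import AlignmentHit, evalue, sw_protein
from .records import GenomeRecord, OrfRecord

logger = logging.getLogger(__name__)

EVALUE_CORE = 1e-05
EVALUE_DB = 1e-03


class ClassificationError(RuntimeError):
    pass


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, str]          # genome_id -> orf_id (<= 1 per genome)
    status: str = "accessory"        # {"core", "accessory"}
    label: str = ""                  # core index "1".."47" or type name "g3"


@dataclass
class RgpLocus:
    label: str
    left_anchor: str                 # core group label ("27") or "" at termini
    right_anchor: str
    content: dict[str, list[str]]    # genome_id -> ordered accessory orf_ids
    flagged_terminal: bool = False


@dataclass
class PangenomeMap:
    groups: list[OrthologGroup]
    backbone: list[str]              # core group_ids, reference order
    genome_ids: list[str]
    reference_id: str
    complete: dict[str, bool]
    accessory_counts: dict[str, int] = field(default_factory=dict)
    accessory_fraction: dict[str, float] = field(default_factory=dict)
    _group_of: dict[str, str] = field(default_factory=dict)

    def group_of(self, orf_id: str) -> str | None:
        return self._group_of.get(orf_id)

    @property
    def core_count(self) -> int:
        return sum(g.status == "core" for g in self.groups)

    @property
    def accessory_type_count(self) -> int:
        return sum(g.status == "accessory" for g in self.groups)


# ---------------------------------------------------------------------------
# all-vs-all protein comparison


def all_vs_all(
    orf_sets: dict[str, list[OrfRecord]],
    evalue_max: float = EVALUE_CORE,
    prefilter: bool = True,
    prescreen_max_dist: float = 0.65,
) -> list[AlignmentHit]:
    """Cross-genome protein comparison; one hit per unordered ORF pair.

    The screening e-value uses m = the shorter sequence and n = the total
    residue count of the compared set, making retention symmetric. With
    ``prefilter`` (default), pairs are prescreened by global edit
    distance (edlib); only pairs within ``prescreen_max_dist`` of the
    longer sequence's length reach the substitution-matrix alignment --
    a seeding heuristic standing in for BLAST's word seeding.
    ``prefilter=False`` runs the exhaustive reference path.
    """
    import edlib

    orfs: list[OrfRecord] = [o for orfs in orf_sets.values() for o in orfs]
    if len(orf_sets) < 2:
        return []
    n_total = sum(len(o.translation) for o in orfs)

    candidates = []
    for i in range(len(orfs)):
        a = orfs[i].translation
        for j in range(i + 1, len(orfs)):
            if orfs[i].genome_id == orfs[j].genome_id:
                continue
            if prefilter:
                b = orfs[j].translation
                limit = int(prescreen_max_dist * max(len(a), len(b)))
                d = edlib.align(a, b, mode="NW", task="distance", k=limit)[
                    "editDistance"
                ]
                if d == -1:  # distance exceeds the prescreen limit
                    continue
            candidates.append((i, j))

    hits: list[AlignmentHit] = []
    for i, j in candidates:
        a, b = orfs[i], orfs[j]
        hit = sw_protein(a.translation, b.translation, a.orf_id, b.orf_id)
        e = evalue(hit.score, min(len(a.translation), len(b.translation)), n_total)
        if e > evalue_max:
            continue
        hit.evalue = e
        hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# synteny-aware grouping


def _synteny_ok(
    hits: list[AlignmentHit],
    orf_by_id: dict[str, OrfRecord],
    window: int,
) -> set[tuple[str, str]]:
    """Subset of hit pairs that are syntenic on MBH-anchored backbones."""
    by_pair: dict[tuple[str, str], list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        a, b = orf_by_id[h.query_id], orf_by_id[h.subject_id]
        key = tuple(sorted((a.genome_id, b.genome_id)))
        by_pair[key].append(h)

    ok: set[tuple[str, str]] = set()
    for (ga, gb), pair_hits in by_pair.items():
        best_a: dict[str, tuple[float, str]] = {}
        best_b: dict[str, tuple[float, str]] = {}
        for h in pair_hits:
            qa, qb = orf_by_id[h.query_id], orf_by_id[h.subject_id]
            if qa.genome_id != ga:
                qa, qb = qb, qa
            cur = best_a.get(qa.orf_id)
            if cur is None or h.score > cur[0]:
                best_a[qa.orf_id] = (h.score, qb.orf_id)
            cur = best_b.get(qb.orf_id)
            if cur is None or h.score > cur[0]:
                best_b[qb.orf_id] = (h.score, qa.orf_id)
        anchors = sorted(
            (orf_by_id[aid].rank, orf_by_id[bid].rank)
            for aid, (_, bid) in best_a.items()
            if best_b.get(bid, (None, None))[1] == aid
        )
        if not anchors:
            continue
        anchor_ranks = [r for r, _ in anchors]
        import bisect

        for h in pair_hits:
            qa, qb = orf_by_id[h.query_id], orf_by_id[h.subject_id]
            if qa.genome_id != ga:
                qa, qb = qb, qa
            i = bisect.bisect_left(anchor_ranks, qa.rank)
            offsets = []
            for idx in (i - 1, i):
                if 0 <= idx < len(anchors):
                    ra, rb = anchors[idx]
                    offsets.append(abs((qa.rank - ra) - (qb.rank - rb)))
            if offsets and min(offsets) <= window:
                ok.add((h.query_id, h.subject_id))
    return ok


def build_ortholog_groups(
    hits: list[AlignmentHit],
    orf_sets: dict[str, list[OrfRecord]],
    synteny_window: int = 2,
) -> list[OrthologGroup]:
    """Connected components of the (homologous AND syntenic) ORF graph.

    When a component holds several ORFs of one genome, the member with
    the highest total within-component score stays; the rest become
    singleton groups (paralog split). Every ORF belongs to exactly one
    group; ORFs with no retained edges are singletons.
    """
    orf_by_id = {o.orf_id: o for orfs in orf_sets.values() for o in orfs}
    syntenic = _synteny_ok(hits, orf_by_id, synteny_window)

    graph = nx.Graph()
    graph.add_nodes_from(orf_by_id)
    edge_score: dict[tuple[str, str], float] = {}
    for h in hits:
        if (h.query_id, h.subject_id) in syntenic:
            graph.add_edge(h.query_id, h.subject_id)
            edge_score[(h.query_id, h.subject_id)] = h.score
            edge_score[(h.subject_id, h.query_id)] = h.score

    groups: list[OrthologGroup] = []
    components = sorted(nx.connected_components(graph), key=min)
    singles: list[str] = []
    for comp in components:
        members_by_genome: dict[str, list[str]] = defaultdict(list)
        for oid in sorted(comp):
            members_by_genome[orf_by_id[oid].genome_id].append(oid)
        kept: dict[str, str] = {}
        for gid, oids in members_by_genome.items():
            if len(oids) == 1:
                kept[gid] = oids[0]
                continue
            scored = sorted(
                oids,
                key=lambda oid: (
                    -sum(edge_score.get((oid, nb), 0.0) for nb in graph[oid]),
                    oid,
                ),
            )
            kept[gid] = scored[0]
            singles.extend(scored[1:])
        if len(kept) == 1 and len(comp) == 1:
            singles.extend(kept.values())
        else:
            groups.append(OrthologGroup(group_id="", members=dict(sorted(kept.items()))))
    for oid in sorted(singles):
        groups.append(
            OrthologGroup(group_id="", members={orf_by_id[oid].genome_id: oid})
        )
    # stable ids by leftmost member position
    def sort_key(g: OrthologGroup):
        positions = sorted(
            (orf_by_id[oid].rank, gid) for gid, oid in g.members.items()
        )
        return (positions[0][0], positions[0][1])

    groups.sort(key=sort_key)
    for i, g in enumerate(groups, start=1):
        g.group_id = f"OG{i:04d}"
    return groups


def recover_missing_members(
    groups: list[OrthologGroup],
    orf_sets: dict[str, list[OrfRecord]],
    genomes: dict[str, "GenomeRecord"],
    evalue_max: float = EVALUE_CORE,
    min_presence: float = 0.5,
) -> int:
    """Restore group members lost to annotation arbitration.

    Comparative re-annotation: for every group populated in at least
    ``min_presence`` of the genomes, each absent genome's syntenic slot
    (between its members of the nearest flanking groups) is re-scanned
    with the raw ORF caller, and the best candidate matching a group
    member at e-value <= ``evalue_max`` is added back (flagged
    ``rescued``). A chance overlapping frame that displaced a real gene
    during overlap arbitration is thereby corrected by family evidence.
    Mutates ``groups`` and ``orf_sets`` in place; returns the number of
    members restored.
    """
    from .annotate import find_orfs
    from .records import assign_ranks

    genome_ids = sorted(orf_sets)
    n = len(genome_ids)
    orf_by_id = {o.orf_id: o for orfs in orf_sets.values() for o in orfs}
    group_of = {oid: g for g in groups for oid in g.members.values()}
    by_rank = {
        gid: sorted(orfs, key=lambda o: o.rank) for gid, orfs in orf_sets.items()
    }
    raw_cache: dict[str, list[OrfRecord]] = {}
    n_added = 0

    for grp in sorted(groups, key=lambda g: g.group_id):
        if len(grp.members) < max(2, int(min_presence * n)):
            continue
        for gid in genome_ids:
            if gid in grp.members:
                continue
            witness = min(grp.members)
            w_orfs = by_rank[witness]
            w_rank = orf_by_id[grp.members[witness]].rank

            def flank_in(gid_, direction):
                r = w_rank + direction
                while 0 <= r < len(w_orfs):
                    g2 = group_of.get(w_orfs[r].orf_id)
                    if g2 is not None and gid_ in g2.members:
                        return orf_by_id[g2.members[gid_]]
                    r += direction
                return None

            left, right = flank_in(gid, -1), flank_in(gid, +1)
            if left is None or right is None:
                continue
            lo = min(left.start, right.start) - 100
            hi = max(left.end, right.end) + 100
            if gid not in raw_cache:
                raw_cache[gid] = find_orfs(genomes[gid])
            cands = [
                o for o in raw_cache[gid] if lo <= o.start and o.end <= hi
            ]
            if not cands:
                continue
            ref = orf_by_id[grp.members[witness]]
            best = None
            for cand in cands:
                hit = sw_protein(cand.translation, ref.translation)
                e = evalue(hit.score, min(len(cand.translation),
                                          len(ref.translation)),
                           len(ref.translation))
                if e <= evalue_max and (best is None or hit.score > best[0]):
                    best = (hit.score, cand)
            if best is None:
                continue
            cand = best[1]
            existing = next(
                (
                    o
                    for o in orf_sets[gid]
                    if (o.start, o.end, o.strand)
                    == (cand.start, cand.end, cand.strand)
                ),
                None,
            )
            if existing is not None:
                old = group_of.get(existing.orf_id)
                if old is grp:
                    continue
                if old is not None and len(old.members) > 1:
                    continue  # already confidently grouped elsewhere
                if old is not None:
                    groups.remove(old)
                grp.members[gid] = existing.orf_id
                group_of[existing.orf_id] = grp
            else:
                cand.rescued = True
                cand.orf_id = f"{cand.orf_id}_r"
                orf_sets[gid].append(cand)
                orf_by_id[cand.orf_id] = cand
                grp.members[gid] = cand.orf_id
                group_of[cand.orf_id] = grp
                assign_ranks(orf_sets[gid])
                by_rank[gid] = sorted(orf_sets[gid], key=lambda o: o.rank)
            grp.members = dict(sorted(grp.members.items()))
            n_added += 1
    if n_added:
        logger.info("synteny refinement restored %d group members", n_added)
    return n_added


# ---------------------------------------------------------------------------
# classification and RGP delineation


def classify_core_accessory(
    groups: list[OrthologGroup],
    genomes: list[GenomeRecord],
    orf_sets: dict[str, list[OrfRecord]],
    reference_id: str | None = None,
) -> PangenomeMap:
    """Split groups into core and accessory and order the core backbone.

    Core = exactly one member in every complete genome (both termini
    present); incomplete genomes cannot veto a group. The backbone is
    numbered by position in the reference genome (first genome by
    default). Raises :class:`ClassificationError` when no genome is
    flagged complete, instructing the caller to override the flags.
    """
    complete = {
        g.id: bool(g.complete_left) and bool(g.complete_right) for g in genomes
    }
    if not any(complete.values()):
        raise ClassificationError(
            "no genome is flagged complete at both ends; override "
            "completeness flags (complete_left/complete_right) to proceed"
        )
    genome_ids = [g.id for g in genomes]
    reference_id = reference_id or genome_ids[0]
    orf_by_id = {o.orf_id: o for orfs in orf_sets.values() for o in orfs}

    required = {gid for gid, c in complete.items() if c}
    for g in groups:
        g.status = "core" if required <= set(g.members) else "accessory"

    core = [g for g in groups if g.status == "core"]

    def backbone_pos(g: OrthologGroup) -> tuple:
        oid = g.members.get(reference_id)
        if oid is not None:
            return (0, orf_by_id[oid].start)
        ranks = sorted(orf_by_id[m].rank for m in g.members.values())
        return (1, ranks[len(ranks) // 2])

    core.sort(key=backbone_pos)
    for i, g in enumerate(core, start=1):
        g.label = str(i)

    pangenome = PangenomeMap(
        groups=groups,
        backbone=[g.group_id for g in core],
        genome_ids=genome_ids,
        reference_id=reference_id,
        complete=complete,
        _group_of={
            oid: g.group_id for g in groups for oid in g.members.values()
        },
    )
    group_status = {g.group_id: g.status for g in groups}
    for g in genomes:
        acc = [
            o
            for o in orf_sets[g.id]
            if group_status.get(pangenome.group_of(o.orf_id)) == "accessory"
        ]
        pangenome.accessory_counts[g.id] = len(acc)
        pangenome.accessory_fraction[g.id] = (
            sum(o.end - o.start for o in acc) / g.length_bp
        )
    return pangenome


def delineate_rgps(
    pangenome: PangenomeMap,
    orf_sets: dict[str, list[OrfRecord]],
    hits: list[AlignmentHit] | None = None,
) -> list[RgpLocus]:
    """Assign accessory runs to loci keyed by their core anchor pair.

    Within each genome, every maximal run of accessory ORFs between two
    consecutive core genes belongs to the locus anchored by that pair of
    backbone groups; loci are labelled A, B, ... by backbone position.
    Accessory ORFs upstream of the first (or downstream of the last) core
    gene go to flagged terminal pseudo-loci. When ``hits`` are given,
    accessory ORFs are additionally typed across genomes (same 1e-05
    homology standard, no synteny requirement) and labelled a1, g3, ...
    """
    group_by_id = {g.group_id: g for g in pangenome.groups}
    backbone_index = {gid: i for i, gid in enumerate(pangenome.backbone)}

    loci: dict[tuple, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for gid, orfs in orf_sets.items():
        last_core: int | None = None
        run: list[str] = []
        for o in sorted(orfs, key=lambda o: o.rank):
            grp = pangenome.group_of(o.orf_id)
            status = group_by_id[grp].status if grp in group_by_id else "accessory"
            if status == "core" and grp in backbone_index:
                idx = backbone_index[grp]
                if run:
                    key = ("terminal-left", idx) if last_core is None else (last_core, idx)
                    loci[key][gid].extend(run)
                    run = []
                last_core = idx
            else:
                run.append(o.orf_id)
        if run:
            loci[("terminal-right", last_core)][gid].extend(run)

    def locus_sort_key(key: tuple):
        if key[0] == "terminal-left":
            return (-1, -1)
        if key[0] == "terminal-right":
            return (len(backbone_index) + 1, 0)
        return key

    out: list[RgpLocus] = []
    internal = [k for k in loci if not isinstance(k[0], str)]
    terminal = [k for k in loci if isinstance(k[0], str)]
    label_iter = _letter_labels()
    for key in sorted(internal, key=locus_sort_key):
        left, right = key
        out.append(
            RgpLocus(
                label=next(label_iter),
                left_anchor=group_by_id[pangenome.backbone[left]].label,
                right_anchor=group_by_id[pangenome.backbone[right]].label,
                content={g: list(v) for g, v in sorted(loci[key].items())},
            )
        )
    for key in sorted(terminal, key=locus_sort_key):
        side = "left" if key[0] == "terminal-left" else "right"
        out.append(
            RgpLocus(
                label=f"term-{side}",
                left_anchor="",
                right_anchor="",
                content={g: list(v) for g, v in sorted(loci[key].items())},
                flagged_terminal=True,
            )
        )

    if hits is not None:
        _type_accessory(pangenome, orf_sets, hits, out)
    return out


def _letter_labels():
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def _type_accessory(
    pangenome: PangenomeMap,
    orf_sets: dict[str, list[OrfRecord]],
    hits: list[AlignmentHit],
    loci: list[RgpLocus],
    evalue_max: float = EVALUE_CORE,
) -> None:
    """Cluster accessory ORFs into cross-genome types and name them."""
    group_by_id = {g.group_id: g for g in pangenome.groups}
    acc_group_ids = [g.group_id for g in pangenome.groups if g.status == "accessory"]
    orf_to_locus: dict[str, str] = {}
    for locus in loci:
        for gid, oids in locus.content.items():
            for oid in oids:
                orf_to_locus[oid] = locus.label

    # groups already cluster accessory ORFs (synteny included); merge
    # groups connected by plain homology so a type spans loci variants
    graph = nx.Graph()
    graph.add_nodes_from(acc_group_ids)
    gof = pangenome.group_of
    acc_set = set(acc_group_ids)
    for h in hits:
        ga, gb = gof(h.query_id), gof(h.subject_id)
        if ga in acc_set and gb in acc_set and ga != gb and h.evalue <= evalue_max:
            graph.add_edge(ga, gb)

    per_locus_counter: Counter = Counter()
    for comp in sorted(nx.connected_components(graph), key=min):
        members = [
            oid
            for g_id in comp
            for oid in group_by_id[g_id].members.values()
        ]
        locus_votes = Counter(
            orf_to_locus.get(oid, "?") for oid in members
        )
        locus_label = locus_votes.most_common(1)[0][0]
        per_locus_counter[locus_label] += 1
        type_name = f"{locus_label.lower()}{per_locus_counter[locus_label]}"
        for g_id in comp:
            group_by_id[g_id].label = type_name


# ---------------------------------------------------------------------------
# homologue counting against an external protein database


def count_homologues(
    orf: OrfRecord,
    protein_db: list[tuple[str, str, str]],
    min_len_share: float = 0.75,
    min_cov: float = 0.75,
    evalue_max: float = EVALUE_DB,
) -> tuple[int, int]:
    """Count database homologues of an ORF, split (viral, bacterial).

    A database sequence counts when the two sequences share at least
    ``min_len_share`` of their total length (shorter/longer), the
    alignment covers at least ``min_cov`` of each sequence, and the
    screening e-value (n = total database residues) is <= ``evalue_max``.
    Records tagged neither virus nor bacterium fall into an ignored
    "other" bin (a warning is logged once per call).
    """
    n_total = sum(len(seq) for _, seq, _ in protein_db) or 1
    counts = {"virus": 0, "bacterium": 0, "other": 0}
    warned = False
    q = orf.translation
    for rec_id, seq, taxon in protein_db:
        if taxon not in ("virus", "bacterium"):
            if taxon != "other" and not warned:
                logger.warning("database record %s has unknown taxon %r; "
                               "counting as 'other'", rec_id, taxon)
                warned = True
            taxon = "other"
        if min(len(q), len(seq)) / max(len(q), len(seq)) < min_len_share:
            continue
        hit = sw_protein(q, seq, orf.orf_id, rec_id)
        if hit.query_cov < min_cov or hit.subject_cov < min_cov:
            continue
        if evalue(hit.score, len(q), n_total) > evalue_max:
            continue
        counts[taxon] += 1
    return counts["virus"], counts["bacterium"]


def read_protein_db(path) -> list[tuple[str, str, str]]:
    """Protein FASTA with a ``taxon=virus|bacterium|other`` header tag."""
    from Bio import SeqIO

    db = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = "other"
        for token in rec.description.split():
            if token.startswith("taxon="):
                taxon = token.split("=", 1)[1]
        db.append((rec.id, str(rec.seq).upper(), taxon))
    return db
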