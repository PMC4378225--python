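"""End-to-end family analysis: the stage order a study run follows.

ingest/simulate -> termini detection and host-flank trimming -> repeat
finding and completeness flagging -> ORF annotation -> all-vs-all
protein comparison -> synteny-aware ortholog groups -> core/accessory
classification -> RGP delineation and accessory typing -> GC valleys ->
translational features -> core-proteome NJ tree with bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import annotate, features, pangenome as pg, phylogeny
from .records import GenomeRecord, OrfRecord

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    evalue_core: float = 1e-05
    evalue_db: float = 1e-03
    len_share: float = 0.75
    cov: float = 0.75
    synteny_window: int = 2
    min_codons: int = 34
    gc_window: int = 500
    gc_step: int = 50
    gc_threshold: float = 0.55
    repeat_motif_len: int = 22
    repeat_window: int = 200
    repeat_max_mismatch: int = 6
    bootstrap_reps: int = 1000
    reference_genome_id: str | None = None
    seed: int = 0


@dataclass
class FamilyAnalysis:
    genomes: list[GenomeRecord]                 # trimmed
    termini: dict[str, features.Termini]
    repeats: dict[str, list[features.RepeatSite]]
    orf_sets: dict[str, list[OrfRecord]]
    hits: list
    pangenome: pg.PangenomeMap
    rgps: list[pg.RgpLocus]
    gc_valleys: dict[str, list[tuple[int, int]]]
    valley_table: object
    distances: phylogeny.DistanceMatrix
    tree: phylogeny.TreeNode
    slippery: dict[str, list[annotate.SlipperySite]] = field(default_factory=dict)
    internal_starts: dict[str, list] = field(default_factory=dict)


def analyze_family(
    genomes: list[GenomeRecord],
    config: AnalysisConfig | None = None,
    orf_sets: dict[str, list[OrfRecord]] | None = None,
) -> FamilyAnalysis:
    """Run the full comparative analysis on a genome family.

    ``orf_sets`` overrides the internal ORF caller with an existing
    annotation (coordinates must refer to the *untrimmed* input, like the
    caller's own output would after trimming -- pass annotations made on
    already-trimmed genomes).
    """
    cfg = config or AnalysisConfig()

    # 1. termini, trimming, repeats, completeness
    termini = {g.id: features.detect_termini(g, family=genomes) for g in genomes}
    trimmed = [features.trim_host_flanks(g, termini[g.id]) for g in genomes]
    consensus = features.repeat_consensus(
        trimmed, cfg.repeat_motif_len, cfg.repeat_window, cfg.repeat_max_mismatch
    )
    repeats = {}
    for g in trimmed:
        sites, _flags = features.find_terminal_repeats(
            g, family=trimmed, consensus=consensus,
            motif_len=cfg.repeat_motif_len, search_window=cfg.repeat_window,
            max_mismatch=cfg.repeat_max_mismatch,
        )
        repeats[g.id] = sites
        g.complete_left, g.complete_right = features.flag_completeness(
            g, termini[g.id], sites
        )

    # 2. annotation
    if orf_sets is None:
        orf_sets = {g.id: annotate.annotate_genome(g, cfg.min_codons) for g in trimmed}
    logger.info("annotated %d genomes, %d ORFs total",
                len(trimmed), sum(map(len, orf_sets.values())))

    # 3. homology, groups, classification, RGPs
    hits = pg.all_vs_all(orf_sets, evalue_max=cfg.evalue_core)
    groups = pg.build_ortholog_groups(hits, orf_sets, cfg.synteny_window)
    pg.recover_missing_members(
        groups, orf_sets, {g.id: g for g in trimmed}, evalue_max=cfg.evalue_core
    )
    pangenome = pg.classify_core_accessory(
        groups, trimmed, orf_sets, reference_id=cfg.reference_genome_id
    )
    rgps = pg.delineate_rgps(pangenome, orf_sets, hits)

    # 4. GC valleys
    gc_valleys = {}
    for g in trimmed:
        profile = features.gc_profile(g, cfg.gc_window, cfg.gc_step)
        gc_valleys[g.id] = features.detect_valleys(profile, cfg.gc_threshold)
    valley_table = features.rgp_gc_overlap(rgps, gc_valleys, orf_sets)

    # 5. translational features
    slippery = {
        g.id: annotate.find_slippery_sites(g, orf_sets[g.id]) for g in trimmed
    }
    internal_starts = {}
    for g in trimmed:
        found = []
        for orf in orf_sets[g.id]:
            for codon_index, hit in annotate.find_internal_starts(g, orf):
                found.append((orf.orf_id, codon_index, hit))
        internal_starts[g.id] = found

    # 6. phylogeny
    distances = phylogeny.core_distance_matrix(pangenome, orf_sets, hits)
    tree = phylogeny.bootstrap_support(
        distances, n_reps=cfg.bootstrap_reps, seed=cfg.seed
    )

    return FamilyAnalysis(
        genomes=trimmed,
        termini=termini,
        repeats=repeats,
        orf_sets=orf_sets,
        hits=hits,
        pangenome=pangenome,
        rgps=rgps,
        gc_valleys=gc_valleys,
        valley_table=valley_table,
        distances=distances,
        tree=tree,
        slippery=slippery,
        internal_starts=internal_starts,
    )
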