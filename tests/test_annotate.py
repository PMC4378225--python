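import numpy as np
import pytest

from oracles import regex_slippery_scan

from mupan.annotate import (
    annotate_genome,
    find_internal_starts,
    find_orfs,
    find_slippery_sites,
    rescue_overlooked_orfs,
    resolve_overlaps,
    score_sd,
)
from mupan.records import GenomeRecord, revcomp
from mupan.simulate import random_dna


def test_minimal_orf():
    g = GenomeRecord("t", "ATGAAATAA")
    orfs = find_orfs(g, min_codons=2)
    fwd = [o for o in orfs if o.strand == "+"]
    assert len(fwd) == 1
    assert fwd[0].translation == "MK"
    assert (fwd[0].start, fwd[0].end) == (0, 9)


def test_long_orfs_rare_in_random_sequence():
    """Random 1 kb at 50% GC carries far fewer long frames than coding DNA.

    Geometric-run expectation: with stop density 3/64 per codon, a
    stop-free run of >=100 codons has probability (61/64)^100 ~ 0.008,
    giving well under one expected 100-codon ORF per 6-frame kb; a
    Poisson bound keeps the total across 10 sequences in single digits.
    """
    total = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        g = GenomeRecord(f"r{seed}", random_dna(rng, 1000, 0.5))
        n = len(find_orfs(g, min_codons=100))
        assert n <= 2
        total += n
    assert total <= 9  # mean ~0.5/genome; 3-sigma Poisson bound


class TestScoreSd:
    def test_printed_seven_mer_and_spacer(self):
        # ACGAGGA placed 9 nt before the start, as printed for the
        # internal start of the protease gene
        up = "C" * 10 + "ACGAGGA" + "TCTCTCTCT"
        g = GenomeRecord("t", up + "ATGAAAAAATAA")
        hit = score_sd(g, len(up), "+")
        assert hit is not None
        assert hit.sd_seq == "ACGAGGA"
        assert hit.spacer_nt == 9

    def test_no_motif_gives_none(self):
        g = GenomeRecord("t", "C" * 30 + "ATGAAATAA")
        assert score_sd(g, 30, "+") is None

    @pytest.mark.parametrize("spacer", range(4, 14))
    def test_exhaustive_spacer_slide(self, spacer):
        up = "C" * 15 + "AGGAGG" + "T" * spacer
        g = GenomeRecord("t", up + "ATGAAAAAATAA")
        hit = score_sd(g, len(up), "+")
        assert hit is not None
        assert hit.score == 6
        assert hit.spacer_nt == spacer

    def test_window_beyond_genome_start(self):
        g = GenomeRecord("t", "ATGAAATAA")
        assert score_sd(g, 0, "+") is None


def test_strand_symmetry_of_orf_calls(small_family):
    _, genomes, _, _ = small_family
    g = genomes[0]
    rc = GenomeRecord(g.id, revcomp(g.seq))
    fwd = {(o.start, o.end, o.strand) for o in find_orfs(g)}
    n = g.length_bp
    mirrored = {
        (n - e, n - s, "+" if strand == "-" else "-")
        for (s, e, strand) in {(o.start, o.end, o.strand) for o in find_orfs(rc)}
    }
    assert fwd == mirrored


def test_planted_orfs_recovered_with_exact_coordinates(small_family):
    _, genomes, orf_sets, truth = small_family
    total = exact = 0
    for g in genomes:
        called = {(o.start, o.end, o.strand) for o in annotate_genome(g)}
        for row in (r for r in truth.orfs if r["genome_id"] == g.id):
            total += 1
            exact += (row["start"], row["end"], row["strand"]) in called
    assert exact / total >= 0.95


def test_resolve_keeps_frameshift_partner(small_family):
    """The planted -1-frame partner overlaps its host but must survive."""
    cfg, genomes, orf_sets, truth = small_family
    slip = truth.slippery
    for g in genomes:
        kept = {(o.start, o.end) for o in annotate_genome(g)}
        for row in truth.orfs:
            if row["genome_id"] == g.id and row["label"] in (
                slip["host_label"], slip["partner_label"]
            ):
                assert (row["start"], row["end"]) in kept


class TestInternalStarts:
    def test_planted_codon_recovered_everywhere(self, small_family):
        _, genomes, orf_sets, truth = small_family
        info = truth.internal_start
        for g in genomes:
            row = next(
                r for r in truth.orfs
                if r["genome_id"] == g.id and r["label"] == info["host_label"]
            )
            orf = next(
                o for o in orf_sets[g.id]
                if (o.start, o.end) == (row["start"], row["end"])
            )
            hits = find_internal_starts(g, orf)
            by_codon = dict(hits)
            assert info["codon_index"] in by_codon
            sd = by_codon[info["codon_index"]]
            assert sd.sd_seq == info["sd_seq"]
            assert sd.spacer_nt == info["spacer_nt"]

    def test_orf_without_internal_start(self):
        g = GenomeRecord("t", "ATG" + "GCC" * 40 + "TAA")
        orf = find_orfs(g, min_codons=10)[0]
        assert find_internal_starts(g, orf) == []


class TestSlipperySites:
    def test_planted_cassette_recovered(self, small_family):
        _, genomes, orf_sets, truth = small_family
        slip = truth.slippery
        for g in genomes:
            sites = [
                s for s in find_slippery_sites(g, orf_sets[g.id])
                if s.heptamer == slip["heptamer"]
            ]
            assert any(
                s.codon_index_in_orf == slip["codon_index"]
                and s.codons_before_stop == slip["codons_before_stop"]
                for s in sites
            )

    def test_heptamer_literally_present_at_reported_position(self, small_family):
        _, genomes, orf_sets, _ = small_family
        for g in genomes:
            for s in find_slippery_sites(g, orf_sets[g.id]):
                literal = g.seq[s.pos : s.pos + 7]
                if s.strand == "-":
                    literal = revcomp(literal)
                assert literal == s.heptamer

    def test_no_sites_without_trigger(self):
        g = GenomeRecord("t", "ATG" + "GCA" * 50 + "TAA")
        orfs = find_orfs(g, min_codons=10)
        assert find_slippery_sites(g, orfs) == []

    def test_equals_regex_oracle(self, small_family):
        _, genomes, orf_sets, _ = small_family
        g = genomes[0]
        ours = {
            (s.host_orf_id, s.codon_index_in_orf)
            for s in find_slippery_sites(g, orf_sets[g.id])
        }
        assert ours == regex_slippery_scan(g.seq, orf_sets[g.id])


class TestRescue:
    def test_nothing_to_rescue_when_annotation_complete(self, small_analysis):
        res = small_analysis
        g = res.genomes[0]
        out = rescue_overlooked_orfs(
            g, res.orf_sets[g.id], res.pangenome, res.orf_sets
        )
        assert out == []

    def test_deleted_orfs_recovered_exactly(self, small_analysis):
        res = small_analysis
        g = res.genomes[0]
        full = res.orf_sets[g.id]
        core_ids = {
            grp.members.get(g.id)
            for grp in res.pangenome.groups
            if grp.status == "core"
        }
        # drop interior core ORFs so each gap is flanked by core genes
        interior = [o for o in full if o.orf_id in core_ids][3:6]
        removed = {o.orf_id for o in interior}
        thinned = [o for o in full if o.orf_id not in removed]
        rescued = rescue_overlooked_orfs(
            g, thinned, res.pangenome, res.orf_sets
        )
        got = {(o.start, o.end, o.strand) for o in rescued}
        for o in interior:
            assert (o.start, o.end, o.strand) in got
        assert all(o.rescued for o in rescued)

    def test_rescue_never_clashes_with_existing_annotation(self, small_analysis):
        res = small_analysis
        g = res.genomes[1]
        full = res.orf_sets[g.id]
        thinned = full[:10] + full[12:]
        rescued = rescue_overlooked_orfs(g, thinned, res.pangenome, res.orf_sets)
        for r in rescued:
            for o in thinned:
                if o.strand == r.strand:
                    assert min(r.end, o.end) - max(r.start, o.start) <= 30
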