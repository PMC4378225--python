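import numpy as np
import pytest

from oracles import partition_agreement
from conftest import small_family_config

from mupan.annotate import annotate_genome
from mupan.pangenome import (
    ClassificationError,
    all_vs_all,
    build_ortholog_groups,
    classify_core_accessory,
    count_homologues,
    delineate_rgps,
)
from mupan.records import GenomeRecord, OrfRecord
from mupan.simulate import simulate_family


@pytest.fixture(scope="module")
def twin_genomes(small_family):
    """One genome duplicated under a second id: perfect homology."""
    _, genomes, orf_sets, truth = small_family
    g = genomes[0]
    ts, te = truth.trimmed_span[g.id]
    a = GenomeRecord("ga", g.seq[ts:te], complete_left=True, complete_right=True)
    b = GenomeRecord("gb", g.seq[ts:te], complete_left=True, complete_right=True)
    orfs = {x.id: annotate_genome(x) for x in (a, b)}
    return a, b, orfs


class TestAllVsAll:
    def test_identical_genomes_hit_every_counterpart(self, twin_genomes):
        a, b, orfs = twin_genomes
        hits = all_vs_all(orfs)
        spans_hit = set()
        for h in hits:
            if h.identity_pct == 100.0:
                spans_hit.add(h.query_id.split("_", 1)[1])
        for o in orfs["ga"]:
            assert o.orf_id.split("_", 1)[1] in spans_hit
        assert all(h.evalue <= 1e-05 for h in hits)

    def test_hit_list_symmetric_under_input_order(self, twin_genomes):
        a, b, orfs = twin_genomes
        fwd = all_vs_all(orfs)
        rev = all_vs_all(dict(reversed(list(orfs.items()))))
        as_pairs = lambda hs: {frozenset((h.query_id, h.subject_id)) for h in hs}
        assert as_pairs(fwd) == as_pairs(rev)

    def test_prefilter_matches_exact_path(self, small_family):
        _, genomes, _, truth = small_family
        sub = {}
        for g in genomes[:2]:
            orfs = annotate_genome(g)[:15]
            sub[g.id] = orfs
        fast = all_vs_all(sub, prefilter=True)
        exact = all_vs_all(sub, prefilter=False)
        key = lambda hs: {frozenset((h.query_id, h.subject_id)) for h in hs}
        assert key(fast) == key(exact)

    def test_planted_confusion_matrix(self, small_family, small_analysis):
        """Within-group pairs pass the screen; unrelated pairs do not."""
        _, genomes, _, truth = small_family
        res = small_analysis
        shift = {g.id: truth.trimmed_span[g.id][0] for g in genomes}
        label = {
            (r["genome_id"], r["start"] - shift[r["genome_id"]],
             r["end"] - shift[r["genome_id"]]): r["label"]
            for r in truth.orfs
        }
        orf_lab = {}
        for gid, orfs in res.orf_sets.items():
            for o in orfs:
                lab = label.get((gid, o.start, o.end))
                if lab:
                    orf_lab[o.orf_id] = lab
        hit_pairs = {frozenset((h.query_id, h.subject_id)) for h in res.hits}
        within = within_hit = 0
        ids = sorted(orf_lab)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if orf_lab[a] == orf_lab[b]:
                    within += 1
                    within_hit += frozenset((a, b)) in hit_pairs
        assert within_hit / within >= 0.99
        between_hits = sum(
            1
            for pair in hit_pairs
            if len(pair) == 2
            and all(p in orf_lab for p in pair)
            and len({orf_lab[p] for p in pair}) == 2
        )
        between_total = len(ids) * (len(ids) - 1) // 2 - within
        assert between_hits / between_total <= 0.01


class TestGrouping:
    def test_zero_hits_gives_singletons(self, twin_genomes):
        _, _, orfs = twin_genomes
        groups = build_ortholog_groups([], orfs)
        n_orfs = sum(len(v) for v in orfs.values())
        assert len(groups) == n_orfs
        assert all(len(g.members) == 1 for g in groups)

    def test_partition_property(self, small_analysis):
        res = small_analysis
        member_total = sum(len(g.members) for g in res.pangenome.groups)
        orf_total = sum(len(v) for v in res.orf_sets.values())
        assert member_total == orf_total
        # and every ORF belongs to exactly one group
        seen = [oid for g in res.pangenome.groups for oid in g.members.values()]
        assert len(seen) == len(set(seen)) == orf_total

    def test_group_partition_matches_planted_truth(self, small_family, small_analysis):
        _, genomes, _, truth = small_family
        res = small_analysis
        shift = {g.id: truth.trimmed_span[g.id][0] for g in genomes}
        agreement = partition_agreement(
            truth.orfs, res.orf_sets, res.pangenome, shift
        )
        assert agreement >= 0.95

    def test_membership_stable_under_genome_order(self, small_family):
        _, genomes, _, _ = small_family
        sub = genomes[:4]
        def run(order):
            for g in order:
                g.complete_left = g.complete_right = True
            orfs = {g.id: annotate_genome(g) for g in order}
            hits = all_vs_all(orfs)
            return build_ortholog_groups(hits, orfs)
        fwd = run(list(sub))
        rev = run(list(reversed(sub)))
        as_sets = lambda groups: {
            frozenset(g.members.values()) for g in groups
        }
        assert as_sets(fwd) == as_sets(rev)


class TestClassification:
    def test_single_genome_all_core(self, small_family):
        _, genomes, _, truth = small_family
        g = genomes[0]
        g2 = GenomeRecord(g.id, g.seq, complete_left=True, complete_right=True)
        orfs = {g2.id: annotate_genome(g2)}
        groups = build_ortholog_groups([], orfs)
        pan = classify_core_accessory(groups, [g2], orfs)
        assert all(grp.status == "core" for grp in pan.groups)

    def test_no_complete_genome_is_an_error(self, small_family):
        _, genomes, _, _ = small_family
        g = GenomeRecord("x", genomes[0].seq,
                         complete_left=False, complete_right=False)
        orfs = {"x": annotate_genome(g)}
        groups = build_ortholog_groups([], orfs)
        with pytest.raises(ClassificationError, match="override"):
            classify_core_accessory(groups, [g], orfs)

    def test_planted_core_count_recovered(self, small_family, small_analysis):
        cfg, _, _, _ = small_family
        assert small_analysis.pangenome.core_count == cfg.n_core

    def test_core_monotone_under_genome_removal(self, small_family, small_analysis):
        """Removing a genome can only grow or preserve the core set."""
        _, genomes, _, _ = small_family
        full_core = {
            frozenset(g.members.values())
            for g in small_analysis.pangenome.groups
            if g.status == "core"
        }
        keep = [g for g in small_analysis.genomes if g.id != "g06"]
        orfs = {g.id: small_analysis.orf_sets[g.id] for g in keep}
        hits = [
            h for h in small_analysis.hits
            if not (h.query_id.startswith("g06") or h.subject_id.startswith("g06"))
        ]
        groups = build_ortholog_groups(hits, orfs)
        pan = classify_core_accessory(groups, keep, orfs)
        reduced_core = {
            frozenset(g.members.values()) for g in pan.groups if g.status == "core"
        }
        # every full-family core group survives (minus the removed member)
        for members in full_core:
            trimmed = frozenset(m for m in members if not m.startswith("g06"))
            assert any(trimmed <= rc for rc in reduced_core)
        assert len(reduced_core) >= len(full_core)

    def test_accessory_statistics_populated(self, small_analysis):
        pan = small_analysis.pangenome
        for gid in pan.genome_ids:
            assert pan.accessory_counts[gid] >= 0
            assert 0.0 <= pan.accessory_fraction[gid] < 0.5


class TestRgps:
    def test_no_accessory_no_loci(self, small_family):
        cfg = small_family_config(seed=77, rgp_layout=[])
        genomes, _, _ = simulate_family(cfg)
        for g in genomes:
            g.complete_left = g.complete_right = True
        orfs = {g.id: annotate_genome(g) for g in genomes}
        hits = all_vs_all(orfs)
        groups = build_ortholog_groups(hits, orfs)
        pan = classify_core_accessory(groups, genomes, orfs)
        loci = [l for l in delineate_rgps(pan, orfs, hits)
                if not l.flagged_terminal]
        # no planted accessory: at most stray singleton calls
        assert sum(len(v) for l in loci for v in l.content.values()) <= 3

    def test_planted_loci_with_exact_anchors(self, small_family, small_analysis):
        cfg, _, _, truth = small_family
        res = small_analysis
        found = {
            (l.left_anchor, l.right_anchor)
            for l in res.rgps
            if not l.flagged_terminal
        }
        for label, left, right in truth.rgp_loci:
            assert (str(left), str(right)) in found

    def test_accessory_types_are_labelled(self, small_analysis):
        pan = small_analysis.pangenome
        labelled = [
            g.label for g in pan.groups if g.status == "accessory" and g.label
        ]
        assert labelled
        assert len(set(labelled)) == len(labelled)  # unique type names

    def test_terminal_accessory_flagged(self):
        """An accessory ORF left of the first core gene lands in a
        flagged terminal pseudo-locus."""
        from mupan.pangenome import OrthologGroup, PangenomeMap

        orfs = {
            "gA": [
                OrfRecord("gA", "gA_acc", 0, 102, "+", "M" * 33, rank=0),
                OrfRecord("gA", "gA_core1", 200, 503, "+", "M" * 100, rank=1),
                OrfRecord("gA", "gA_core2", 600, 903, "+", "M" * 100, rank=2),
            ]
        }
        groups = [
            OrthologGroup("OG1", {"gA": "gA_core1"}, "core", "1"),
            OrthologGroup("OG2", {"gA": "gA_core2"}, "core", "2"),
            OrthologGroup("OG3", {"gA": "gA_acc"}, "accessory", ""),
        ]
        pan = PangenomeMap(
            groups=groups, backbone=["OG1", "OG2"], genome_ids=["gA"],
            reference_id="gA", complete={"gA": True},
            _group_of={"gA_core1": "OG1", "gA_core2": "OG2", "gA_acc": "OG3"},
        )
        loci = delineate_rgps(pan, orfs)
        terminal = [l for l in loci if l.flagged_terminal]
        assert len(terminal) == 1
        assert terminal[0].content["gA"] == ["gA_acc"]


class TestCountHomologues:
    @staticmethod
    def _mutate_protein(p, n_changes, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        arr = list(p)
        for i in rng.choice(len(arr), size=n_changes, replace=False):
            arr[i] = aas[rng.integers(0, 20)]
        return "".join(arr)

    def test_empty_db(self):
        orf = OrfRecord("g", "o", 0, 303, "+", "M" * 100)
        assert count_homologues(orf, []) == (0, 0)

    def test_self_hit_counts_once(self):
        orf = OrfRecord("g", "o", 0, 303, "+", "MKTAYIAKQR" * 10)
        assert count_homologues(orf, [("self", orf.translation, "virus")]) == (1, 0)

    def test_planted_database_recovery(self):
        """20 true homologues at ~80% identity among 50 decoys."""
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        query = "".join(aas[i] for i in rng.integers(0, 20, size=120))
        orf = OrfRecord("g", "o", 0, 3 * 121, "+", query)
        db = []
        for i in range(20):
            hom = self._mutate_protein(query, 24, rng)  # 80% identity
            taxon = "virus" if i < 12 else "bacterium"
            db.append((f"hom{i}", hom, taxon))
        for i in range(40):
            decoy = "".join(aas[j] for j in rng.integers(0, 20, size=120))
            db.append((f"dec{i}", decoy, "bacterium"))
        for i in range(10):  # wrong length: fails the 75% length share
            short = "".join(aas[j] for j in rng.integers(0, 20, size=40))
            db.append((f"short{i}", short, "virus"))
        assert count_homologues(orf, db) == (12, 8)
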