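"""Distance-based phylogeny of the phage family.

Inter-genome distances are 1 minus the mean pairwise amino-acid identity
over the shared core proteome (alignment-length weighted), and the tree
is built by neighbor joining (Saitou-Nei) with a deterministic
lexicographic tie-break. Support values come from gene-wise
bootstrapping: core ortholog groups are resampled with replacement, the
distance matrix and tree rebuilt per replicate, and each internal edge
annotated with the percentage of replicates containing the same
bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import sw_protein
from .records import OrfRecord

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    #: per core group: {(label_i, label_j): (identity fraction, weight)}
    pair_stats: dict[str, dict[tuple[str, str], tuple[float, float]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        assert self.d.shape == (n, n)
        assert np.allclose(self.d, self.d.T)
        assert np.allclose(np.diag(self.d), 0.0)


class TreeNode:
    """Minimal rooted representation of the (unrooted) NJ result."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name: str | None = None,
                 children: list[tuple["TreeNode", float]] | None = None):
        self.name = name
        self.children = children or []
        self.support: int | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(
            f"{c._newick_inner()}:{bl:.6f}" for c, bl in self.children
        )
        label = "" if self.support is None else str(self.support)
        return f"({inner}){label}"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller (tie: sorted-first) side."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(_canonical_split(side, all_leaves))
                below = below | side
            return below

        walk(self)
        return out

    def internal_nodes(self):
        nodes = []

        def walk(node: TreeNode):
            if not node.is_leaf():
                nodes.append(node)
                for child, _ in node.children:
                    walk(child)

        walk(self)
        return nodes


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: sorted(s))


def core_distance_matrix(
    pangenome,
    orf_sets: dict[str, list[OrfRecord]],
    hits=None,
) -> DistanceMatrix:
    """Core-proteome distance: 1 - weighted mean pairwise aa identity.

    Pairwise identities come from the all-vs-all hits when supplied and
    are realigned only for pairs the screening stage did not retain.
    Genome pairs sharing no core group get distance 1.0 with a warning.
    The per-group statistics are kept on the matrix (``pair_stats``) so
    the bootstrap can resample groups without realigning anything.
    """
    labels = list(pangenome.genome_ids)
    if len(labels) < 3:
        raise ValueError("need at least 3 genomes for a distance matrix")
    orf_by_id = {o.orf_id: o for orfs in orf_sets.values() for o in orfs}
    hit_by_pair = {}
    for h in hits or []:
        hit_by_pair[(h.query_id, h.subject_id)] = h
        hit_by_pair[(h.subject_id, h.query_id)] = h

    core_groups = [
        g for g in pangenome.groups if g.status == "core"
    ]
    pair_stats: dict[str, dict[tuple[str, str], tuple[float, float]]] = {}
    for grp in core_groups:
        stats: dict[tuple[str, str], tuple[float, float]] = {}
        gids = sorted(grp.members)
        for i, gi in enumerate(gids):
            for gj in gids[i + 1 :]:
                a, b = grp.members[gi], grp.members[gj]
                h = hit_by_pair.get((a, b))
                if h is None:
                    h = sw_protein(
                        orf_by_id[a].translation, orf_by_id[b].translation, a, b
                    )
                stats[(gi, gj)] = (h.identity_pct / 100.0, float(h.aligned_cols))
        pair_stats[grp.group_id] = stats

    n = len(labels)
    d = np.zeros((n, n))
    idx = {g: i for i, g in enumerate(labels)}
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for stats in pair_stats.values():
        for (gi, gj), (ident, w) in stats.items():
            i, j = idx[gi], idx[gj]
            num[i, j] += ident * w
            den[i, j] += w
    for i in range(n):
        for j in range(i + 1, n):
            if den[i, j] > 0:
                d[i, j] = d[j, i] = 1.0 - num[i, j] / den[i, j]
            else:
                logger.warning("genomes %s and %s share no core group; "
                               "distance set to 1.0", labels[i], labels[j])
                d[i, j] = d[j, i] = 1.0
    return DistanceMatrix(labels=labels, d=d, pair_stats=pair_stats)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei agglomeration with deterministic tie-breaking.

    At each step the pair minimising the Q-criterion is joined; exact Q
    ties are broken by the lexicographically smallest (label, label)
    pair, where an internal node carries the smallest leaf label beneath
    it. Negative branch-length estimates are clamped to zero (logged).
    The final three lineages join at an unrooted trifurcation.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(lab) for lab in dm.labels]
    labels: list[str] = list(dm.labels)
    D = dm.d.astype(float).copy()

    while len(labels) > 3:
        m = len(labels)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(Q <= qmin + 1e-12)
        i, j = min(
            ((ii, jj) for ii, jj in cands if ii < jj),
            key=lambda p: tuple(sorted((labels[p[0]], labels[p[1]]))),
        )
        dij = D[i, j]
        la = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lb = dij - la
        merged = TreeNode(children=[(nodes[i], _clamp(la)), (nodes[j], _clamp(lb))])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        new_label = min(labels[i], labels[j])
        nodes = [nodes[x] for x in keep] + [merged]
        labels = [labels[x] for x in keep] + [new_label]

    (a, b, c) = range(3)
    la = _clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = _clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = _clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    return TreeNode(
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )


def _clamp(x: float) -> float:
    if x < 0:
        logger.debug("negative NJ branch length %.4f clamped to 0", x)
        return 0.0
    return x


def _group_stacks(
    labels: list[str], pair_stats: dict[str, dict]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-group (identity*weight, weight) matrices stacked for resampling."""
    idx = {g: i for i, g in enumerate(labels)}
    group_ids = sorted(pair_stats)
    n = len(labels)
    num = np.zeros((len(group_ids), n, n))
    den = np.zeros((len(group_ids), n, n))
    for gi_, gid in enumerate(group_ids):
        for (ga, gb), (ident, w) in pair_stats[gid].items():
            i, j = idx[ga], idx[gb]
            num[gi_, i, j] = num[gi_, j, i] = ident * w
            den[gi_, i, j] = den[gi_, j, i] = w
    return group_ids, num, den


def _matrix_from_stacks(
    labels: list[str], num: np.ndarray, den: np.ndarray
) -> DistanceMatrix:
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, 1.0 - num / np.maximum(den, 1e-300), 1.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry despite float summation order
    return DistanceMatrix(labels=labels, d=d)


def bootstrap_support(
    dm: DistanceMatrix,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with gene-wise bootstrap supports on internal edges.

    Core ortholog groups are resampled with replacement ``n_reps`` times
    using the cached per-group identity statistics; each original
    internal edge receives the percentage of replicates whose tree
    contains the same bipartition.
    """
    if not dm.pair_stats:
        raise ValueError("distance matrix carries no per-group statistics")
    tree = neighbor_joining(dm)
    split_count: dict[frozenset, int] = {s: 0 for s in tree.bipartitions()}
    group_ids, num, den = _group_stacks(dm.labels, dm.pair_stats)
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, len(group_ids), len(group_ids))
        rep_dm = _matrix_from_stacks(dm.labels, num[idx].sum(0), den[idx].sum(0))
        rep_tree = neighbor_joining(rep_dm)
        for split in rep_tree.bipartitions():
            if split in split_count:
                split_count[split] += 1

    all_leaves = frozenset(tree.leaves())

    def annotate(node: TreeNode):
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below = below | annotate(child)
        split = _canonical_split(below, all_leaves)
        if 1 < len(below) < len(all_leaves) - 1 and split in split_count:
            node.support = round(100.0 * split_count[split] / n_reps)
        return below

    annotate(tree)
    return tree


def write_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for lab, row in zip(dm.labels, dm.d):
            fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
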