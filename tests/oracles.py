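"""Independent reference implementations used as test oracles.

Everything here is written against the *definitions* (exhaustive
recursion, closed forms, plain regular-expression scans) and never calls
the implementation paths it checks.
"""

from __future__ import annotations

import re
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1

_B62 = substitution_matrices.load("BLOSUM62")


def _sub(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def brute_force_local_score(a: str, b: str) -> float:
    """Optimal local-alignment score by exhaustive recursion.

    Recursion over (i, j, state) where state records whether a gap is
    being extended in either sequence; local behaviour comes from letting
    the score restart at zero and taking the running maximum. Affine
    costs: a gap of length k costs GAP_OPEN + k * GAP_EXTEND. Exponential
    in principle, memoised; only for tiny strings.
    """
    best = 0.0

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, state: int) -> float:
        # best score of an alignment whose last column ends at (i, j) in
        # the given state (0 = pair, 1 = gap in b, 2 = gap in a)
        options = [-(10**9)]
        if state == 0 and i > 0 and j > 0:
            base = max(0.0, ext(i - 1, j - 1, 0), ext(i - 1, j - 1, 1),
                       ext(i - 1, j - 1, 2))
            options.append(base + _sub(a[i - 1], b[j - 1]))
        if state == 1 and i > 0:  # gap in b (consume a[i-1])
            options.append(max(ext(i - 1, j, 0), 0.0) - GAP_OPEN - GAP_EXTEND)
            options.append(ext(i - 1, j, 1) - GAP_EXTEND)
        if state == 2 and j > 0:  # gap in a
            options.append(max(ext(i, j - 1, 0), 0.0) - GAP_OPEN - GAP_EXTEND)
            options.append(ext(i, j - 1, 2) - GAP_EXTEND)
        return max(options)

    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            for state in (0, 1, 2):
                best = max(best, ext(i, j, state))
    return best


def mutate_per_site_loop(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Site-by-site substitution loop (reference for the vectorised path)."""
    bases = "ACGT"
    out = []
    for ch in seq:
        if ch != "N" and rng.random() < rate:
            out.append(rng.choice([b for b in bases if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# additive trees for neighbor joining


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (leaf labels, distance matrix, set of bipartitions), built by
    sequential taxon attachment; distances are path lengths, hence
    exactly additive.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # graph as adjacency: node -> {neighbor: branch length}
    w01 = _bl(rng)
    adj: dict[int, dict[int, float]] = {0: {1: w01}, 1: {0: w01}}
    leaf_node = {0: 0, 1: 1}
    next_node = 2
    for t in range(2, n_taxa):
        # pick a random edge, split it, hang the new taxon off the middle
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid, leaf = next_node, next_node + 1
        next_node += 2
        lo = w * float(rng.uniform(0.2, 0.8))
        adj[mid] = {}
        adj[u][mid] = adj[mid][u] = lo
        adj[v][mid] = adj[mid][v] = w - lo
        bl = _bl(rng)
        adj[mid][leaf] = bl
        adj[leaf] = {mid: bl}
        leaf_node[t] = leaf

    # all-pairs path lengths between leaves; float summation order can
    # differ per direction, so symmetrise exactly
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        dist = _dijkstra(adj, leaf_node[i])
        for j in range(n):
            d[i, j] = dist[leaf_node[j]]
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return labels, d, _tree_bipartitions(adj, leaf_node, labels)


def _bl(rng) -> float:
    return float(rng.uniform(0.05, 1.0))


def _dijkstra(adj, start):
    import heapq

    dist = {start: 0.0}
    heap = [(0.0, start)]
    while heap:
        du, u = heapq.heappop(heap)
        if du > dist.get(u, np.inf):
            continue
        for v, w in adj[u].items():
            alt = du + w
            if alt < dist.get(v, np.inf):
                dist[v] = alt
                heapq.heappush(heap, (alt, v))
    return dist


def _tree_bipartitions(adj, leaf_node, labels):
    node_of_leaf = {v: k for k, v in leaf_node.items()}
    all_set = frozenset(labels)
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                side = _reachable(adj, v, banned=u)
                leaves = frozenset(
                    labels[node_of_leaf[x]] for x in side if x in node_of_leaf
                )
                if 1 < len(leaves) < len(labels) - 1:
                    other = all_set - leaves
                    splits.add(min(leaves, other, key=lambda s: (len(s), sorted(s))))
    return splits


def _reachable(adj, start, banned):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != banned and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


# ---------------------------------------------------------------------------
# slippery-heptamer regex scan


def regex_slippery_scan(genome_seq: str, orfs) -> set[tuple[str, int]]:
    """(host orf_id, codon index) pairs by a plain regex re-derivation.

    Scans each ORF's reading-direction CDS for X XXY YYZ heptamers whose
    first base is the third base of a codon, then requires a same-strand
    ORF in the -1 frame starting within 200 nt downstream and inside the
    host span.
    """
    from mupan.records import revcomp

    pat = re.compile(r"(?=((.)\2\2(.)\3\3.))", re.S)
    n = len(genome_seq)
    found = set()
    for host in orfs:
        cds = (
            genome_seq[host.start : host.end]
            if host.strand == "+"
            else revcomp(genome_seq[host.start : host.end])
        )
        read_start = host.start if host.strand == "+" else n - host.end
        for m in pat.finditer(cds):
            r = m.start()
            if r % 3 != 2 or r + 7 > len(cds) - 3:
                continue
            hept_read = read_start + r
            for cand in orfs:
                if cand.strand != host.strand or cand.orf_id == host.orf_id:
                    continue
                c_read = cand.start if cand.strand == "+" else n - cand.end
                if (
                    hept_read < c_read <= hept_read + 200
                    and (c_read - read_start) % 3 == 2
                    and c_read < read_start + len(cds)
                ):
                    found.add((host.orf_id, r // 3 + 1))
                    break
    return found


def partition_agreement(truth_rows, orf_sets, pangenome, trim_shift):
    """Fraction of planted ORFs assigned to a group matching their label.

    Recovered groups are matched to planted labels by majority vote; a
    planted ORF counts as recovered when its group's majority label is
    its own and that group maps to no other label better.
    """
    from collections import Counter, defaultdict

    span_to_label = {}
    for r in truth_rows:
        shift = trim_shift[r["genome_id"]]
        span_to_label[(r["genome_id"], r["start"] - shift, r["end"] - shift)] = r[
            "label"
        ]
    votes = defaultdict(Counter)
    orf_label = {}
    for gid, orfs in orf_sets.items():
        for o in orfs:
            lab = span_to_label.get((gid, o.start, o.end))
            if lab is None:
                continue
            orf_label[o.orf_id] = lab
            grp = pangenome.group_of(o.orf_id)
            votes[grp][lab] += 1
    group_label = {
        grp: counts.most_common(1)[0][0] for grp, counts in votes.items()
    }
    n_ok = sum(
        1
        for oid, lab in orf_label.items()
        if group_label.get(pangenome.group_of(oid)) == lab
    )
    return n_ok / len(span_to_label)
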