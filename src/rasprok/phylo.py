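"""Distance trees, bootstrap consensus, and coupled-tree congruence.

Trees are built by neighbor joining from Poisson-corrected p-distances,
with column-resampled bootstrap replicates summarized by a strict
majority-rule (>50%) consensus whose internal-node labels carry the
bipartition retention fraction.  The congruence statistic quantifies, for
a GTPase tree and the tree of its coupled MglB partners, what fraction of
the GTPase tree's internal bipartitions map onto bipartitions of the
partner tree - an operational surrogate for visual clade matching between
the two coevolving families.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import skbio
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = [
    "distances",
    "neighbor_joining",
    "bipartitions",
    "TreeSummary",
    "bootstrap_consensus",
    "CongruenceReport",
    "congruence",
]

#: Poisson-corrected distance is capped at d(0.95) = -ln(0.05)
P_CAP = 0.95
D_CAP = -math.log(1.0 - P_CAP)


def _alignment_matrix(alignment: Mapping[str, str]):
    ids = sorted(alignment)
    L = {len(alignment[i]) for i in ids}
    if len(L) != 1:
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(alignment[i]) for i in ids], dtype="U1")
    return ids, arr


def distances(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances, d = -ln(1 - p).

    p is the mismatch fraction over columns where both sequences are
    ungapped; p >= 0.95 is capped at d(0.95).  A pair with zero
    comparable columns is an error.
    """
    ids, arr = _alignment_matrix(alignment)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences")
    gap = (arr == "-") | (arr == ".")
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            d = D_CAP if p >= P_CAP else -math.log(1.0 - p)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids)


def neighbor_joining(dm: DistanceMatrix) -> skbio.TreeNode:
    """Canonical neighbor joining; requires >= 3 taxa.

    Input ids are canonicalized to sorted order first, so the unrooted
    topology is independent of the caller's taxon ordering; negative
    branch lengths are clamped to zero.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    return nj(dm, neg_as_zero=True)


def bipartitions(
    tree: skbio.TreeNode,
    leaf_set: frozenset | None = None,
    min_length: float | None = None,
) -> set[frozenset]:
    """Internal (non-trivial) bipartitions of an unrooted tree.

    Each bipartition is a frozenset of its two frozenset sides; both
    sides have >= 2 leaves.  Invariant under rerooting.  With
    `min_length` set, edges at or below it (zero-length polytomy edges)
    are skipped.
    """
    if leaf_set is None:
        leaf_set = frozenset(t.name for t in tree.tips())
    out: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        if min_length is not None and node.length is not None and node.length <= min_length:
            continue
        side = frozenset(t.name for t in node.tips())
        other = leaf_set - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


@dataclass
class TreeSummary:
    """Majority-rule consensus of bootstrap replicates."""

    consensus_newick: str
    #: sorted (sorted-leaf-tuple of the smaller side, support fraction)
    supports: list[tuple[tuple[str, ...], float]]
    n_replicates: int


def _consensus_tree(leaves: list[str], clades: list[tuple[frozenset, float]]) -> skbio.TreeNode:
    """Build a rooted representation of compatible clusters.

    `clades` are sides not containing the anchor leaf (clusters), each
    with a support value; >50% majority guarantees joint compatibility.
    """
    root = skbio.TreeNode()
    tips = {name: skbio.TreeNode(name=name) for name in leaves}
    for t in tips.values():
        root.append(t)
    # insert larger clusters first so nesting works by reparenting
    for cluster, support in sorted(clades, key=lambda c: (-len(c[0]), sorted(c[0]))):
        # current parents of the cluster's tips
        members = [tips[name] for name in cluster]
        parents = {id(m.parent): m.parent for m in members}
        # all members must currently share one parent (guaranteed compatible)
        if len(parents) != 1:
            # overlapping but incompatible should not happen for >50% clades
            continue
        parent = next(iter(parents.values()))
        node = skbio.TreeNode(name=f"{support:.2f}")
        for m in members:
            parent.remove(m)
            node.append(m)
        parent.append(node)
    return root


def bootstrap_consensus(
    alignment: Mapping[str, str], n_replicates: int, seed: int
) -> TreeSummary:
    """Column-resampled bootstrap with strict majority-rule consensus.

    Each replicate resamples alignment columns with replacement, builds a
    neighbor-joining tree, and the consensus retains exactly the internal
    bipartitions present in more than half of the replicates; supports are
    retention fractions.  Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, arr = _alignment_matrix(alignment)
    rng = np.random.default_rng(seed)
    L = arr.shape[1]
    counts: dict[frozenset, int] = {}
    leaf_set = frozenset(ids)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = {i: "".join(arr[k][cols]) for k, i in enumerate(ids)}
        tree = neighbor_joining(distances(rep))
        # zero-length internal edges are unresolved, not evidence
        for bp in bipartitions(tree, leaf_set, min_length=0.0):
            counts[bp] = counts.get(bp, 0) + 1
    majority = [
        (bp, c / n_replicates) for bp, c in counts.items() if c / n_replicates > 0.5
    ]
    anchor = sorted(ids)[0]
    clades = [
        (next(s for s in bp if anchor not in s), sup) for bp, sup in majority
    ]
    tree = _consensus_tree(sorted(ids), clades)
    supports = sorted(
        (tuple(sorted(min(bp, key=lambda s: (len(s), sorted(s))))), sup)
        for bp, sup in majority
    )
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return TreeSummary(
        consensus_newick=buf.getvalue().strip(),
        supports=supports,
        n_replicates=n_replicates,
    )


@dataclass
class CongruenceReport:
    """Outcome of coupled-tree bipartition matching."""

    fraction: float
    n_bipartitions: int
    n_matched: int
    #: per GTPase-tree bipartition: (sorted smaller side, matched?)
    matches: list[tuple[tuple[str, ...], bool]] = field(default_factory=list)
    #: partner actually used for each GTPase that has two (chosen per match)
    chosen_partners: dict[str, str] = field(default_factory=dict)


def congruence(
    tree_g: skbio.TreeNode,
    tree_b: skbio.TreeNode,
    partner_map: Mapping[str, Sequence[str]],
) -> CongruenceReport:
    """Fraction of GTPase-tree bipartitions realized in the partner tree.

    Both trees are restricted to mapped leaves.  A GTPase bipartition
    {S, S-bar} matches when some partner-tree bipartition {T, T-bar} lets
    every GTPase in S choose a partner inside T and every GTPase in S-bar
    a partner inside T-bar (so for 1:2 systems either partner may carry
    the signal; the chosen one is recorded).
    """
    if not partner_map:
        raise ValueError("empty partner map")
    g_leaves = {t.name for t in tree_g.tips()}
    b_leaves = {t.name for t in tree_b.tips()}
    mapped = {
        g: [b for b in bs if b in b_leaves]
        for g, bs in partner_map.items()
        if g in g_leaves
    }
    mapped = {g: bs for g, bs in mapped.items() if bs}
    missing = set(partner_map) - set(mapped)
    if missing:
        raise ValueError(f"mapped leaves missing from trees: {sorted(missing)[:5]}")
    g_keep = sorted(mapped)
    b_keep = sorted({b for bs in mapped.values() for b in bs})
    tg = tree_g.shear(g_keep)
    tb = tree_b.shear(b_keep)
    bps_g = bipartitions(tg)
    bps_b = bipartitions(tb)
    b_sides = [side for bp in bps_b for side in bp]

    matches: list[tuple[tuple[str, ...], bool]] = []
    chosen: dict[str, str] = {}
    n_matched = 0
    for bp in sorted(bps_g, key=lambda x: sorted(map(sorted, x))):
        s1, s2 = tuple(bp)
        small = min((s1, s2), key=lambda s: (len(s), sorted(s)))
        ok = False
        for T in b_sides:
            if all(any(b in T for b in mapped[g]) for g in s1) and all(
                any(b not in T for b in mapped[g]) for g in s2
            ):
                ok = True
                for g in s1:
                    if len(mapped[g]) > 1:
                        chosen[g] = next(b for b in mapped[g] if b in T)
                break
        if ok:
            n_matched += 1
        matches.append((tuple(sorted(small)), ok))
    n = len(bps_g)
    return CongruenceReport(
        fraction=(n_matched / n) if n else 1.0,
        n_bipartitions=n,
        n_matched=n_matched,
        matches=matches,
        chosen_partners=chosen,
    )
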