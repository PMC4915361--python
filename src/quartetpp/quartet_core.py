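"""Quartet frequency counting around species-tree branches.

An internal branch of an unrooted binary species tree splits the taxa into
four clusters (A, B, C, D) with A and B on one side — a *quadripartition*
with topology AB|CD. A quartet around the branch picks one leaf from each
cluster; each such quartet has three possible unrooted topologies,
corresponding to the quadripartition itself (Q) and its two rearrangements
Q2 = AC|BD and Q3 = AD|BC.

For each gene tree we count how many quartets around the branch it resolves
into each topology. The efficient path does one postorder pass per gene
tree, accumulating for every node the sizes of the intersections of its
subtree with A, B, C and D; each internal node contributes via a closed-form
sum over the 12 cluster matchings between the quadripartition and the
node's tripartition. Every resolved quartet is seen at exactly two nodes,
so the doubled total is halved (and its parity asserted). A brute-force
enumerator over all quartets serves as the independent oracle.

Polytomies in gene trees resolve nothing by themselves: a node of degree d
is scored over all C(d, 3) tripartitions formed by choosing 3 of its d
neighbor clusters (leaves in the unchosen clusters are excluded, i.e. those
quartets stay unresolved at that node). Missing taxa simply shrink the
cluster intersections; a gene tree with no quartet around the branch is
excluded from that branch's effective gene count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import prod
from typing import Iterable, Optional, Sequence

from .trees import PhyloTree, popcount

__all__ = [
    "Quadripartition",
    "Tripartition",
    "QuartetSupportRecord",
    "quadripartition_of_edge",
    "count_matching_quartets",
    "gene_tree_quartet_counts",
    "brute_force_quartet_counts",
    "quartet_support",
]


class CountingError(RuntimeError):
    """Internal-consistency failure in quartet counting (parity violation)."""


@dataclass(frozen=True)
class Quadripartition:
    """Four disjoint taxon clusters (bitmasks) read as topology AB|CD."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self):
        ms = (self.A, self.B, self.C, self.D)
        if any(m == 0 for m in ms):
            raise ValueError("quadripartition clusters must be non-empty")
        for x, y in combinations(ms, 2):
            if x & y:
                raise ValueError("quadripartition clusters must be disjoint")

    @property
    def clusters(self) -> tuple[int, int, int, int]:
        return (self.A, self.B, self.C, self.D)

    @property
    def m_total(self) -> int:
        """Number of quartets around the branch: product of cluster sizes."""
        return prod(popcount(m) for m in self.clusters)

    def alternatives(self) -> tuple["Quadripartition", "Quadripartition"]:
        """The two rearrangements AC|BD and AD|BC."""
        return (
            Quadripartition(self.A, self.C, self.B, self.D),
            Quadripartition(self.A, self.D, self.B, self.C),
        )


@dataclass(frozen=True)
class Tripartition:
    """Three disjoint clusters (bitmasks) around a gene-tree internal node."""

    X: int
    Y: int
    Z: int

    @property
    def clusters(self) -> tuple[int, int, int]:
        return (self.X, self.Y, self.Z)


@dataclass
class QuartetSupportRecord:
    """Averaged quartet frequencies for one species-tree branch.

    ``z`` are the averaged counts for (Q, Q2, Q3); ``n_eff`` is the number
    of multinomial trials used downstream; ``m_bar`` the average number of
    quartets around the branch present per effective gene; ``m_total`` the
    number of quartets when no taxa are missing; ``n_genes_eff`` the count
    of genes contributing at least one quartet.
    """

    z: tuple[float, float, float]
    n_eff: float
    m_bar: float
    m_total: int
    n_genes_eff: int

    @property
    def has_signal(self) -> bool:
        return self.n_eff > 0

    @property
    def frequencies(self) -> tuple[float, float, float]:
        """Normalized quartet frequencies z_j / n_eff (NaN without signal)."""
        if not self.has_signal:
            return (float("nan"),) * 3
        return tuple(zj / self.n_eff for zj in self.z)


# ---------------------------------------------------------------------------
# quadripartitions from species-tree edges


def quadripartition_of_edge(
    species_tree: PhyloTree, edge
) -> tuple[Quadripartition, Quadripartition, Quadripartition]:
    """The quadripartition (Q, Q2, Q3) defined by an internal edge.

    The edge's child node v and parent node u must both have degree 3 in the
    unrooted sense; A, B are the two subtree clusters on v's side and C, D
    the two on u's side. Cluster order is canonical: within each pair the
    cluster containing the smaller minimum taxon index comes first, and the
    (C, D) pair is oriented so Q2/Q3 labels are reproducible run to run.
    """
    v = edge.head_node
    u = edge.tail_node
    if v.is_leaf() or u is None:
        raise ValueError("edge is not internal")
    masks = species_tree.node_masks()
    full = species_tree.leaf_mask()

    v_kids = v.child_nodes()
    if len(v_kids) != 2:
        raise ValueError(
            f"unscorable polytomy edge: node below edge has degree {len(v_kids) + 1}"
        )
    a, b = masks[v_kids[0]], masks[v_kids[1]]

    # u side: u's other neighbors (other children, plus u's parent side)
    others = [masks[ch] for ch in u.child_nodes() if ch is not v]
    if u.parent_node is not None:
        others.append(full & ~masks[u])
    if len(others) != 2:
        raise ValueError(
            f"unscorable polytomy edge: node above edge has degree {len(others) + 2}"
        )
    c, d = others

    def lo(mask: int) -> int:
        return (mask & -mask).bit_length()  # position of lowest set bit

    if lo(b) < lo(a):
        a, b = b, a
    if lo(d) < lo(c):
        c, d = d, c
    # put the pair containing the overall smallest taxon first
    if lo(c) < lo(a):
        a, b, c, d = c, d, a, b
    q = Quadripartition(a, b, c, d)
    q2, q3 = q.alternatives()
    return q, q2, q3


# ---------------------------------------------------------------------------
# the 12-matching counting formula


def _count_from_intersections(
    x: Sequence[int], y: Sequence[int], z: Sequence[int]
) -> int:
    """Sum over the 12 matchings between a quadripartition and a tripartition.

    ``x[i]``, ``y[i]``, ``z[i]`` are |cluster_i ∩ X|, |cluster_i ∩ Y|,
    |cluster_i ∩ Z| for the quadripartition clusters i = A, B, C, D with
    topology AB|CD. A matching sends one sibling pair ({A,B} or {C,D}) into
    one part of the tripartition and the two remaining clusters into the two
    remaining parts (2 sibling pairs x 3 parts x 2 assignments = 12).
    """
    parts = (x, y, z)
    total = 0
    for pair, (s1, s2) in (((0, 1), (2, 3)), ((2, 3), (0, 1))):
        i, j = pair
        for p in range(3):
            pp = parts[p]
            paired = pp[i] * pp[j]
            if not paired:
                continue
            (q1, q2) = [parts[t] for t in range(3) if t != p]
            total += paired * (q1[s1] * q2[s2] + q1[s2] * q2[s1])
    return total


def count_matching_quartets(Q: Quadripartition, R: Tripartition) -> int:
    """|psi(R) ∩ psi(Q)|: quartets around Q resolved as AB|CD at node R."""
    inter = [
        [popcount(c & p) for c in Q.clusters] for p in R.clusters
    ]
    return _count_from_intersections(*inter)


# ---------------------------------------------------------------------------
# efficient per-gene-tree counting


def gene_tree_quartet_counts(
    Q: Quadripartition,
    alternatives: tuple[Quadripartition, Quadripartition],
    gene_tree: PhyloTree,
) -> tuple[int, int, int, int]:
    """(c1, c2, c3, m_g) for one gene tree by a single postorder pass.

    c_j is the number of quartets around the branch that the gene tree
    resolves as topology j; m_g is the number of quartets with all four
    leaves present in the gene tree. c1+c2+c3 = m_g when the gene tree is
    binary and complete, and <= m_g otherwise (polytomies leave quartets
    unresolved; missing taxa remove them).
    """
    if gene_tree.n_leaves < 4:
        return (0, 0, 0, 0)
    quads = (Q,) + tuple(alternatives)
    cl = Q.clusters  # the same four clusters in all three arrangements
    base_index = {c: i for i, c in enumerate(cl)}
    # permutation taking each arrangement's cluster order into base order
    perms = [tuple(base_index[c] for c in q.clusters) for q in quads]
    gene_mask = gene_tree.leaf_mask()
    m_g = prod(popcount(c & gene_mask) for c in cl)
    if m_g == 0:
        return (0, 0, 0, 0)

    # postorder intersection-size vectors: cnt[node][i] = |subtree ∩ cluster i|
    cnt: dict = {}
    for nd in gene_tree.dtree.postorder_node_iter():
        if nd.is_leaf():
            bit = gene_tree.taxa.bit(nd.taxon.label)
            cnt[nd] = tuple(1 if (c & bit) else 0 for c in cl)
        else:
            acc = [0, 0, 0, 0]
            for ch in nd.child_nodes():
                v = cnt[ch]
                for i in range(4):
                    acc[i] += v[i]
            cnt[nd] = tuple(acc)

    totals = tuple(popcount(c & gene_mask) for c in cl)
    doubled = [0, 0, 0]
    for nd in gene_tree.dtree.postorder_node_iter():
        if nd.is_leaf():
            continue
        neighbors = [cnt[ch] for ch in nd.child_nodes()]
        if nd.parent_node is not None:
            me = cnt[nd]
            neighbors.append(tuple(totals[i] - me[i] for i in range(4)))
        if len(neighbors) < 3:
            continue
        for trip in combinations(neighbors, 3):
            for j, perm in enumerate(perms):
                inter = [[part[perm[k]] for k in range(4)] for part in trip]
                doubled[j] += _count_from_intersections(*inter)

    for j in range(3):
        if doubled[j] % 2:
            raise CountingError(
                "odd doubled quartet count — each resolved quartet must be "
                "seen at exactly two gene-tree nodes"
            )
    c1, c2, c3 = (d // 2 for d in doubled)
    if c1 + c2 + c3 > m_g:
        raise CountingError("resolved quartet count exceeds present quartets")
    return (c1, c2, c3, m_g)


# ---------------------------------------------------------------------------
# brute-force oracle


def _bits(mask: int) -> Iterable[int]:
    while mask:
        low = mask & -mask
        yield low
        mask ^= low


def brute_force_quartet_counts(
    Q: Quadripartition,
    alternatives: tuple[Quadripartition, Quadripartition],
    gene_tree: PhyloTree,
) -> tuple[int, int, int, int]:
    """Oracle: classify every quartet around Q by restriction of the gene tree.

    Enumerates all (a, b, c, d) with one leaf per cluster present in the
    gene tree, and asks which pairing (if any) is separated by some gene-tree
    bipartition. Intended for small instances only.
    """
    if gene_tree.n_leaves < 4:
        return (0, 0, 0, 0)
    gm = gene_tree.leaf_mask()
    masks = list(gene_tree.node_masks().values())
    quads = (Q,) + tuple(alternatives)
    counts = [0, 0, 0]
    m_g = 0
    A, B, C, D = (c & gm for c in Q.clusters)
    for a in _bits(A):
        for b in _bits(B):
            for c in _bits(C):
                for d in _bits(D):
                    m_g += 1
                    four = a | b | c | d
                    topo = _classify_quartet(masks, four, quads, a, b, c, d)
                    if topo is not None:
                        counts[topo] += 1
    return (counts[0], counts[1], counts[2], m_g)


def _classify_quartet(masks, four, quads, a, b, c, d):
    # which of the three pairings is separated by some gene-tree cluster?
    base = quads[0].clusters
    pos = {base[0]: a, base[1]: b, base[2]: c, base[3]: d}
    for j, q in enumerate(quads):
        s1 = pos[q.clusters[0]] | pos[q.clusters[1]]
        s2 = pos[q.clusters[2]] | pos[q.clusters[3]]
        for m in masks:
            mm = m & four
            if mm == s1 or mm == s2:
                return j
    return None


# ---------------------------------------------------------------------------
# averaging over gene trees


def quartet_support(
    Q: Quadripartition,
    alternatives: tuple[Quadripartition, Quadripartition],
    gene_trees: Sequence[PhyloTree],
    strict_n: bool = False,
    counter=gene_tree_quartet_counts,
) -> QuartetSupportRecord:
    """Averaged quartet frequencies z = (z1, z2, z3) for one branch.

    A gene is *effective* if at least one quartet around the branch is
    present in it (m_g >= 1). With complete data every gene has m_g equal to
    the full quartet count m and z_j reduces to the plain average of
    per-quartet topology counts over genes. With missing data, totals are
    divided by the mean number of present quartets per effective gene.

    ``n_eff`` — the number of multinomial trials used by the posterior — is
    z1 + z2 + z3 by default, which equals the effective gene count when all
    effective gene trees are binary but does not count quartets left
    unresolved by polytomies as observed outcomes. ``strict_n=True`` uses
    the literal effective gene count instead.
    """
    if not gene_trees:
        raise ValueError("at least one gene tree required")
    sums = [0, 0, 0]
    m_list = []
    for gt in gene_trees:
        c1, c2, c3, m_g = counter(Q, alternatives, gt)
        if m_g >= 1:
            m_list.append(m_g)
            sums[0] += c1
            sums[1] += c2
            sums[2] += c3
    if not m_list:
        return QuartetSupportRecord(
            z=(0.0, 0.0, 0.0), n_eff=0.0, m_bar=0.0,
            m_total=Q.m_total, n_genes_eff=0,
        )
    m_bar = sum(m_list) / len(m_list)
    z = tuple(s / m_bar for s in sums)
    n_eff = float(len(m_list)) if strict_n else sum(z)
    return QuartetSupportRecord(
        z=z, n_eff=n_eff, m_bar=m_bar, m_total=Q.m_total,
        n_genes_eff=len(m_list),
    )
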