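"""Synthetic data: Yule species trees, MSC gene trees, noise, missing taxa.

The generator mirrors the model the scoring machinery assumes: a species
tree whose branch lengths (in coalescent units) come from a pure-birth Yule
process, and gene trees drawn from the multi-species coalescent with one
sampled lineage per species. Two perturbations emulate the departures seen
in real inputs: random nearest-neighbor interchanges stand in for gene-tree
estimation error, and independent random taxon deletion stands in for
missing data. Everything is driven by a single integer seed and is fully
reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy

from .trees import PhyloTree, TaxonIndex, unroot

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "simulate_msc_gene_trees",
    "perturb_gene_trees",
    "delete_taxa",
    "clamp_internal_lengths",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic replicate.

    n_leaves   — species count (>= 4);
    lam        — Yule speciation rate per coalescent time unit (default 1/2,
                 matching the flat-prior rate the scorer assumes);
    n_genes    — number of gene trees;
    seed       — integer seed; identical seeds give identical output;
    noise      — probability that each internal gene-tree edge is hit by a
                 random NNI re-draw (0 = true gene trees);
    missing    — probability that each gene-tree leaf is deleted.
    """

    n_leaves: int = 8
    lam: float = 0.5
    n_genes: int = 200
    seed: int = 0
    noise: float = 0.0
    missing: float = 0.0

    def __post_init__(self):
        if self.n_leaves < 4:
            raise ValueError("need at least 4 species")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        for p in (self.noise, self.missing):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Yule species trees


def simulate_yule_tree(config: SimConfig) -> PhyloTree:
    """A rooted binary Yule tree with coalescent-unit branch lengths.

    Pure-birth process: with k extant lineages the waiting time to the next
    speciation is Exp(k * lam); the splitting lineage is uniform. Growth
    stops when ``n_leaves`` tips exist, after which one extra Exp(k * lam)
    waiting time is appended so the youngest pendant edges are not zero.
    Leaf labels are t1..tL in birth order.
    """
    rng = random.Random(config.seed)
    taxa = TaxonIndex()
    tree = dendropy.Tree()
    tips = [tree.seed_node]
    tree.seed_node.edge.length = 0.0
    waiting_times: list[tuple[int, float]] = []
    while len(tips) < config.n_leaves:
        k = len(tips)
        dt = rng.expovariate(k * config.lam)
        waiting_times.append((k, dt))
        for t in tips:
            t.edge.length += dt
        parent = tips.pop(rng.randrange(k))
        for _ in range(2):
            ch = parent.new_child()
            ch.edge.length = 0.0
            tips.append(ch)
    dt = rng.expovariate(len(tips) * config.lam)
    waiting_times.append((len(tips), dt))
    for t in tips:
        t.edge.length += dt
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for i, t in enumerate(tips, 1):
        label = f"t{i}"
        t.taxon = dendropy.Taxon(label=label)
        ns.add_taxon(t.taxon)
        taxa.add(label)
    tree.seed_node.edge.length = None
    out = PhyloTree(tree, taxa)
    # exposed for distributional checks: (lineage count k, Exp(k*lam) draw)
    out.waiting_times = waiting_times
    return out


def clamp_internal_lengths(
    tree: PhyloTree, low: float, high: float
) -> PhyloTree:
    """Clamp internal (non-pendant, non-root) edge lengths into [low, high].

    Used to pin study conditions: keeps simulated species-tree branches away
    from the unresolvable (near-zero) and trivially easy (very long) ends.
    """
    for nd in tree.dtree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        if nd.edge.length is not None:
            nd.edge.length = min(max(nd.edge.length, low), high)
    return tree


# ---------------------------------------------------------------------------
# MSC gene trees


class _Lineage:
    __slots__ = ("node", "blen")

    def __init__(self, node, blen=0.0):
        self.node = node
        self.blen = blen


def _coalesce(lineages: list[_Lineage], duration: float, rng: random.Random):
    """Standard coalescent within one branch (rate 1 per pair per unit)."""
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        dt = rng.expovariate(k * (k - 1) / 2.0)
        if t + dt > duration:
            break
        t += dt
        for ln in lineages:
            ln.blen += dt
        i, j = rng.sample(range(k), 2)
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        for child in (a, b):
            parent.add_child(child.node)
            child.node.edge.length = child.blen
        merged = _Lineage(parent, 0.0)
        lineages = [ln for idx, ln in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    rest = duration - t
    for ln in lineages:
        ln.blen += rest
    return lineages


def _sample_gene_tree(
    species: PhyloTree, rng: random.Random, ns: dendropy.TaxonNamespace
) -> dendropy.Tree:
    def recurse(sp_node) -> list[_Lineage]:
        if sp_node.is_leaf():
            leaf = dendropy.Node()
            leaf.taxon = ns.get_taxon(sp_node.taxon.label) or dendropy.Taxon(
                label=sp_node.taxon.label
            )
            if leaf.taxon not in ns:
                ns.add_taxon(leaf.taxon)
            lineages = [_Lineage(leaf, 0.0)]
        else:
            lineages = []
            for ch in sp_node.child_nodes():
                lineages.extend(recurse(ch))
        dur = sp_node.edge.length
        if sp_node.parent_node is None:
            # above the root: coalesce everything
            while len(lineages) > 1:
                lineages = _coalesce(lineages, float("inf"), rng)
            return lineages
        if dur is None:
            raise ValueError("species tree has a branch without length")
        return _coalesce(lineages, dur, rng)

    root_lineage = recurse(species.dtree.seed_node)[0]
    gt = dendropy.Tree(taxon_namespace=ns)
    gt.seed_node = root_lineage.node
    return gt


def simulate_msc_gene_trees(
    species_tree: PhyloTree, n: int, seed: int
) -> list[PhyloTree]:
    """n independent MSC gene trees (returned unrooted, binary, complete).

    One lineage is sampled per species; within each species-tree branch
    lineages coalesce at rate 1 per pair per coalescent time unit, surviving
    lineages propagate to the parent branch, and coalescence is free above
    the root.
    """
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        ns = dendropy.TaxonNamespace()
        gt = _sample_gene_tree(species_tree, rng, ns)
        out.append(unroot(PhyloTree(gt, species_tree.taxa)))
    return out


# ---------------------------------------------------------------------------
# perturbations


def _redraw_nni(node, rng: random.Random) -> None:
    """Redraw the arrangement around the edge above ``node`` uniformly.

    The four subtrees around an internal edge admit three arrangements (the
    current one and the two nearest-neighbor interchanges); one of the three
    is chosen uniformly, so a hit edge keeps its topology with probability
    1/3.
    """
    u = node.parent_node
    siblings = [ch for ch in u.child_nodes() if ch is not node]
    if not siblings:
        return
    w = rng.choice(siblings)
    a = rng.choice(node.child_nodes() + [None])
    if a is None:
        return
    la, lw = a.edge.length, w.edge.length
    node.remove_child(a)
    u.remove_child(w)
    node.add_child(w)
    u.add_child(a)
    a.edge.length, w.edge.length = la, lw


def perturb_gene_trees(
    trees: Sequence[PhyloTree], noise_rate: float, seed: int
) -> list[PhyloTree]:
    """Independently hit each internal edge with a random NNI redraw.

    Emulates topological gene-tree estimation error. Leaf sets and branch
    lengths are preserved; only topology changes.
    """
    rng = random.Random(seed)
    out = []
    for t in trees:
        c = t.clone()
        internal = [
            nd
            for nd in c.dtree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        for nd in internal:
            if rng.random() < noise_rate:
                _redraw_nni(nd, rng)
        out.append(c)
    return out


def delete_taxa(
    trees: Sequence[PhyloTree], missing_prob: float, seed: int
) -> list[PhyloTree]:
    """Remove each leaf of each tree independently with ``missing_prob``.

    Degree-2 nodes left behind are suppressed. Trees reduced below 4 leaves
    are kept (the scorer simply gets no quartets from them).
    """
    rng = random.Random(seed)
    out = []
    for t in trees:
        c = t.clone()
        doomed = [
            lf.taxon
            for lf in c.dtree.leaf_node_iter()
            if rng.random() < missing_prob
        ]
        if doomed:
            if len(doomed) == c.n_leaves:
                c.dtree.seed_node = dendropy.Node()  # empty tree
            else:
                c.dtree.prune_taxa(doomed)
                c.dtree.suppress_unifurcations()
        out.append(c)
    return out
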