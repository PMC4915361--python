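"""End-to-end branch scoring: species tree + gene trees -> annotated tree.

For every internal branch of the (binary, unrooted) species tree this module
computes the averaged quartet frequencies from the gene trees, turns them
into the three local posterior probabilities and the ML/MAP branch lengths,
and attaches the results to a copy of the input tree. The topology is never
changed; terminal branches are never given coalescent-unit lengths (a single
lineage per species carries no coalescence information about them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import trees as _trees
from .msc_model import (
    DEFAULT_LENGTH_CAP,
    LengthEstimates,
    PosteriorTriple,
    PriorConfig,
    branch_length_estimates,
    local_pp,
)
from .quartet_core import (
    Quadripartition,
    QuartetSupportRecord,
    quadripartition_of_edge,
    quartet_support,
)
from .trees import PhyloTree, popcount, unroot

__all__ = ["ScoreConfig", "BranchAnnotation", "score_tree", "annotation_table"]


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring configuration.

    lam            — Yule prior rate (1/2 = flat prior on theta);
    annotation     — newick output mode: "pp" (posterior as node label),
                     "len" (lengths only) or "full" (label, length and a
                     bracketed comment with the complete per-branch record);
    collapse       — optional gene-tree support threshold; internal gene-tree
                     edges with support strictly below it are contracted
                     before counting (33 is the usual choice for bootstrap
                     supports);
    strict_n       — use the literal effective-gene count as the number of
                     multinomial trials instead of z1+z2+z3;
    length_cap     — finite stand-in for infinite length estimates;
    length_kind    — which estimate goes on the branch ("map" or "ml");
    prune_unknown  — drop gene-tree taxa absent from the species tree
                     instead of raising.
    """

    lam: float = 0.5
    annotation: str = "pp"
    collapse: Optional[float] = None
    strict_n: bool = False
    length_cap: float = DEFAULT_LENGTH_CAP
    length_kind: str = "map"
    prune_unknown: bool = False

    def prior(self) -> PriorConfig:
        return PriorConfig(lam=self.lam)


@dataclass
class BranchAnnotation:
    """Everything computed for one internal species-tree branch."""

    branch_id: int
    cluster_sizes: tuple[int, int, int, int]
    record: QuartetSupportRecord
    posterior: PosteriorTriple
    lengths: Optional[LengthEstimates]

    @property
    def frequencies(self) -> tuple[float, float, float]:
        return self.record.frequencies


def _validate_species_tree(sp: PhyloTree) -> PhyloTree:
    sp = unroot(sp.clone())
    if sp.n_leaves < 4:
        raise ValueError("species tree must have at least 4 taxa")
    if not sp.is_binary_unrooted():
        bad = [
            nd
            for nd in sp.dtree.preorder_node_iter()
            if not nd.is_leaf()
            and len(nd.child_nodes()) + (0 if nd.parent_node is None else 1) != 3
        ]
        raise ValueError(
            f"species tree has {len(bad)} polytomy node(s); every internal "
            "branch must be scorable (resolve the tree first)"
        )
    return sp


def _prepare_gene_trees(
    gene_trees: Sequence[PhyloTree], sp: PhyloTree, config: ScoreConfig
) -> list[PhyloTree]:
    if not gene_trees:
        raise ValueError("no gene trees given")
    sp_mask = sp.leaf_mask()
    prepared = []
    for i, gt in enumerate(gene_trees):
        if gt.taxa is not sp.taxa:
            raise ValueError(
                "species tree and gene trees must share one TaxonIndex "
                "(parse them with the same index object)"
            )
        extra = gt.leaf_mask() & ~sp_mask
        g = gt.clone()
        if extra:
            names = gt.taxa.labels_of(extra)
            if not config.prune_unknown:
                raise ValueError(
                    f"gene tree {i} contains taxa absent from the species "
                    f"tree: {', '.join(names)} (use prune_unknown to drop)"
                )
            taxa_objs = [
                lf.taxon for lf in g.dtree.leaf_node_iter()
                if lf.taxon.label in set(names)
            ]
            g.dtree.prune_taxa(taxa_objs)
        # unroot first: a support label on a degree-2 root's edge describes
        # the root bipartition, which survives collapsing only one root edge
        if g.n_leaves >= 3:
            unroot(g)
        if config.collapse is not None:
            _trees.collapse_low_support(g, config.collapse)
        prepared.append(g)
    return prepared


def score_tree(
    species_tree: PhyloTree,
    gene_trees: Sequence[PhyloTree],
    config: ScoreConfig = ScoreConfig(),
) -> tuple[PhyloTree, list[BranchAnnotation]]:
    """Score every internal branch of the species tree against the gene trees.

    Returns the annotated copy of the species tree (unrooted) and one
    :class:`BranchAnnotation` per internal branch, ordered by a preorder
    traversal. Branches no gene tree informs (n_eff = 0) are annotated NA
    with length left unknown. Deterministic for fixed inputs; gene-tree
    order does not matter.
    """
    sp = _validate_species_tree(species_tree)
    genes = _prepare_gene_trees(gene_trees, sp, config)
    prior = config.prior()

    annotations: list[BranchAnnotation] = []
    for bid, (edge, _mask) in enumerate(_trees.internal_bipartitions(sp)):
        q, q2, q3 = quadripartition_of_edge(sp, edge)
        rec = quartet_support(q, (q2, q3), genes, strict_n=config.strict_n)
        if rec.has_signal:
            pp = local_pp(rec.z, rec.n_eff, prior)
            le = branch_length_estimates(
                min(rec.z[0], rec.n_eff), rec.n_eff, prior,
                length_cap=config.length_cap,
            )
        else:
            pp = PosteriorTriple.undefined()
            le = None
        ann = BranchAnnotation(
            branch_id=bid,
            cluster_sizes=tuple(popcount(c) for c in q.clusters),
            record=rec,
            posterior=pp,
            lengths=le,
        )
        annotations.append(ann)
        _attach(edge.head_node, ann, config)
    return sp, annotations


def _attach(node, ann: BranchAnnotation, config: ScoreConfig) -> None:
    mode = config.annotation
    if ann.lengths is not None and mode in ("len", "pp", "full"):
        node.edge.length = getattr(ann.lengths, config.length_kind)
    if mode in ("pp", "full"):
        node.label = (
            f"{ann.posterior.pp1:.4g}" if ann.posterior.defined else "NA"
        )
    if mode == "full":
        z = ann.record.z
        f = ann.record.frequencies
        pp = ann.posterior.values
        le = ann.lengths
        fields = [
            f"pp1={pp[0]:.6g}", f"pp2={pp[1]:.6g}", f"pp3={pp[2]:.6g}",
            f"f1={f[0]:.6g}", f"f2={f[1]:.6g}", f"f3={f[2]:.6g}",
            f"z1={z[0]:.6g}", f"z2={z[1]:.6g}", f"z3={z[2]:.6g}",
            f"n_eff={ann.record.n_eff:.6g}",
        ]
        if le is not None:
            fields += [f"ml={le.ml:.6g}", f"map={le.map:.6g}"]
        node.comments.append("&" + ",".join(fields))


_COLUMNS = [
    "branch", "size_a", "size_b", "size_c", "size_d",
    "z1", "z2", "z3", "n_eff", "m_bar",
    "f1", "f2", "f3", "pp1", "pp2", "pp3", "len_ml", "len_map",
]


def annotation_table(annotations: Sequence[BranchAnnotation]) -> pd.DataFrame:
    """One row per internal branch; NA markers for uninformed branches."""
    rows = []
    for a in annotations:
        rec, pp = a.record, a.posterior
        if rec.has_signal:
            f = rec.frequencies
            row = dict(
                zip(
                    _COLUMNS,
                    [
                        a.branch_id, *a.cluster_sizes,
                        *rec.z, rec.n_eff, rec.m_bar,
                        *f, *pp.values,
                        a.lengths.ml, a.lengths.map,
                    ],
                )
            )
        else:
            row = dict(
                zip(
                    _COLUMNS,
                    [a.branch_id, *a.cluster_sizes, *rec.z, 0.0, math.nan]
                    + [math.nan] * 8,
                )
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)
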