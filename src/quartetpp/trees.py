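"""Tree containers and newick plumbing.

Trees are stored as :class:`dendropy.Tree` objects wrapped together with a
:class:`TaxonIndex` that maps taxon labels to stable integer bit positions.
All set algebra on taxon clusters is done on plain Python integers used as
bitmasks, which keeps intersection/union/cardinality exact.

Conventions:

* internal node labels in newick are read as branch *support* values
  (an option switches to bracketed ``[&support=x]`` comments instead);
* a missing edge length is stored as ``None`` ("unknown"), never as ``0.0``,
  because zero is a meaningful coalescent-unit length;
* unrooted trees are represented rooted at an internal node of degree >= 3
  (the usual "seed node" convention); ``unroot`` suppresses a degree-2 root.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = [
    "TaxonIndex",
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "parse_newick_file",
    "write_newick",
    "unroot",
    "internal_bipartitions",
    "collapse_low_support",
    "popcount",
]


def popcount(mask: int) -> int:
    """Number of taxa in a bitmask cluster."""
    return mask.bit_count()


class NewickParseError(ValueError):
    """Raised for malformed newick input or inconsistent taxon labels."""


@dataclass
class TaxonIndex:
    """Bijection between taxon labels and bit positions ``0..l-1``.

    The index is shared by every tree in one run so that a cluster bitmask
    computed on a gene tree is directly comparable with one computed on the
    species tree.
    """

    names: list[str] = field(default_factory=list)
    _pos: dict[str, int] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._pos

    def add(self, name: str) -> int:
        if not name:
            raise NewickParseError("empty taxon label")
        if name in self._pos:
            return self._pos[name]
        self._pos[name] = len(self.names)
        self.names.append(name)
        return self._pos[name]

    def index_of(self, name: str) -> int:
        return self._pos[name]

    def bit(self, name: str) -> int:
        return 1 << self._pos[name]

    def mask_of(self, names: Sequence[str]) -> int:
        m = 0
        for n in names:
            m |= self.bit(n)
        return m

    @property
    def full_mask(self) -> int:
        return (1 << len(self.names)) - 1

    def labels_of(self, mask: int) -> list[str]:
        return [n for n in self.names if mask >> self._pos[n] & 1]


class PhyloTree:
    """A phylogenetic tree bound to a :class:`TaxonIndex`.

    Thin wrapper over :class:`dendropy.Tree`; quartet counting and scoring
    modules only ever see bitmasks derived from it.
    """

    def __init__(self, dtree: dendropy.Tree, taxa: TaxonIndex):
        self.dtree = dtree
        self.taxa = taxa

    # -- basic structure ---------------------------------------------------
    @property
    def seed(self) -> dendropy.Node:
        return self.dtree.seed_node

    def leaf_nodes(self) -> list[dendropy.Node]:
        return [lf for lf in self.dtree.leaf_node_iter() if lf.taxon]

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.leaf_nodes()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    def leaf_mask(self) -> int:
        """Bitmask of all taxa present in this tree."""
        m = 0
        for lf in self.leaf_nodes():
            m |= self.taxa.bit(lf.taxon.label)
        return m

    def node_masks(self) -> dict[dendropy.Node, int]:
        """Postorder map node -> bitmask of the leaves under it."""
        masks: dict[dendropy.Node, int] = {}
        for nd in self.dtree.postorder_node_iter():
            if nd.is_leaf():
                masks[nd] = self.taxa.bit(nd.taxon.label) if nd.taxon else 0
            else:
                m = 0
                for ch in nd.child_nodes():
                    m |= masks[ch]
                masks[nd] = m
        return masks

    def is_binary_unrooted(self) -> bool:
        """True if every internal node has degree exactly 3."""
        for nd in self.dtree.preorder_node_iter():
            if nd.is_leaf():
                continue
            deg = len(nd.child_nodes()) + (0 if nd.parent_node is None else 1)
            if deg != 3:
                return False
        return True

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.dtree.clone(depth=1), self.taxa)

    def __str__(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# parsing


def _support_from_comments(nd: dendropy.Node) -> Optional[str]:
    for c in nd.comments or []:
        txt = c.strip().lstrip("&")
        for part in txt.split(","):
            if "=" in part:
                k, v = part.split("=", 1)
                if k.strip().lower() == "support":
                    return v.strip()
    return None


def parse_newick(
    text: str,
    taxa: Optional[TaxonIndex] = None,
    support_in_comments: bool = False,
) -> PhyloTree:
    """Parse a single newick tree.

    Internal node labels are interpreted as support values on the subtending
    edge; with ``support_in_comments=True`` supports are instead read from
    bracketed ``[&support=x]`` comments. New taxon labels are appended to
    ``taxa`` (created if not given); duplicates within one tree are an error.
    """
    if taxa is None:
        taxa = TaxonIndex()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf label(s): {', '.join(dupes)}")
    for lb in labels:
        taxa.add(lb)
    if support_in_comments:
        for nd in dtree.preorder_node_iter():
            if not nd.is_leaf():
                sup = _support_from_comments(nd)
                if sup is not None:
                    nd.label = sup
    return PhyloTree(dtree, taxa)


def parse_newick_file(
    path: str,
    taxa: Optional[TaxonIndex] = None,
    support_in_comments: bool = False,
) -> list[PhyloTree]:
    """Read one newick tree per non-empty line (the usual gene-tree format)."""
    if taxa is None:
        taxa = TaxonIndex()
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line, taxa, support_in_comments))
            except NewickParseError as exc:
                raise NewickParseError(f"{path}:{lineno}: {exc}") from exc
    return trees


# ---------------------------------------------------------------------------
# writing


def write_newick(tree: PhyloTree, mode: str = "both") -> str:
    """Serialize to newick.

    Modes control internal-edge annotation:

    * ``"support"`` — node label only;
    * ``"length"``  — edge lengths only;
    * ``"both"``    — labels and lengths (default);
    * ``"full-comment"`` — labels, lengths, and any bracketed comments
      attached to nodes (used for the full per-branch scoring record).
    """
    if mode not in ("support", "length", "both", "full-comment"):
        raise ValueError(f"unknown annotation mode: {mode!r}")
    kwargs = dict(
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_item_comments=(mode != "full-comment"),
    )
    if mode == "support":
        kwargs["suppress_edge_lengths"] = True
    if mode == "length":
        kwargs["suppress_internal_node_labels"] = True
    out = tree.dtree.as_string(schema="newick", **kwargs)
    return out.strip()


# ---------------------------------------------------------------------------
# unrooting


def unroot(tree: PhyloTree) -> PhyloTree:
    """Suppress a degree-2 root, summing the two merged edge lengths.

    Idempotent; the input object is returned modified in place. Unifurcations
    anywhere else are suppressed too, so the result has no degree-2 nodes.
    """
    if tree.n_leaves < 3:
        raise ValueError("unrooting requires at least 3 leaves")
    dtree = tree.dtree
    root = dtree.seed_node
    kids = root.child_nodes()
    if len(kids) == 2:
        # keep the internal child as the new seed; fold the other child in
        keep, move = kids if not kids[0].is_leaf() else (kids[1], kids[0])
        if keep.is_leaf():
            raise ValueError("cannot unroot a 2-leaf tree")
        lengths = [e for e in (keep.edge.length, move.edge.length) if e is not None]
        merged = sum(lengths) if lengths else None
        root.remove_child(move)
        root.remove_child(keep)
        keep.parent_node = None
        keep.add_child(move)
        move.edge.length = merged
        # the two root edges describe the same bipartition: keep one label
        if move.label is None and not move.is_leaf():
            move.label = keep.label
        keep.label = None
        keep.edge.length = None
        dtree.seed_node = keep
    dtree.suppress_unifurcations()
    dtree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions


def internal_bipartitions(tree: PhyloTree) -> list[tuple[dendropy.Edge, int]]:
    """All internal edges of an unrooted tree as (edge, cluster bitmask).

    The mask is the leaf set on the child side of the edge. A binary unrooted
    tree on ``l`` leaves yields exactly ``l - 3`` entries.
    """
    masks = tree.node_masks()
    full = tree.leaf_mask()
    out = []
    for nd in tree.dtree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        m = masks[nd]
        if popcount(m) >= 2 and popcount(full & ~m) >= 2:
            out.append((nd.edge, m))
    return out


# ---------------------------------------------------------------------------
# support collapsing


def _parse_support(label: Optional[str]) -> Optional[float]:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def _to_probability(value: float) -> float:
    """Auto-detect support scale: values in (1, 100] are percentages."""
    return value / 100.0 if 1.0 < value <= 100.0 else value


def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract internal edges whose support is strictly below ``threshold``.

    Support labels and the threshold may each be on a percentage (1, 100] or
    probability [0, 1] scale; both are normalized before comparison. Edges
    without a (numeric) support label are retained; a non-numeric label
    triggers a warning. Modifies and returns the input tree; the output may
    be multifurcating.
    """
    thr = _to_probability(threshold)
    to_collapse = []
    for nd in tree.dtree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        sup = _parse_support(nd.label)
        if sup is None:
            if nd.label not in (None, ""):
                warnings.warn(
                    f"non-numeric support label {nd.label!r}; edge retained",
                    stacklevel=2,
                )
            continue
        if _to_probability(sup) < thr:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return tree
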