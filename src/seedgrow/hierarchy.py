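"""Agglomerative hierarchy over cluster centroids for computer-assisted naming.

After growing, hundreds of fine clusters remain that often depict the same
or closely related classes.  Arranging them as a UPGMA (average-linkage)
dendrogram over their centroids places look-alike clusters on neighboring
leaves, so an annotator can work leaves-to-root, merge duplicates, move
branches, and name nodes; flattening then transfers each node's name to
its objects via the nearest named ancestor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .core import (
    UNNAMED_LABEL,
    Cluster,
    FeatureSet,
    LabelTable,
    StateError,
    ValidationError,
)


@dataclass
class HNode:
    """One node of the naming hierarchy.

    ``clusters`` holds the node's *direct* member clusters (leaves start
    with exactly one; merges can concentrate several on a node).  The
    node's full object set is the union over its subtree.
    """

    node_id: int
    height: float = 0.0
    name: str | None = None
    approved: bool = False
    clusters: list[Cluster] = field(default_factory=list)
    children: list["HNode"] = field(default_factory=list)
    parent: "HNode | None" = None

    def walk(self) -> Iterator["HNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def is_leaf(self) -> bool:
        return not self.children

    def subtree_clusters(self) -> list[Cluster]:
        return [cl for n in self.walk() for cl in n.clusters]

    def subtree_objects(self) -> set[str]:
        out: set[str] = set()
        for cl in self.subtree_clusters():
            out |= cl.members
        return out


class HierarchyTree:
    """Rooted tree over clusters with editable structure and names."""

    def __init__(self, root: HNode):
        self.root = root
        for n in root.walk():
            if any(c.parent is not n for c in n.children):
                raise ValidationError("child/parent links inconsistent")

    def nodes(self) -> list[HNode]:
        return list(self.root.walk())

    def find(self, node_id: int) -> HNode:
        for n in self.root.walk():
            if n.node_id == node_id:
                return n
        raise KeyError(f"no node {node_id}")

    def leaves(self) -> list[HNode]:
        return [n for n in self.root.walk() if n.is_leaf()]

    def depth(self) -> int:
        """Edge count of the deepest leaf."""

        def d(n: HNode) -> int:
            return 0 if n.is_leaf() else 1 + max(d(c) for c in n.children)

        return d(self.root)

    def objects(self) -> set[str]:
        return self.root.subtree_objects()

    def _is_ancestor(self, anc: HNode, node: HNode) -> bool:
        p = node.parent
        while p is not None:
            if p is anc:
                return True
            p = p.parent
        return False


def build_hierarchy(
    clusters: list[Cluster], features: FeatureSet
) -> HierarchyTree:
    """UPGMA dendrogram over the clusters' full-member centroids.

    Node heights are ultrametric: a merge of groups at average pairwise
    centroid distance d sits at height d/2, so two clusters at distance d
    join at d/2 and leaves sit at height 0.  Ties in merge distances are
    broken deterministically by ordering the input clusters by id.
    """
    if not clusters:
        raise ValidationError("cannot build a hierarchy over zero clusters")
    ordered = sorted(clusters, key=lambda c: c.cluster_id)
    leaves = [
        HNode(node_id=i, height=0.0, clusters=[c]) for i, c in enumerate(ordered)
    ]
    if len(ordered) == 1:
        return HierarchyTree(leaves[0])

    centroids = np.vstack([c.full_centroid(features) for c in ordered])
    Z = linkage(pdist(centroids), method="average")

    nodes: list[HNode] = list(leaves)
    next_id = len(leaves)
    for a, b, dist, _n in Z:
        left, right = nodes[int(a)], nodes[int(b)]
        parent = HNode(node_id=next_id, height=float(dist) / 2.0)
        parent.children = [left, right]
        left.parent = right.parent = parent
        nodes.append(parent)
        next_id += 1
    return HierarchyTree(nodes[-1])


def merge_nodes(tree: HierarchyTree, node_ids: Iterable[int]) -> HierarchyTree:
    """Collapse several related nodes into one.

    Allowed when the nodes all share a parent, or when one of them is an
    ancestor of all the others; anything else must be rearranged with
    :func:`move_node` first.  The surviving node absorbs every cluster in
    the merged subtrees, so the object multiset is conserved.
    """
    ids = sorted(set(node_ids))
    nodes = [tree.find(i) for i in ids]
    if len(nodes) <= 1:
        return tree  # merging a node with itself is a no-op

    anc = next(
        (n for n in nodes if all(m is n or tree._is_ancestor(n, m) for m in nodes)),
        None,
    )
    if anc is not None:
        target, others = anc, [n for n in nodes if n is not anc]
    else:
        parents = {id(n.parent) for n in nodes}
        if len(parents) != 1 or nodes[0].parent is None:
            raise StateError(
                "nodes must share a parent or be nested under one of them"
            )
        target, others = nodes[0], nodes[1:]

    for n in others:
        target.clusters.extend(n.subtree_clusters())
        n.parent.children.remove(n)
        n.parent = None
    if anc is not None:
        # absorbed descendants may leave empty internal nodes behind
        _prune_empty(target)
    # splice out cluster-less parents left with a single child so the
    # merged node becomes a sibling of its next surviving relative
    p = target.parent
    while p is not None and len(p.children) == 1 and not p.clusters:
        gp = p.parent
        if gp is None:
            tree.root = target
            target.parent = None
            break
        gp.children[gp.children.index(p)] = target
        target.parent = gp
        p.parent = None
        p = gp
    return tree


def _prune_empty(node: HNode) -> None:
    for c in list(node.children):
        _prune_empty(c)
        if c.is_leaf() and not c.clusters:
            node.children.remove(c)
            c.parent = None


def move_node(tree: HierarchyTree, node_id: int, new_parent_id: int) -> HierarchyTree:
    """Reattach a node (and its subtree) under another node.

    Refuses moves that would detach the root or create a cycle.
    """
    node = tree.find(node_id)
    new_parent = tree.find(new_parent_id)
    if node is tree.root:
        raise StateError("cannot move the root")
    if node is new_parent or tree._is_ancestor(node, new_parent):
        raise StateError("move would create a cycle")
    if node.parent is new_parent:
        return tree
    node.parent.children.remove(node)
    node.parent = new_parent
    new_parent.children.append(node)
    return tree


def name_node(tree: HierarchyTree, node_id: int, name: str) -> HierarchyTree:
    """Assign a free-form nonempty name to a node (idempotent)."""
    if not name or not name.strip():
        raise ValidationError("names must be nonempty")
    tree.find(node_id).name = name
    return tree


def flatten_labels(tree: HierarchyTree) -> LabelTable:
    """Transfer node names to objects.

    Each object receives the name of the nearest named node on the path
    from its cluster's node to the root (the owning node itself preferred);
    objects under no named node get the reserved label ``"unnamed"``.
    Residual objects (in no cluster) are absent from the result.
    """
    mapping: dict[str, str] = {}

    def visit(node: HNode, inherited: str | None) -> None:
        effective = node.name if node.name else inherited
        label = effective if effective else UNNAMED_LABEL
        for cl in node.clusters:
            for oid in cl.members:
                mapping[oid] = label
        for c in node.children:
            visit(c, effective)

    visit(tree.root, None)
    return LabelTable(mapping)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def to_newick(tree: HierarchyTree) -> str:
    """Newick string with names as labels and height differences as branch
    lengths (labels with spaces are quoted)."""
    dt = dendropy.Tree()

    def convert(node: HNode, parent):
        dn = parent.new_child() if parent is not None else dt.seed_node
        label = node.name or f"node{node.node_id}"
        if node.is_leaf():
            dn.taxon = dt.taxon_namespace.new_taxon(label=label)
        else:
            dn.label = label
        if node.parent is not None:
            dn.edge.length = max(node.parent.height - node.height, 0.0)
        for c in node.children:
            convert(c, dn)

    convert(tree.root, None)
    return dt.as_string(schema="newick", suppress_rooting=True).strip()


def to_json(tree: HierarchyTree) -> str:
    """JSON dialect carrying structure, heights, names and member lists."""

    def enc(node: HNode) -> dict:
        return {
            "node_id": node.node_id,
            "height": node.height,
            "name": node.name,
            "approved": node.approved,
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "seed_members": sorted(c.seed_members),
                    "grown_members": sorted(c.grown_members),
                    "name": c.name,
                }
                for c in node.clusters
            ],
            "children": [enc(c) for c in node.children],
        }

    return json.dumps(enc(tree.root), indent=1)
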