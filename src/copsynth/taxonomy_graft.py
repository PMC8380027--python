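"""Grafting unsampled taxonomy species onto a synthesis tree.

The Linnaean hierarchy is tree-like: species form a polytomy within
their genus, genera within their family, and so on.  Treating that
hierarchy as a null hypothesis of monophyly, every species absent from
the synthesis tree is attached as a polytomy under the lowest containing
taxon that is both sampled and *unbroken*.  A taxon is broken when its
sampled members are not monophyletic in the synthesis tree; unsampled
members of a broken taxon cannot be placed inside it and escalate to the
attachment point of the next higher rank — which is how large basal
polytomies of never-sampled families arise in practice.

"No rank" containers are transparent for escalation, and species whose
recorded parent is the taxonomy root (uncertain ordinal status) join the
root polytomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .synthesis import SynthesisTree
from .treeio import Node, RootedTree, Taxonomy, resolve_species_keys

__all__ = ["GraftedTree", "broken_taxa", "graft", "tip_count"]


@dataclass
class Attachment:
    species_id: int
    attached_under: str  # name of the taxon whose attachment point was used
    attachment_rank: str
    reason: str  # "in-place" | "broken-<taxon>" | "unsampled-parent"


@dataclass
class GraftedTree:
    tree: RootedTree
    attachments: list = field(default_factory=list)  # list[Attachment]
    broken: frozenset = frozenset()

    def attachment_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species_id": a.species_id,
                    "attached_under": a.attached_under,
                    "attachment_rank": a.attachment_rank,
                    "reason": a.reason,
                }
                for a in self.attachments
            ],
            columns=["species_id", "attached_under", "attachment_rank", "reason"],
        )


def tip_count(grafted: GraftedTree) -> int:
    return grafted.tree.n_tips()


def _tree_of(synth) -> RootedTree:
    return synth.tree if isinstance(synth, SynthesisTree) else synth


def broken_taxa(synth, taxonomy: Taxonomy) -> frozenset:
    """Taxa whose sampled members are not monophyletic in the synthesis tree.

    A taxon with at least two sampled species is broken when the MRCA of
    those species also contains a sampled tip from outside the taxon
    (including tips with no taxonomy record at all).
    """
    tree = _tree_of(synth)
    mapping = resolve_species_keys(tree.tip_set(), taxonomy)  # tip key -> species id
    inverse = {sp: key for key, sp in mapping.items()}
    sampled_species = set(mapping.values())
    out = set()
    for tid in taxonomy.preorder():
        rec = taxonomy[tid]
        if rec.rank == "species":
            continue
        members = taxonomy.species_of(tid) & sampled_species
        if len(members) < 2:
            continue
        node = tree.mrca({inverse[sp] for sp in members})
        for key in tree.tipset_of(node):
            # extra-taxonomic tips inside the span break the taxon too
            if mapping.get(key) not in taxonomy.species_of(tid):
                out.add(tid)
                break
    return frozenset(out)


def graft(
    synth,
    taxonomy: Taxonomy,
    extra_taxonomic: Optional[set] = None,
) -> GraftedTree:
    """Attach every taxonomy species missing from the synthesis tree.

    Sampled tips must map to taxonomy species unless listed in
    ``extra_taxonomic`` (e.g. terminals identified only to genus level in
    sequence databases); those stay where the synthesis placed them.
    Unsampled material is walked in taxonomy preorder, so a wholly
    unsampled higher taxon attaches once, as one nested-polytomy subtree,
    before its contents are considered individually.
    """
    tree = _tree_of(synth).copy()
    extra = set(extra_taxonomic or ())
    mapping = resolve_species_keys(tree.tip_set(), taxonomy)  # tip key -> species id
    inverse = {sp: key for key, sp in mapping.items()}
    sampled = set(mapping.values())
    unmapped = {t for t in tree.tip_set() if t not in mapping and t not in extra}
    if unmapped:
        raise ValueError(
            "sampled tips absent from taxonomy and not flagged extra-taxonomic: "
            f"{sorted(unmapped, key=str)[:10]}"
        )

    grafted = GraftedTree(tree=tree, broken=broken_taxa(_tree_of(synth), taxonomy))
    # attachment-node cache; leaf-splitting for single-sampled taxa must
    # happen once so later grafts reuse the same new internal node
    anchors: dict[int, Node] = {}

    def attachment_node(tid: int) -> tuple[Node, int]:
        """Node under which material contained in taxon ``tid`` attaches,
        plus the id of the taxon that finally anchored it."""
        if tid in anchors:
            return anchors[tid], tid
        rec = taxonomy[tid]
        if rec.parent_id is None:
            node = tree.root
        elif tid in grafted.broken or not (taxonomy.species_of(tid) & sampled):
            # polyphyletic or invisible at this level: next higher rank
            return attachment_node(rec.parent_id)
        else:
            members = taxonomy.species_of(tid) & sampled
            node = tree.mrca({inverse[sp] for sp in members})
            if node.is_leaf:
                # single sampled member: a new node above that tip keeps
                # the taxon's monophyly claim, grafts become its siblings
                node = _split_leaf(tree, node)
        anchors[tid] = node
        return node, tid

    def materialize(tid: int) -> Node:
        rec = taxonomy[tid]
        if rec.rank == "species":
            return Node(label=rec.name, taxon_id=rec.id)
        node = Node(label=rec.name)
        for child in taxonomy.children[tid]:
            node.add_child(materialize(child))
        return node

    def log_subtree(tid: int, anchor_tid: int, reason: str):
        rec = taxonomy[anchor_tid]
        for sp in sorted(taxonomy.species_of(tid)):
            grafted.attachments.append(
                Attachment(sp, rec.name, rec.rank, reason)
            )

    def walk(tid: int):
        for child in taxonomy.children[tid]:
            crec = taxonomy[child]
            members = taxonomy.species_of(child) & sampled
            if members:
                walk(child)
                continue
            # maximal unsampled taxon (or unsampled species): attach its
            # whole subtree at the parent's attachment point
            node, anchor_tid = attachment_node(tid)
            node.add_child(materialize(child))
            if anchor_tid == tid and tid not in grafted.broken:
                reason = "in-place"
            elif tid in grafted.broken or anchor_tid in grafted.broken:
                reason = f"broken-{taxonomy[tid].name}"
            else:
                reason = "unsampled-parent"
            log_subtree(child, anchor_tid, reason)

    walk(taxonomy.root_id)
    return grafted


def _split_leaf(tree: RootedTree, leaf: Node) -> Node:
    fresh = Node()
    parent = leaf.parent
    if parent is None:
        tree.root = fresh
    else:
        idx = parent.children.index(leaf)
        parent.children[idx] = fresh
        fresh.parent = parent
    leaf.parent = None
    fresh.add_child(leaf)
    return fresh
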